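"""Disproportionality statistics for spontaneous-report signal detection.

All four classical screening statistics are computed from the 2x2
report-count table of a drug–event pair over the deduplicated report
universe:

================  ===========  ===============
                  target event  other events
----------------  -----------  ---------------
suspect drug          a              b
other drugs           c              d
================  ===========  ===============

* ROR  = ad/bc with a log-normal 95% CI,
* PRR  = [a/(a+b)] / [c/(c+d)] with a log-normal 95% CI,
* IC   = shrunken log2 observed-to-expected (BCPNN), with the credibility
  lower bound IC025,
* EBGM = empirical Bayes geometric mean of the relative reporting rate,
  with the 5% lower bound EBGM05. The default EBGM is the simplified
  observed/expected form; a full DuMouchel gamma-mixture fit is available
  via :func:`mgps_full`.

A pair is a *signal* only when all four methods pass their thresholds:
ROR and PRR each need a >= 3 and CI lower bound > 1, IC025 > 0, and
EBGM05 > 2 with a > 0. The four-way AND is deliberately conservative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile
Z90 = 1.6448536269514722  # one-sided 5% normal quantile

#: WHO ATC level-1 class descriptions.
ATC_LEVEL1 = {
    "A": "Alimentary tract and metabolism",
    "B": "Blood and blood forming organs",
    "C": "Cardiovascular system",
    "D": "Dermatologicals",
    "G": "Genito urinary system and sex hormones",
    "H": "Systemic hormonal preparations, excl. sex hormones and insulins",
    "J": "Antiinfectives for systemic use",
    "L": "Antineoplastic and immunomodulating agents",
    "M": "Musculo-skeletal system",
    "N": "Nervous system",
    "P": "Antiparasitic products, insecticides and repellents",
    "R": "Respiratory system",
    "S": "Sensory organs",
    "V": "Various",
}


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts of a drug–event four-fold table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected a under independence: (a+b)(a+c)/N."""
        if self.N == 0:
            return float("nan")
        return (self.a + self.b) * (self.a + self.c) / self.N


@dataclass
class SignalMetrics:
    """Point estimates, 95% bounds, and the combined four-way verdict."""

    name: str
    level: str  # drug | drug_pt | atc_class
    a: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    prr_lo: float
    prr_hi: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    is_signal: bool = False
    event: str = ""

    @property
    def n_reports(self) -> int:
        return self.a


def _finite(*xs: float) -> bool:
    return all(math.isfinite(x) for x in xs)


def ror(ct: ContingencyTable, haldane: bool = False) -> tuple[float, float, float]:
    """Reporting odds ratio ad/bc and its log-normal 95% CI.

    With any zero cell the estimate is undefined (NaN) unless
    ``haldane`` adds 0.5 to every cell. No correction is applied by
    default: the signal criteria require a >= 3 anyway.
    """
    a, b, c, d = ct.a, ct.b, ct.c, ct.d
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) <= 0:
        return (math.nan, math.nan, math.nan)
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se))


def prr(ct: ContingencyTable, haldane: bool = False) -> tuple[float, float, float]:
    """Proportional reporting ratio and its log-normal 95% CI.

    a = 0 yields PRR = 0 (never a signal) with undefined bounds; zero
    denominators yield NaN.
    """
    a, b, c, d = ct.a, ct.b, ct.c, ct.d
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if (a + b) <= 0 or c <= 0 or (c + d) <= 0:
        return (math.nan, math.nan, math.nan)
    est = (a / (a + b)) / (c / (c + d))
    if a <= 0:
        return (0.0, math.nan, math.nan)
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return (est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se))


def ic(ct: ContingencyTable, variant: str = "noren") -> tuple[float, float]:
    """BCPNN information component and its 95% credibility lower bound.

    ``noren`` (default): shrunken observed-to-expected
    IC = log2[(a+1/2)/(E+1/2)] with the credibility-interval
    approximation IC025 = IC - 3.3(a+1/2)^(-1/2) - 2.0(a+1/2)^(-3/2).

    ``bate``: the beta/Dirichlet-prior expectation–variance form of the
    original BCPNN, IC025 = E(IC) - 1.96 sqrt(V(IC)). The two variants
    agree closely for a >= 3.
    """
    N = ct.N
    if N <= 0:
        return (math.nan, math.nan)
    a = ct.a
    E = ct.expected
    if variant == "noren":
        ic_ = math.log2((a + 0.5) / (E + 0.5))
        ic025 = ic_ - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
        return (ic_, ic025)
    if variant == "bate":
        n1 = ct.a + ct.b  # drug margin
        n2 = ct.a + ct.c  # event margin
        alpha1 = beta1 = 1.0
        alpha = beta = 2.0
        g11 = 1.0
        gamma = g11 * (N + alpha) * (N + beta) / ((n1 + alpha1) * (n2 + beta1))
        e_ic = math.log2(
            (a + g11) * (N + alpha) * (N + beta)
            / ((N + gamma) * (n1 + alpha1) * (n2 + beta1))
        )
        v_ic = (1 / math.log(2)) ** 2 * (
            (N - a + gamma - g11) / ((a + g11) * (1 + N + gamma))
            + (N - n1 + alpha - alpha1) / ((n1 + alpha1) * (1 + N + alpha))
            + (N - n2 + beta - beta1) / ((n2 + beta1) * (1 + N + beta))
        )
        return (e_ic, e_ic - Z95 * math.sqrt(v_ic))
    raise ValueError(f"unknown IC variant {variant!r}")


def ebgm(ct: ContingencyTable) -> tuple[float, float]:
    """Simplified EBGM: relative reporting rate a/E with lognormal EB05.

    EBGM05 = exp(ln EBGM - 1.645 sqrt(1/a + 1/b + 1/c + 1/d)). a = 0
    (or a degenerate margin) is undefined — and by the "a > 0" clause
    can never be a signal.
    """
    if ct.N <= 0 or ct.a <= 0:
        return (math.nan, math.nan)
    E = ct.expected
    if E <= 0:
        return (math.nan, math.nan)
    est = ct.a / E
    if min(ct.b, ct.c, ct.d) <= 0:
        return (est, math.nan)
    se = math.sqrt(1 / ct.a + 1 / ct.b + 1 / ct.c + 1 / ct.d)
    return (est, est * math.exp(-Z90 * se))


def compute_metrics(
    ct: ContingencyTable,
    name: str = "",
    level: str = "drug",
    event: str = "",
    ic_variant: str = "noren",
    haldane: bool = False,
) -> SignalMetrics:
    """All four statistics for one table, plus the combined verdict."""
    r, r_lo, r_hi = ror(ct, haldane=haldane)
    p, p_lo, p_hi = prr(ct, haldane=haldane)
    i, i025 = ic(ct, variant=ic_variant)
    e, e05 = ebgm(ct)
    m = SignalMetrics(
        name=name, level=level, event=event, a=ct.a,
        ror=r, ror_lo=r_lo, ror_hi=r_hi,
        prr=p, prr_lo=p_lo, prr_hi=p_hi,
        ic=i, ic025=i025, ebgm=e, ebgm05=e05,
    )
    m.is_signal = evaluate_signal(m)
    return m


def evaluate_signal(m: SignalMetrics) -> bool:
    """Combined four-way criterion (all thresholds strict).

    ROR: a >= 3 and CI lower bound > 1; PRR: same; BCPNN: IC025 > 0;
    MGPS: EBGM05 > 2 and a > 0. Any undefined statistic fails.
    """
    if not _finite(m.ror_lo, m.prr_lo, m.ic025, m.ebgm05):
        return False
    return (
        m.a >= 3
        and m.ror_lo > 1
        and m.prr_lo > 1
        and m.ic025 > 0
        and m.ebgm05 > 2
        and m.a > 0
    )


def build_contingency(drug_flags, event_flags) -> ContingencyTable:
    """Count the four cells from per-report boolean vectors.

    Both vectors must cover the same deduplicated report universe; a
    report with the suspect drug and >= 1 target event contributes one
    count to cell a.
    """
    drug = np.asarray(drug_flags, dtype=bool)
    event = np.asarray(event_flags, dtype=bool)
    if drug.shape != event.shape:
        raise ValueError(
            f"flag vectors span different universes: {drug.shape} vs {event.shape}"
        )
    a = int(np.sum(drug & event))
    b = int(np.sum(drug & ~event))
    c = int(np.sum(~drug & event))
    d = int(np.sum(~drug & ~event))
    return ContingencyTable(a, b, c, d)


# ---------------------------------------------------------------------------
# Full MGPS (DuMouchel gamma-Poisson shrinker)
# ---------------------------------------------------------------------------

@dataclass
class MGPSResult:
    """Fitted DuMouchel prior and per-table posterior summaries."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    converged: bool
    ebgm: np.ndarray = field(default_factory=lambda: np.array([]))
    eb05: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def prior(self) -> tuple[float, float, float, float, float]:
        return (self.alpha1, self.beta1, self.alpha2, self.beta2, self.w)


def _nb_logpmf(a: np.ndarray, shape: float, rate: float, E: np.ndarray) -> np.ndarray:
    # marginal of Poisson(lambda*E) with lambda ~ Gamma(shape, rate)
    p = rate / (rate + E)
    return stats.nbinom.logpmf(a, shape, p)


def _mgps_negloglik(theta: np.ndarray, a: np.ndarray, E: np.ndarray) -> float:
    la1, lb1, la2, lb2, logit_w = np.clip(theta, -7, 7)
    a1, b1, a2, b2 = np.exp([la1, lb1, la2, lb2])
    w = special.expit(logit_w)
    with np.errstate(all="ignore"):
        l1 = _nb_logpmf(a, a1, b1, E) + np.log(w)
        l2 = _nb_logpmf(a, a2, b2, E) + np.log1p(-w)
        nll = -float(np.sum(np.logaddexp(l1, l2)))
    return nll if math.isfinite(nll) else 1e12


def mgps_full(tables: list[ContingencyTable]) -> MGPSResult:
    """Fit the two-component gamma-mixture prior and shrink every pair.

    The prior (alpha1, beta1, alpha2, beta2, w) maximises the
    negative-binomial marginal likelihood of the observed a's given their
    expectations E; each pair's posterior is a gamma mixture with
    EBGM = 2^(E[log2 lambda | a]) and EB05 its 5th percentile. Requires
    >= 50 tables over one shared universe; on optimizer failure the
    result is flagged and callers fall back to the simplified estimator.
    """
    if len(tables) < 50:
        raise ValueError("mgps_full needs >= 50 drug-event tables")
    a = np.array([t.a for t in tables], dtype=float)
    E = np.array([t.expected for t in tables], dtype=float)
    if np.any(~np.isfinite(E)) or np.any(E <= 0):
        raise ValueError("every table needs a positive expected count")

    # Multi-start bounded fit: the classic DuMouchel start plus starts
    # that place the second component near the empirical extremes of
    # a/E, so a heterogeneous tail is not missed. Best finite optimum
    # wins; Nelder-Mead polishes within the same parameter box.
    rel = (a + 0.5) / E
    hi = float(np.log(np.clip(np.max(rel), 1.5, 500.0)))
    starts = [
        np.array([np.log(0.2), np.log(0.1), np.log(2.0), np.log(4.0), 0.0]),
        np.array([np.log(5.0), np.log(5.0), np.log(1.0), np.log(1.0), 1.0]),
        np.array([np.log(2.0), np.log(2.0), np.log(4.0) + hi, np.log(4.0), 2.0]),
    ]
    bounds = [(-7.0, 7.0)] * 5
    res = None
    for x0 in starts:
        cand = optimize.minimize(_mgps_negloglik, x0, args=(a, E),
                                 method="L-BFGS-B", bounds=bounds)
        cand = optimize.minimize(
            _mgps_negloglik, cand.x, args=(a, E), method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-9},
        )
        if res is None or (math.isfinite(cand.fun) and cand.fun < res.fun):
            res = cand
    res.x = np.clip(res.x, -7, 7)
    a1, b1, a2, b2 = np.exp(res.x[:4])
    w = float(special.expit(res.x[4]))
    out = MGPSResult(a1, b1, a2, b2, w, converged=bool(res.success))
    if not res.success:
        logger.warning("MGPS prior fit did not converge: %s", res.message)
        return out

    # posterior mixture: component j is Gamma(alpha_j + a, beta_j + E)
    l1 = _nb_logpmf(a, a1, b1, E) + np.log(w)
    l2 = _nb_logpmf(a, a2, b2, E) + np.log1p(-w)
    q1 = np.exp(l1 - np.logaddexp(l1, l2))
    q2 = 1.0 - q1
    s1, r1 = a1 + a, b1 + E
    s2, r2 = a2 + a, b2 + E
    elog = q1 * (special.digamma(s1) - np.log(r1)) + q2 * (special.digamma(s2) - np.log(r2))
    out.ebgm = np.exp(elog)

    eb05 = np.empty_like(a)
    for i in range(len(a)):
        lo = min(stats.gamma.ppf(0.001, s1[i], scale=1 / r1[i]),
                 stats.gamma.ppf(0.001, s2[i], scale=1 / r2[i]))
        hi = max(stats.gamma.ppf(0.999, s1[i], scale=1 / r1[i]),
                 stats.gamma.ppf(0.999, s2[i], scale=1 / r2[i]))

        def cdf(x: float, i: int = i) -> float:
            return (q1[i] * stats.gamma.cdf(x, s1[i], scale=1 / r1[i])
                    + q2[i] * stats.gamma.cdf(x, s2[i], scale=1 / r2[i]) - 0.05)

        if cdf(lo) > 0:
            eb05[i] = lo
        elif cdf(hi) < 0:
            eb05[i] = hi
        else:
            eb05[i] = optimize.brentq(cdf, lo, hi, xtol=1e-10)
    out.eb05 = eb05
    return out


# ---------------------------------------------------------------------------
# Analysis-level wrappers
# ---------------------------------------------------------------------------

def drug_level_analysis(
    drug_of_report: pd.Series,
    ocular_flags: pd.Series,
    min_a: int = 0,
    ic_variant: str = "noren",
) -> pd.DataFrame:
    """Per-drug signal metrics over the deduplicated report universe.

    ``drug_of_report``: the PS drug's INN per report (None/NaN =
    unmapped, kept in the universe N but given no drug row).
    ``ocular_flags``: boolean per report. Counting unit is the report —
    one count regardless of how many target PTs it carries.
    """
    drug_of_report = pd.Series(drug_of_report).reset_index(drop=True)
    event = np.asarray(ocular_flags, dtype=bool)
    if len(drug_of_report) != len(event):
        raise ValueError("drug and event vectors span different universes")
    N = len(event)
    n_event = int(event.sum())
    rows = []
    grouped = pd.DataFrame({"inn": drug_of_report, "event": event}).dropna(subset=["inn"])
    for inn, grp in grouped.groupby("inn", sort=True):
        n_drug = len(grp)
        a = int(grp["event"].sum())
        ct = ContingencyTable(a, n_drug - a, n_event - a, N - n_drug - n_event + a)
        if a < min_a:
            continue
        m = compute_metrics(ct, name=str(inn), level="drug", ic_variant=ic_variant)
        rows.append(m)
    return metrics_frame(rows)


def pair_level_analysis(
    drug_of_report: pd.Series,
    report_pts: pd.DataFrame,
    min_a: int = 1,
    ic_variant: str = "noren",
) -> pd.DataFrame:
    """Per (drug, PT) signal metrics.

    ``report_pts`` holds one row per (primaryid, pt) over the universe
    index of ``drug_of_report`` (indexed by primaryid). The event margin
    of a PT counts every report carrying it, whatever the drug.
    """
    N = len(drug_of_report)
    pid_to_inn = drug_of_report
    pts = report_pts.drop_duplicates(["primaryid", "pt"])
    pts = pts[pts["primaryid"].isin(pid_to_inn.index)]
    rows = []
    pt_counts = pts.groupby("pt")["primaryid"].nunique()
    drug_counts = pid_to_inn.dropna().value_counts()
    with_inn = pts.assign(inn=pts["primaryid"].map(pid_to_inn)).dropna(subset=["inn"])
    for (inn, pt), grp in with_inn.groupby(["inn", "pt"], sort=True):
        a = grp["primaryid"].nunique()
        if a < min_a:
            continue
        n_drug = int(drug_counts[inn])
        n_event = int(pt_counts[pt])
        ct = ContingencyTable(a, n_drug - a, n_event - a, N - n_drug - n_event + a)
        rows.append(compute_metrics(ct, name=str(inn), level="drug_pt",
                                    event=str(pt), ic_variant=ic_variant))
    return metrics_frame(rows)


def atc_class_analysis(
    mentions: pd.DataFrame,
    drug_of_report: pd.Series,
    ocular_flags: pd.Series,
    ic_variant: str = "noren",
) -> pd.DataFrame:
    """Per ATC level-1 class signal metrics with repeated counting.

    A report whose PS drug carries codes in k classes contributes its
    count to each of the k class tallies (so class counts sum to more
    than the number of distinct reports).
    """
    event = np.asarray(ocular_flags, dtype=bool)
    N = len(event)
    n_event = int(event.sum())
    # level-1 classes per INN
    inn_classes: dict[str, set[str]] = {}
    for inn, lv1 in zip(mentions["inn"], mentions["atc_level1"]):
        if inn is not None and isinstance(lv1, (set, frozenset)) and lv1:
            inn_classes.setdefault(inn, set()).update(lv1)
    ev = pd.Series(event, index=drug_of_report.index)
    rows = []
    all_classes = sorted(set().union(*inn_classes.values())) if inn_classes else []
    for cls in all_classes:
        in_cls = drug_of_report.map(
            lambda i: i is not None and i == i and cls in inn_classes.get(i, ())
        ).astype(bool)
        n_drug = int(in_cls.sum())
        a = int((in_cls & ev).sum())
        ct = ContingencyTable(a, n_drug - a, n_event - a, N - n_drug - n_event + a)
        rows.append(compute_metrics(ct, name=cls, level="atc_class",
                                    ic_variant=ic_variant))
    return metrics_frame(rows)


def metrics_frame(rows: list[SignalMetrics]) -> pd.DataFrame:
    """Signal metrics as a tidy frame, sorted by report count."""
    cols = ["name", "event", "level", "a", "ror", "ror_lo", "ror_hi",
            "prr", "prr_lo", "prr_hi", "ic", "ic025", "ebgm", "ebgm05", "is_signal"]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame([{c: getattr(m, c) for c in cols} for m in rows])
    return df.sort_values(["a", "name"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals for presentation outputs."""
    import decimal

    if x != x or not math.isfinite(x):
        return x
    return float(
        decimal.Decimal(repr(x)).quantize(decimal.Decimal("0.01"),
                                          rounding=decimal.ROUND_HALF_UP)
    )
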