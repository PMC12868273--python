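"""Time-to-onset (TTO) analysis with Weibull failure typing.

TTO is the interval in whole days from the suspect drug's therapy start
(earliest valid START_DT among its THER rows) to adverse-event onset
(EVENT_DT). Reports with missing or malformed dates, or with onset before
start, are excluded with a recorded reason. Same-day onset (TTO = 0) is a
real, retained observation — many topical ocular products act within
hours.

Onset-time distributions are modelled as Weibull(scale alpha, shape
beta). The shape parameter determines the hazard profile over time and
hence the *failure type* of the drug–event pair:

* early failure — beta's 95% CI entirely below 1 (decreasing hazard);
* random failure — CI includes 1 (roughly constant hazard);
* wear-out failure — CI entirely above 1 (increasing hazard).

The boundary is conventional: an upper limit of exactly 1.00 counts as
"includes 1", i.e. random failure.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from pvfaers.cleaning import parse_date

logger = logging.getLogger(__name__)

EXCLUSION_REASONS = ("missing_event", "missing_start", "negative", "malformed")

#: Closed integer day-bands used in descriptive TTO tables.
TTO_BANDS: tuple[tuple[str, int, float], ...] = (
    ("0-30d", 0, 30),
    ("31-60d", 31, 60),
    ("61-90d", 61, 90),
    ("91-120d", 91, 120),
    ("121-150d", 121, 150),
    ("151-180d", 151, 180),
    ("181-360d", 181, 360),
    ("360d<", 361, math.inf),
)


@dataclass
class TTOSample:
    """Valid onset intervals for one drug plus exclusion bookkeeping."""

    drug: str
    tto_days: np.ndarray
    n_excluded: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        self.tto_days = np.asarray(self.tto_days, dtype=float)
        if len(self.tto_days) and self.tto_days.min() < 0:
            raise ValueError("tto_days must be non-negative")

    @property
    def n_valid(self) -> int:
        return len(self.tto_days)

    @property
    def n_total(self) -> int:
        return self.n_valid + sum(self.n_excluded.values())


@dataclass
class WeibullFit:
    """Maximum-likelihood Weibull fit with failure classification.

    ``alpha`` is the scale in days, ``beta`` the shape; the 95% CI for
    beta is a Wald interval on ln(beta) from the observed information,
    exponentiated (so bounds are always positive).
    """

    drug: str
    n_cases: int
    alpha: float = math.nan
    beta: float = math.nan
    beta_lo: float = math.nan
    beta_hi: float = math.nan
    alpha_lo: float = math.nan
    alpha_hi: float = math.nan
    failure_type: str | None = None
    converged: bool = False
    zero_handling: str = "replace_0.5"

    def summary(self) -> str:
        if not self.converged:
            return f"{self.drug}: fit not available (n={self.n_cases})"
        return (
            f"{self.drug}: n={self.n_cases}, alpha={self.alpha:.2f} d "
            f"({self.alpha_lo:.2f}-{self.alpha_hi:.2f}), "
            f"beta={self.beta:.2f} ({self.beta_lo:.2f}-{self.beta_hi:.2f}) "
            f"-> {self.failure_type} failure"
        )


def compute_tto(
    event_dt: str | _dt.date | None,
    start_dts: list[str | _dt.date | None],
) -> tuple[int | None, str | None]:
    """One report's TTO in whole days, or ``(None, reason)``.

    Start is the earliest valid START_DT among the PS drug's therapy
    rows. Reasons: ``missing_event`` / ``missing_start`` (blank),
    ``malformed`` (present but unparseable, e.g. partial dates),
    ``negative`` (onset before start). Exclusion is a value, never an
    exception.
    """
    def _as_date(v) -> tuple[_dt.date | None, bool]:
        # returns (date, was_present)
        if isinstance(v, _dt.date):
            return v, True
        s = "" if v is None else str(v).strip()
        if not s:
            return None, False
        return parse_date(s), True

    ev, ev_present = _as_date(event_dt)
    if not ev_present:
        return None, "missing_event"
    if ev is None:
        return None, "malformed"

    starts: list[_dt.date] = []
    any_present = False
    for s in start_dts:
        d, present = _as_date(s)
        any_present = any_present or present
        if d is not None:
            starts.append(d)
    if not starts:
        return None, ("malformed" if any_present else "missing_start")
    tto = (ev - min(starts)).days
    if tto < 0:
        return None, "negative"
    return tto, None


def build_tto_sample(
    drug: str,
    event_dts: list,
    start_dt_lists: list[list],
) -> TTOSample:
    """Assemble a drug's TTOSample from per-report date inputs."""
    vals: list[int] = []
    excl: Counter = Counter()
    for ev, starts in zip(event_dts, start_dt_lists):
        t, reason = compute_tto(ev, starts)
        if t is None:
            excl[reason] += 1
        else:
            vals.append(t)
    return TTOSample(drug=drug, tto_days=np.array(vals, dtype=float), n_excluded=excl)


def tto_summary(sample: TTOSample | np.ndarray) -> dict:
    """Descriptive summary: moments, quartiles, and day-band counts.

    Quartiles use linear interpolation between order statistics (the
    numpy default, "type 7"); bands are the closed integer intervals of
    :data:`TTO_BANDS`. An empty sample yields an all-missing summary.
    """
    if isinstance(sample, TTOSample):
        x = sample.tto_days
        n_missing = sum(sample.n_excluded.values())
    else:
        x = np.asarray(sample, dtype=float)
        n_missing = 0
    out: dict = {"n": int(len(x)), "n_missing": int(n_missing)}
    if len(x) == 0:
        out.update({k: math.nan for k in ("mean", "sd", "median", "q1", "q3", "min", "max")})
        out["bands"] = {label: 0 for label, *_ in TTO_BANDS}
        return out
    out["mean"] = float(np.mean(x))
    out["sd"] = float(np.std(x, ddof=1)) if len(x) > 1 else math.nan
    out["median"] = float(np.percentile(x, 50))
    out["q1"] = float(np.percentile(x, 25))
    out["q3"] = float(np.percentile(x, 75))
    out["min"] = float(np.min(x))
    out["max"] = float(np.max(x))
    out["bands"] = {
        label: int(np.sum((x >= lo) & (x <= hi))) for label, lo, hi in TTO_BANDS
    }
    return out


def _weibull_negloglik(params: np.ndarray, x: np.ndarray) -> float:
    la, lb = params
    beta = math.exp(lb)
    lx = np.log(x)
    z = np.exp(beta * (lx - la))
    return -float(len(x) * lb - len(x) * beta * la + (beta - 1) * lx.sum() - z.sum())


def fit_weibull(
    sample: TTOSample | np.ndarray,
    min_n: int = 30,
    zero_replacement: float = 0.5,
    drop_zeros: bool = False,
) -> WeibullFit:
    """Weibull MLE on a drug's TTO sample.

    Zero-day onsets are replaced by ``zero_replacement`` (default half a
    day) because the Weibull density is singular at 0 for beta < 1;
    alternatively ``drop_zeros`` removes them. The fit maximises the
    log-likelihood over (ln alpha, ln beta); 95% CIs come from the
    observed information (Wald on the log scale, exponentiated).
    Degenerate samples (zero spread) or fewer than ``min_n`` valid
    values yield a flagged, unclassified fit.
    """
    if isinstance(sample, TTOSample):
        drug, x = sample.drug, sample.tto_days
    else:
        drug, x = "", np.asarray(sample, dtype=float)
    n = len(x)
    fit = WeibullFit(drug=drug, n_cases=n,
                     zero_handling="drop" if drop_zeros else f"replace_{zero_replacement}")
    if n < min_n:
        logger.info("fit_weibull(%s): n=%d below floor %d", drug, n, min_n)
        return fit
    x = x[x > 0] if drop_zeros else np.where(x <= 0, zero_replacement, x)
    fit.n_cases = len(x)
    if len(x) < min_n or np.ptp(x) == 0:
        return fit

    lx = np.log(x)
    b0 = math.pi / math.sqrt(6) / max(np.std(lx), 1e-3)
    a0 = float(np.mean(lx)) + 0.5772 / b0
    res = optimize.minimize(
        _weibull_negloglik, np.array([a0, math.log(b0)]), args=(x,),
        method="BFGS", options={"gtol": 1e-8, "maxiter": 500},
    )
    la, lb = res.x
    # observed information via central differences on the log-scale params
    h = 1e-4
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            e_i = np.eye(2)[i] * h
            e_j = np.eye(2)[j] * h
            H[i, j] = (
                _weibull_negloglik(res.x + e_i + e_j, x)
                - _weibull_negloglik(res.x + e_i - e_j, x)
                - _weibull_negloglik(res.x - e_i + e_j, x)
                + _weibull_negloglik(res.x - e_i - e_j, x)
            ) / (4 * h * h)
    try:
        cov = np.linalg.inv(H)
        se_la, se_lb = math.sqrt(max(cov[0, 0], 0)), math.sqrt(max(cov[1, 1], 0))
    except np.linalg.LinAlgError:
        logger.warning("fit_weibull(%s): singular information matrix", drug)
        return fit
    if not (np.isfinite([la, lb, se_la, se_lb]).all() and se_lb > 0):
        return fit

    z = 1.959963984540054
    fit.alpha = math.exp(la)
    fit.beta = math.exp(lb)
    fit.alpha_lo = math.exp(la - z * se_la)
    fit.alpha_hi = math.exp(la + z * se_la)
    fit.beta_lo = math.exp(lb - z * se_lb)
    fit.beta_hi = math.exp(lb + z * se_lb)
    fit.converged = True
    fit.failure_type = classify_failure(fit.beta, fit.beta_lo, fit.beta_hi)
    return fit


def classify_failure(beta: float, beta_lo: float, beta_hi: float) -> str:
    """Failure type from the shape parameter's 95% CI.

    ``early`` iff the CI lies entirely below 1 (hi < 1); ``wear_out``
    iff entirely above (lo > 1); ``random`` otherwise — including an
    endpoint exactly at 1. Exactly one label for every valid interval.
    """
    if not all(math.isfinite(v) for v in (beta, beta_lo, beta_hi)):
        raise ValueError("classify_failure requires a valid fit")
    if beta_hi < 1:
        return "early"
    if beta_lo > 1:
        return "wear_out"
    return "random"


def fits_frame(fits: list[WeibullFit], summaries: dict[str, dict] | None = None) -> pd.DataFrame:
    """Tidy frame of Weibull fits (one row per drug)."""
    rows = []
    for f in fits:
        s = (summaries or {}).get(f.drug, {})
        rows.append(
            {
                "drug": f.drug,
                "n": f.n_cases,
                "median": s.get("median", math.nan),
                "q1": s.get("q1", math.nan),
                "q3": s.get("q3", math.nan),
                "alpha": f.alpha,
                "beta": f.beta,
                "beta_lo": f.beta_lo,
                "beta_hi": f.beta_hi,
                "failure_type": f.failure_type or "",
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows, columns=["drug", "n", "median", "q1", "q3", "alpha",
                                       "beta", "beta_lo", "beta_hi", "failure_type",
                                       "converged"])
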