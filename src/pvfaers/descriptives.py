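"""Descriptive tabulation of the ocular-injury case series.

Produces the standard pharmacovigilance characteristics table: sex, age
bands, report year, reporter type, country, serious outcomes and
time-to-onset bands, each as count and percentage of the unique-patient
denominator. Percentages are rounded half-up to two decimals at
presentation; outcome sections are multi-select (a case with
hospitalisation and disability increments both rows, so outcome counts
may legitimately exceed the denominator).
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pvfaers.cleaning import AGE_BANDS, OUTCOME_CODES, OUTCOME_LABELS
from pvfaers.tto import TTO_BANDS

#: Outcome codes counted as "serious" by default. The share of serious
#: reports depends on this set; OT ("Other") is excluded by default but
#: the set is caller-configurable.
DEFAULT_SERIOUS_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI"})

SUMMARY_COLUMNS = ["section", "label", "count", "percent"]


def percent(count: int, denominator: int) -> float:
    """100*count/denominator, rounded half-up to 2 decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    frac = decimal.Decimal(count) * 100 / decimal.Decimal(denominator)
    return float(frac.quantize(decimal.Decimal("0.01"),
                               rounding=decimal.ROUND_HALF_UP))


def _section(section: str, counts: dict, denom: int) -> list[dict]:
    return [
        {"section": section, "label": str(k), "count": int(v),
         "percent": percent(int(v), denom)}
        for k, v in counts.items()
    ]


def summarize_cases(
    cases: pd.DataFrame,
    denominator: int | None = None,
    tto_days: pd.Series | None = None,
    serious_codes: frozenset[str] = DEFAULT_SERIOUS_CODES,
) -> pd.DataFrame:
    """Characteristics table over a deduplicated case series.

    ``denominator`` defaults to the number of cases (unique patients
    after deduplication) and is the base of every percentage, including
    the multi-select outcome section. ``tto_days`` (float days, NaN =
    missing/excluded) adds the TTO band section.
    """
    denom = denominator if denominator is not None else len(cases)
    if denom <= 0:
        raise ValueError("summarize_cases needs a positive denominator")
    rows: list[dict] = []

    sex = cases["sex"].value_counts()
    rows += _section("Gender", {k: sex.get(k, 0) for k in ("F", "M", "unspecified")}, denom)

    band = cases["age_band"].value_counts()
    rows += _section("Age", {k: band.get(k, 0) for k in AGE_BANDS}, denom)

    years = cases["report_year"].dropna().astype(int).value_counts().sort_index()
    rows += _section("Report year", years.to_dict(), denom)

    rep = cases["reporter"].value_counts().sort_index()
    rows += _section("Reporter", rep.to_dict(), denom)

    if "country" in cases.columns:
        top = cases["country"].replace("", "unspecified").value_counts()
        rows += _section("Country", top.head(10).to_dict(), denom)

    rows += outcome_rows(cases, denom, serious_codes)

    if tto_days is not None:
        x = np.asarray(tto_days, dtype=float)
        valid = x[~np.isnan(x)]
        bands = {
            label: int(np.sum((valid >= lo) & (valid <= hi)))
            for label, lo, hi in TTO_BANDS
        }
        bands["missing"] = int(np.isnan(x).sum())
        rows += _section("Time-to-Onset", bands, denom)

    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def outcome_rows(cases: pd.DataFrame, denom: int,
                 serious_codes: frozenset[str]) -> list[dict]:
    counts = {code: 0 for code in OUTCOME_CODES}
    n_serious = 0
    for oset in cases["outcomes"]:
        oset = oset or frozenset()
        for code in oset:
            if code in counts:
                counts[code] += 1
        if oset & serious_codes:
            n_serious += 1
    rows = _section("Outcome", {OUTCOME_LABELS[c]: n for c, n in counts.items()}, denom)
    rows.append({"section": "Outcome", "label": "Serious (any)",
                 "count": n_serious, "percent": percent(n_serious, denom)})
    return rows


def outcome_summary(
    cases: pd.DataFrame,
    denominator: int | None = None,
    serious_codes: frozenset[str] = DEFAULT_SERIOUS_CODES,
) -> tuple[pd.DataFrame, float]:
    """Per-outcome-code counts plus the share of serious cases.

    Returns ``(rows, serious_share_percent)``. Which codes define
    "serious" is configurable: published serious shares are often not
    reconstructible from per-code rows alone, so the choice must be
    explicit.
    """
    denom = denominator if denominator is not None else len(cases)
    rows = outcome_rows(cases, denom, serious_codes)
    serious = next(r for r in rows if r["label"] == "Serious (any)")
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS), serious["percent"]


def render_markdown(summary: pd.DataFrame) -> str:
    """Render a summary frame as a GitHub-style Markdown table."""
    lines = ["| Section | Label | Count | % |", "|---|---|---:|---:|"]
    for r in summary.itertuples(index=False):
        lines.append(f"| {r.section} | {r.label} | {r.count:,} | {r.percent:.2f} |")
    return "\n".join(lines)


@dataclass
class ReferenceCohort:
    """Published summary tabulation of a FAERS ocular-injury cohort.

    Bundled reference counts (2004Q1–2024Q4 cohort: 832,314 patients,
    1,242,518 reports) used to exercise the percentage and accounting
    code paths against printed values.
    """

    counts: pd.DataFrame

    @classmethod
    def bundled(cls) -> "ReferenceCohort":
        from importlib import resources

        path = resources.files("pvfaers.data") / "reference_cohort_counts.csv"
        with path.open("r", encoding="utf-8") as fh:
            df = pd.read_csv(fh)
        return cls(counts=df)

    def count(self, section: str, label: str) -> int:
        sel = self.counts[(self.counts["section"] == section)
                          & (self.counts["label"] == label)]
        if len(sel) != 1:
            raise KeyError(f"no unique reference count for {section}/{label}")
        return int(sel["count"].iloc[0])

    @property
    def n_patients(self) -> int:
        return self.count("Totals", "patients")

    def share(self, section: str, label: str) -> float:
        """Percentage of a reference count against the patient denominator."""
        return percent(self.count(section, label), self.n_patients)
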