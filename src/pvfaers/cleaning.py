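"""FDA-style case deduplication, deletion lists, and date/age parsing.

FAERS cases are versioned: a CASEID may appear with several PRIMARYIDs as
follow-up reports arrive. Per FDA guidance the analysis keeps, for each
CASEID, the version with the most recent FDA_DT, breaking FDA_DT ties by
the largest PRIMARYID. Quarterly deleted-case lists (distributed from
2019Q1 onward) are applied after deduplication; a deleted case is removed
globally, whichever quarter it arrived in.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "HO": "Hospitalization - initial or prolonged",
    "DS": "Disability",
    "CA": "Congenital Anomaly",
    "RI": "Required intervention to prevent permanent Impairment/Damage",
    "OT": "Other",
}

REPORTER_CODES = {
    "CN": "consumer",
    "LW": "lawyer",
    "MD": "physician",
    "PH": "pharmacist",
    "HP": "other-health-professional",
    "OT": "other-health-professional",
}

AGE_BANDS = ("<18", "18-44", "45-64", ">=65", "unspecified")

#: Conversion of AGE_COD units to years.
_AGE_FACTORS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}


@dataclass
class DedupAccounting:
    """Row bookkeeping of a deduplication pass.

    The accounting identity ``rows_in - duplicates_removed == rows_out``
    holds by construction; ``rows_out`` is the number of unique retained
    reports (one per patient case).
    """

    rows_in: int
    duplicates_removed: int
    quarantined: int = 0

    @property
    def rows_out(self) -> int:
        return self.rows_in - self.duplicates_removed - self.quarantined


@dataclass
class CleaningReport:
    dedup: DedupAccounting | None = None
    deletions_applied: int = 0
    notes: list[str] = field(default_factory=list)


def _order_key(s: pd.Series) -> pd.Series:
    """Total ordering key for FAERS identifiers and dates.

    Numeric strings compare numerically; anything else falls back to
    lexicographic comparison after left-padding, which coincides with
    numeric order on all-digit values.
    """
    stripped = s.fillna("").astype(str).str.strip()
    if stripped.empty:
        return stripped
    width = int(stripped.str.len().max() or 1)
    return stripped.str.rjust(width, "0")


def deduplicate(demo_rows: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, DedupAccounting]:
    """Keep one DEMO row per CASEID: max FDA_DT, ties by max PRIMARYID.

    Returns ``(kept, quarantined, accounting)``. Rows with a missing
    CASEID are quarantined, not silently dropped. Output is sorted by
    (CASEID, FDA_DT, PRIMARYID) under the numeric-aware ordering, so the
    result is deterministic for any input order.
    """
    for col in ("primaryid", "caseid", "fda_dt"):
        if col not in demo_rows.columns:
            raise KeyError(f"deduplicate requires column {col!r}")
    rows_in = len(demo_rows)
    caseid = demo_rows["caseid"].fillna("").astype(str).str.strip()
    bad = caseid == ""
    quarantined = demo_rows.loc[bad]
    work = demo_rows.loc[~bad].copy()
    work["_k_case"] = _order_key(work["caseid"])
    work["_k_fda"] = _order_key(work["fda_dt"])
    work["_k_pid"] = _order_key(work["primaryid"])
    work = work.sort_values(["_k_case", "_k_fda", "_k_pid"], kind="mergesort")
    kept = work.groupby("_k_case", sort=False).tail(1)
    kept = kept.drop(columns=["_k_case", "_k_fda", "_k_pid"])
    acc = DedupAccounting(
        rows_in=rows_in,
        duplicates_removed=len(work) - len(kept),
        quarantined=int(bad.sum()),
    )
    logger.info("deduplicate: %d in, %d duplicates removed, %d quarantined, %d kept",
                acc.rows_in, acc.duplicates_removed, acc.quarantined, len(kept))
    return kept.reset_index(drop=True), quarantined.reset_index(drop=True), acc


def apply_deletions(rows: pd.DataFrame, deleted_caseids: Iterable[str]) -> pd.DataFrame:
    """Drop rows whose CASEID is on a deletion list (applied post-dedup)."""
    deleted = {str(c).strip() for c in deleted_caseids}
    if not deleted or rows.empty:
        return rows.copy()
    mask = rows["caseid"].astype(str).str.strip().isin(deleted)
    removed = int(mask.sum())
    unknown = len(deleted) - rows.loc[mask, "caseid"].astype(str).str.strip().nunique()
    logger.info("apply_deletions: removed %d rows (%d listed caseids not present)",
                removed, max(unknown, 0))
    return rows.loc[~mask].reset_index(drop=True)


def parse_date(raw: str | None) -> _dt.date | None:
    """Parse an 8-digit FAERS date; partial or invalid dates are missing.

    Only exactly-8-digit strings forming a valid calendar date parse;
    empty strings, 4/6-digit partials (``2023``, ``202301``) and
    impossible dates (``20231340``) map to ``None`` by contract.
    """
    if raw is None:
        return None
    s = str(raw).strip()
    if len(s) != 8 or not s.isdigit():
        return None
    try:
        return _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    except ValueError:
        return None


def parse_date_series(raw: pd.Series) -> pd.Series:
    """Vectorised :func:`parse_date` → datetime64 series (NaT = missing)."""
    s = raw.fillna("").astype(str).str.strip()
    ok = s.str.fullmatch(r"\d{8}")
    out = pd.to_datetime(s.where(ok, None), format="%Y%m%d", errors="coerce")
    return out


def age_to_years(age_value: str | None, age_code: str | None = "YR") -> float | None:
    """Convert a FAERS (AGE, AGE_COD) pair to years.

    A missing code with a numeric value is read as years. Non-numeric or
    negative values are missing. Implausibly large ages are retained —
    the reporting stream genuinely contains them and no plausibility
    filter is applied.
    """
    if age_value is None:
        return None
    s = str(age_value).strip()
    if not s:
        return None
    try:
        v = float(s)
    except ValueError:
        return None
    if v < 0:
        return None
    code = (age_code or "YR").strip().upper() or "YR"
    if code not in _AGE_FACTORS:
        logger.warning("age_to_years: unknown AGE_COD %r -> missing", code)
        return None
    return v * _AGE_FACTORS[code]


def age_band(age_years: float | None) -> str:
    """Half-open age bands [0,18), [18,45), [45,65), [65, inf)."""
    if age_years is None or age_years != age_years:
        return "unspecified"
    if age_years < 18:
        return "<18"
    if age_years < 45:
        return "18-44"
    if age_years < 65:
        return "45-64"
    return ">=65"


def _normalize_sex(s: pd.Series) -> pd.Series:
    up = s.fillna("").astype(str).str.strip().str.upper()
    return up.where(up.isin(["F", "M"]), "unspecified")


def _normalize_reporter(s: pd.Series) -> pd.Series:
    up = s.fillna("").astype(str).str.strip().str.upper()
    return up.map(REPORTER_CODES).fillna("unspecified")


def build_case_table(
    demo_rows: pd.DataFrame,
    outc_rows: pd.DataFrame | None = None,
    deleted_caseids: Iterable[str] = (),
    country_field: str = "occr_country",
) -> tuple[pd.DataFrame, CleaningReport]:
    """Deduplicate DEMO, apply deletions, and derive analysis columns.

    Returns a case table with one row per retained case: ``primaryid``,
    ``caseid``, ``fda_dt``, ``event_dt`` (verbatim), ``sex``,
    ``age_years``, ``age_band``, ``reporter``, ``country``, ``outcomes``
    (frozenset of OUTC codes) and ``report_year`` (from the retained
    version's FDA_DT). ``country_field`` selects occurrence
    (``occr_country``, default) or reporter country.
    """
    report = CleaningReport()
    kept, _quar, acc = deduplicate(demo_rows)
    report.dedup = acc
    n_before = len(kept)
    kept = apply_deletions(kept, deleted_caseids)
    report.deletions_applied = n_before - len(kept)

    cases = pd.DataFrame(
        {
            "primaryid": kept["primaryid"].astype(str).str.strip(),
            "caseid": kept["caseid"].astype(str).str.strip(),
            "fda_dt": kept["fda_dt"].fillna("").astype(str).str.strip(),
            "event_dt": kept.get("event_dt", pd.Series("", index=kept.index))
            .fillna("").astype(str).str.strip(),
            "sex": _normalize_sex(kept.get("sex", pd.Series("", index=kept.index))),
            "reporter": _normalize_reporter(
                kept.get("occp_cod", pd.Series("", index=kept.index))
            ),
        }
    )
    country = kept.get(country_field, pd.Series("", index=kept.index))
    cases["country"] = country.fillna("").astype(str).str.strip()

    ages = [
        age_to_years(v, c)
        for v, c in zip(
            kept.get("age", pd.Series("", index=kept.index)),
            kept.get("age_cod", pd.Series("YR", index=kept.index)),
        )
    ]
    cases["age_years"] = pd.array([a if a is not None else np.nan for a in ages], dtype=float)
    cases["age_band"] = [age_band(a) for a in ages]

    fda = parse_date_series(cases["fda_dt"])
    cases["report_year"] = fda.dt.year.astype("Int64")

    # OUTC rows are versioned too: join on the retained PRIMARYID only.
    outcome_sets: dict[str, set[str]] = {}
    if outc_rows is not None and len(outc_rows):
        oc = outc_rows.copy()
        oc["primaryid"] = oc["primaryid"].astype(str).str.strip()
        oc["outc_cod"] = oc["outc_cod"].fillna("").astype(str).str.strip().str.upper()
        oc = oc[oc["outc_cod"].isin(OUTCOME_CODES)]
        for pid, grp in oc.groupby("primaryid")["outc_cod"]:
            outcome_sets[pid] = set(grp)
    cases["outcomes"] = [
        frozenset(outcome_sets.get(pid, ())) for pid in cases["primaryid"]
    ]
    return cases.reset_index(drop=True), report
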