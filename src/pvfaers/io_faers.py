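"""Reading and writing FAERS Quarterly Data Extract ASCII tables.

The FDA distributes FAERS as ``$``-delimited text files, one per table
(DEMO, DRUG, REAC, OUTC, THER, INDI, RPSR), with a single header line and
no quoting. Quarters from 2019Q1 onward additionally ship a deleted-case
list (one CASEID per line). All fields are kept verbatim as text — type
coercion happens downstream in :mod:`pvfaers.cleaning`.

The raw FDA dialect has no escaping; to make round-trips total this module
additionally understands backslash-escaped delimiters (``\\$``) on read and
emits them on write, so fields containing the delimiter survive unchanged.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: Tables of a FAERS quarterly package, in conventional order.
FAERS_TABLES = ("demo", "drug", "reac", "outc", "ther", "indi", "rpsr")

#: Minimal column sets per table. Extra columns in a file are preserved;
#: these are the ones the pipeline relies on.
DEFAULT_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": (
        "primaryid",
        "caseid",
        "fda_dt",
        "event_dt",
        "age",
        "age_cod",
        "sex",
        "occp_cod",
        "reporter_country",
        "occr_country",
    ),
    "drug": ("primaryid", "caseid", "drug_seq", "role_cod", "drugname"),
    "reac": ("primaryid", "caseid", "pt"),
    "outc": ("primaryid", "caseid", "outc_cod"),
    "ther": ("primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"),
    "indi": ("primaryid", "caseid", "indi_drug_seq", "indi_pt"),
    "rpsr": ("primaryid", "caseid", "rpsr_cod"),
}


class FaersFormatError(ValueError):
    """A file does not conform to the declared FAERS dialect."""


@dataclass(frozen=True)
class FaersDialect:
    """Column layout and delimiter conventions of a FAERS extract era.

    The FDA changed column layouts over the years; users may extend or
    override ``columns`` per table to match a specific era. ``columns``
    lists required columns — files may carry more.
    """

    delimiter: str = "$"
    escape: str = "\\"
    columns: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COLUMNS)
    )

    def with_columns(self, **per_table: tuple[str, ...]) -> "FaersDialect":
        merged = dict(self.columns)
        merged.update({k.lower(): tuple(v) for k, v in per_table.items()})
        return FaersDialect(self.delimiter, self.escape, merged)


@dataclass
class TableReadReport:
    rows_in: int = 0
    rows_kept: int = 0
    rows_skipped: int = 0
    orphans: int = 0


@dataclass
class RawQuarter:
    """One FAERS quarterly package, all fields verbatim text.

    Every non-DEMO table's ``primaryid`` should appear in DEMO; rows that
    do not are *orphans* — retained here, counted in ``report``, and
    excluded from analysis joins downstream.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    rpsr: pd.DataFrame
    quarter_label: str = ""
    deleted_caseids: list[str] = field(default_factory=list)
    report: dict[str, TableReadReport] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name.lower())


def _empty_table(name: str, dialect: FaersDialect) -> pd.DataFrame:
    cols = dialect.columns.get(name, ())
    return pd.DataFrame({c: pd.Series(dtype=str) for c in cols})


def _split_line(line: str, dialect: FaersDialect) -> list[str]:
    delim, esc = dialect.delimiter, dialect.escape
    if esc not in line:
        return line.split(delim)
    fields: list[str] = []
    buf: list[str] = []
    i, n = 0, len(line)
    while i < n:
        ch = line[i]
        if ch == esc and i + 1 < n and line[i + 1] in (delim, esc):
            buf.append(line[i + 1])
            i += 2
        elif ch == delim:
            fields.append("".join(buf))
            buf = []
            i += 1
        else:
            buf.append(ch)
            i += 1
    fields.append("".join(buf))
    return fields


def _escape_field(value: str, dialect: FaersDialect) -> str:
    out = value.replace(dialect.escape, dialect.escape * 2)
    return out.replace(dialect.delimiter, dialect.escape + dialect.delimiter)


def _read_faers_file(path: Path, name: str, dialect: FaersDialect) -> tuple[pd.DataFrame, TableReadReport]:
    report = TableReadReport()
    with open(path, encoding="utf-8", errors="replace") as fh:
        header_line = fh.readline().rstrip("\r\n")
        if dialect.delimiter not in header_line:
            raise FaersFormatError(
                f"{path.name}: header line is not {dialect.delimiter!r}-delimited"
            )
        header = [h.strip().lower() for h in _split_line(header_line, dialect)]
        missing = [c for c in dialect.columns.get(name, ()) if c not in header]
        if missing:
            raise FaersFormatError(f"{path.name}: missing required columns {missing}")
        ncol = len(header)
        rows: list[list[str]] = []
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            report.rows_in += 1
            fields = _split_line(line, dialect)
            if len(fields) != ncol:
                report.rows_skipped += 1
                continue
            rows.append(fields)
        report.rows_kept = len(rows)
    df = pd.DataFrame(rows, columns=header, dtype=str) if rows else pd.DataFrame(
        {c: pd.Series(dtype=str) for c in header}
    )
    return df, report


def _find_table_file(path: Path, name: str) -> Path | None:
    cands = sorted(
        p
        for p in path.iterdir()
        if p.is_file()
        and p.name.lower().startswith(name)
        and p.suffix.lower() in (".txt", "")
        and "delet" not in p.name.lower()
    )
    return cands[0] if cands else None


def read_deleted_caseids(path: Path) -> list[str]:
    """Read a deleted-case list: one CASEID per line, optional header."""
    out: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            tok = line.strip().strip("$")
            if not tok or tok.lower() in ("caseid", "case_id"):
                continue
            out.append(tok)
    return out


def read_quarter(path: str | Path, dialect: FaersDialect | None = None) -> RawQuarter:
    """Read one quarter's directory of FAERS ASCII tables.

    Absent table files yield empty tables; ragged rows are skipped and
    counted in the per-table read report. Fields are kept verbatim.
    """
    dialect = dialect or FaersDialect()
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"not a directory: {path}")

    tables: dict[str, pd.DataFrame] = {}
    reports: dict[str, TableReadReport] = {}
    for name in FAERS_TABLES:
        f = _find_table_file(path, name)
        if f is None:
            tables[name] = _empty_table(name, dialect)
            reports[name] = TableReadReport()
        else:
            tables[name], reports[name] = _read_faers_file(f, name, dialect)
        logger.info(
            "%s/%s: %d rows kept, %d skipped",
            path.name, name.upper(), reports[name].rows_kept, reports[name].rows_skipped,
        )

    deleted: list[str] = []
    for f in sorted(path.iterdir()):
        if f.is_file() and "delet" in f.name.lower():
            deleted.extend(read_deleted_caseids(f))

    demo_ids = set(tables["demo"].get("primaryid", pd.Series(dtype=str)))
    for name in FAERS_TABLES[1:]:
        tab = tables[name]
        if "primaryid" in tab.columns and len(tab):
            reports[name].orphans = int((~tab["primaryid"].isin(demo_ids)).sum())
            if reports[name].orphans:
                logger.info("%s: %d orphan rows (PRIMARYID absent from DEMO)",
                            name.upper(), reports[name].orphans)

    return RawQuarter(
        demo=tables["demo"], drug=tables["drug"], reac=tables["reac"],
        outc=tables["outc"], ther=tables["ther"], indi=tables["indi"],
        rpsr=tables["rpsr"], quarter_label=path.name,
        deleted_caseids=deleted, report=reports,
    )


def write_faers_table(rows: pd.DataFrame, path: str | Path,
                      dialect: FaersDialect | None = None) -> None:
    """Write a table in the FAERS ``$``-delimited dialect (escaped)."""
    dialect = dialect or FaersDialect()
    path = Path(path)
    cols = list(rows.columns)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(dialect.delimiter.join(cols) + "\n")
        for row in rows.itertuples(index=False):
            fh.write(
                dialect.delimiter.join(
                    _escape_field("" if v is None or v != v else str(v), dialect)
                    for v in row
                )
                + "\n"
            )


def write_table(rows: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    """Write an internal output table as RFC-4180-style CSV (UTF-8).

    Column order is the frame's order (deterministic by construction).
    """
    rows.to_csv(path, sep=delimiter, index=False, quoting=csv.QUOTE_MINIMAL,
                encoding="utf-8", lineterminator="\n")


def read_table(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read back a table written by :func:`write_table` (all text)."""
    return pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                       encoding="utf-8")
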