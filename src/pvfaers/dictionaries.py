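"""Drug-name standardisation, ATC annotation, and MedDRA PT→SOC mapping.

Real analyses use the licensed WHO Drug Dictionary and MedDRA; both are
supplied by the user as two-column delimited files. For tests and the
synthetic pipeline the package bundles mock mini-dictionaries (~50 common
ophthalmology-relevant drugs with their ATC codes, ~30 ocular preferred
terms plus non-ocular decoys) under ``pvfaers/data``.

A case is an ocular-injury case iff at least one of its reaction PTs has
the primary System Organ Class "Eye disorders".
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

EYE_SOC = "Eye disorders"

#: Dosage/form tokens stripped from the tail of verbatim drug names.
DEFAULT_SUFFIX_TOKENS = (
    "tab", "tabs", "tablet", "tablets", "cap", "caps", "capsule", "capsules",
    "injection", "inj", "solution", "soln", "cream", "ointment", "drops",
    "oral", "ophthalmic", "topical", "er", "xr", "sr", "hfa",
)

_ATC_RE = re.compile(r"^[A-Z]\d{2}[A-Z0-9]*$")
_DOSE_RE = re.compile(r"^\d+(\.\d+)?(mg|mcg|g|ml|%|iu|u)$")


def _canon(s: str) -> str:
    """Case-fold, trim, and collapse internal whitespace."""
    return " ".join(str(s).casefold().split())


@dataclass
class DictionaryMaps:
    """The three lookup tables of the standardisation step.

    ``name_to_inn``: case-folded verbatim drug string → INN.
    ``inn_to_atc``: INN → non-empty list of ATC codes (a drug may belong
    to several classes). ``pt_to_soc``: MedDRA PT → primary SOC name.
    Combination products are single entities whose INN joins components
    with ``"; "`` (e.g. ``dorzolamide; timolol``).
    """

    name_to_inn: dict[str, str] = field(default_factory=dict)
    inn_to_atc: dict[str, list[str]] = field(default_factory=dict)
    pt_to_soc: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.name_to_inn = {_canon(k): v for k, v in self.name_to_inn.items()}
        self.inn_to_atc = {_canon(k): list(v) for k, v in self.inn_to_atc.items()}
        self.pt_to_soc = {_canon(k): v for k, v in self.pt_to_soc.items()}
        for inn, codes in self.inn_to_atc.items():
            bad = [c for c in codes if not _ATC_RE.match(c)]
            if bad:
                raise ValueError(f"invalid ATC code(s) for {inn!r}: {bad}")

    @classmethod
    def from_files(cls, drug_dict: str | Path, atc_dict: str | Path,
                   meddra: str | Path) -> "DictionaryMaps":
        """Load the three maps from two-column CSVs (key,value).

        The ATC file allows repeated keys (one row per code).
        """
        name_to_inn = dict(_read_pairs(drug_dict))
        inn_to_atc: dict[str, list[str]] = {}
        for inn, code in _read_pairs(atc_dict):
            inn_to_atc.setdefault(_canon(inn), []).append(code.strip().upper())
        pt_to_soc = dict(_read_pairs(meddra))
        return cls(name_to_inn=name_to_inn, inn_to_atc=inn_to_atc, pt_to_soc=pt_to_soc)

    @classmethod
    def bundled(cls) -> "DictionaryMaps":
        """The mock mini-dictionaries shipped with the package."""
        pkg = resources.files("pvfaers.data")
        return cls.from_files(
            pkg / "mock_drug_inn.csv",
            pkg / "mock_inn_atc.csv",
            pkg / "mock_pt_soc.csv",
        )

    def merged_with(self, other: "DictionaryMaps") -> "DictionaryMaps":
        return DictionaryMaps(
            name_to_inn={**self.name_to_inn, **other.name_to_inn},
            inn_to_atc={**self.inn_to_atc, **other.inn_to_atc},
            pt_to_soc={**self.pt_to_soc, **other.pt_to_soc},
        )


def _read_pairs(path: str | Path) -> list[tuple[str, str]]:
    pairs = []
    with (path.open("r", encoding="utf-8") if hasattr(path, "open")
          else open(path, encoding="utf-8")) as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row or (i == 0 and row[0].strip().lower() in ("key", "verbatim", "inn", "pt")):
                continue
            if len(row) < 2:
                continue
            pairs.append((row[0].strip(), row[1].strip()))
    return pairs


def _strip_suffix_tokens(name: str, suffixes: tuple[str, ...]) -> str:
    toks = name.split()
    while len(toks) > 1 and (toks[-1] in suffixes or _DOSE_RE.match(toks[-1])):
        toks.pop()
    return " ".join(toks)


def normalize_drug(verbatim: str, maps: DictionaryMaps,
                   suffixes: tuple[str, ...] = DEFAULT_SUFFIX_TOKENS) -> str | None:
    """Map a verbatim drug string to its INN; ``None`` when unmapped.

    Normalisation: case-fold, trim, collapse whitespace, then repeatedly
    strip trailing dosage/form tokens; lookup is exact on the normalised
    string (tried before and after suffix stripping). Unmapped reports
    stay in the database denominator but are excluded from drug-level
    statistics.
    """
    key = _canon(verbatim)
    if key in maps.name_to_inn:
        return maps.name_to_inn[key]
    stripped = _strip_suffix_tokens(key, suffixes)
    return maps.name_to_inn.get(stripped)


def map_pt_to_soc(pt: str, maps: DictionaryMaps) -> str | None:
    """Primary SOC for a MedDRA PT (case-insensitive); None if unmapped."""
    soc = maps.pt_to_soc.get(_canon(pt))
    if soc is None:
        logger.debug("unmapped PT: %r", pt)
    return soc


def assign_atc(inn: str, maps: DictionaryMaps) -> tuple[list[str], set[str]]:
    """All ATC codes of an INN and the derived set of level-1 letters.

    A drug belonging to k level-1 classes is tallied in each of the k
    classes downstream (repeated counting across classifications).
    """
    codes = maps.inn_to_atc.get(_canon(inn), [])
    if not codes:
        logger.debug("no ATC codes for INN %r", inn)
    return list(codes), {c[0] for c in codes}


def select_ocular_cases(
    reac_rows: pd.DataFrame, maps: DictionaryMaps, soc: str = EYE_SOC
) -> tuple[set[str], pd.DataFrame]:
    """Report IDs with ≥1 PT mapping to the target primary SOC.

    Returns ``(primaryids, pairs)`` where ``pairs`` has one row per
    (report, matching PT) — a case with three ocular PTs is selected once
    but contributes three case–PT pairs.
    """
    if reac_rows.empty:
        return set(), pd.DataFrame(columns=["primaryid", "pt"])
    df = pd.DataFrame(
        {
            "primaryid": reac_rows["primaryid"].astype(str).str.strip(),
            "pt": reac_rows["pt"].fillna("").astype(str).str.strip(),
        }
    )
    socs = df["pt"].map(lambda p: map_pt_to_soc(p, maps))
    n_unmapped = int(socs.isna().sum())
    if n_unmapped:
        logger.info("select_ocular_cases: %d reaction rows with unmapped PT", n_unmapped)
    pairs = df.loc[socs == soc, ["primaryid", "pt"]].drop_duplicates().reset_index(drop=True)
    return set(pairs["primaryid"]), pairs


def annotate_mentions(drug_rows: pd.DataFrame, maps: DictionaryMaps) -> pd.DataFrame:
    """Standardise DRUG rows into drug mentions with INN and ATC.

    Output columns: primaryid, drug_seq, role, verbatim, inn (None when
    unmapped), atc_codes (list), atc_level1 (set of letters).
    """
    if drug_rows.empty:
        return pd.DataFrame(
            columns=["primaryid", "drug_seq", "role", "verbatim", "inn",
                     "atc_codes", "atc_level1"]
        )
    out = pd.DataFrame(
        {
            "primaryid": drug_rows["primaryid"].astype(str).str.strip(),
            "drug_seq": drug_rows.get("drug_seq", pd.Series("", index=drug_rows.index))
            .fillna("").astype(str).str.strip(),
            "role": drug_rows.get("role_cod", pd.Series("", index=drug_rows.index))
            .fillna("").astype(str).str.strip().str.upper(),
            "verbatim": drug_rows["drugname"].fillna("").astype(str),
        }
    )
    # Lookup on unique verbatims only; DRUG tables repeat names heavily.
    uniq = out["verbatim"].unique()
    inn_of = {v: normalize_drug(v, maps) for v in uniq}
    out["inn"] = out["verbatim"].map(inn_of)
    atc_of = {
        inn: assign_atc(inn, maps) for inn in set(inn_of.values()) if inn is not None
    }
    out["atc_codes"] = out["inn"].map(lambda i: atc_of.get(i, ([], set()))[0] if i else [])
    out["atc_level1"] = out["inn"].map(lambda i: atc_of.get(i, ([], set()))[1] if i else set())
    return out
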