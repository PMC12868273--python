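"""Synthetic FAERS-like quarterly data with planted ground truth.

The generator emits the seven quarterly ASCII tables plus deleted-case
lists in the FDA dialect, with the statistical structure the pipeline is
meant to recover:

* one Primary Suspect drug per report, drawn by configured report share;
* planted drug–event structure: P(ocular PT | drug) = background rate x
  the drug's ocular rate ratio;
* per-drug Weibull(alpha, beta) onset times realised as START_DT /
  EVENT_DT pairs, with a configurable fraction of blank or partial dates;
* injected duplicate case versions (same CASEID, later FDA_DT, larger
  PRIMARYID) and deleted-case lists on post-2019 quarters;
* demographics, reporter, country and multi-select outcomes drawn from
  configured marginals.

Everything drawn is recorded in a :class:`SyntheticTruth` so recovery can
be scored exactly. The same seed and config give a byte-identical file
set.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from pvfaers.dictionaries import DictionaryMaps
from pvfaers.io_faers import RawQuarter, TableReadReport, write_faers_table

_ATC_CYCLE = "ABCDGHJLMNPRSV"


class DrugSpec(BaseModel):
    inn: str
    atc_codes: list[str] = Field(default_factory=list)
    report_share: float = Field(gt=0, le=1)
    ocular_rate_ratio: float = Field(default=1.0, gt=0)
    weibull_alpha_days: float = Field(default=180.0, gt=0)
    weibull_beta: float = Field(default=1.0, gt=0)


class SyntheticConfig(BaseModel):
    """Study conditions of a synthetic run (all rates are probabilities)."""

    seed: int = 0
    n_reports: int = 20000
    quarters: list[str] = Field(
        default_factory=lambda: ["2023Q1", "2023Q2", "2023Q3", "2023Q4"]
    )
    drugs: list[DrugSpec] = Field(default_factory=list)
    n_background_drugs: int = 40
    background_ocular_rate: float = Field(default=0.05, gt=0, le=1)
    sex_probs: dict[str, float] = Field(
        default_factory=lambda: {"F": 0.6056, "M": 0.3018, "unspecified": 0.0926}
    )
    age_band_probs: dict[str, float] = Field(
        default_factory=lambda: {"<18": 0.0587, "18-44": 0.2231,
                                 "45-64": 0.3656, ">=65": 0.3526}
    )
    age_missing_rate: float = Field(default=0.3865, ge=0, le=1)
    tto_missing_rate: float = Field(default=0.7365, ge=0, le=1)
    duplicate_rate: float = Field(default=0.2021, ge=0, le=1)
    deletion_rate: float = Field(default=0.002, ge=0, le=1)
    reporter_probs: dict[str, float] = Field(
        default_factory=lambda: {"CN": 0.5004, "LW": 0.0189, "": 0.0467,
                                 "HP": 0.0964, "PH": 0.1155, "MD": 0.2221}
    )
    country_probs: dict[str, float] = Field(
        default_factory=lambda: {"US": 0.6291, "CA": 0.0527, "GB": 0.0437,
                                 "FR": 0.03, "JP": 0.03, "DE": 0.025, "XX": 0.1895}
    )
    outcome_probs: dict[str, float] = Field(
        default_factory=lambda: {"DE": 0.0214, "LT": 0.0249, "HO": 0.1790,
                                 "DS": 0.0510, "CA": 0.0053, "RI": 0.0070,
                                 "OT": 0.5116}
    )
    alias_probability: float = Field(default=0.5, ge=0, le=1)

    @model_validator(mode="after")
    def _check_rates(self) -> "SyntheticConfig":
        total = sum(d.report_share for d in self.drugs)
        if total > 1 + 1e-9:
            raise ValueError(f"drug report shares sum to {total:.3f} > 1")
        for d in self.drugs:
            if self.background_ocular_rate * d.ocular_rate_ratio > 1 + 1e-9:
                raise ValueError(
                    f"{d.inn}: rate ratio {d.ocular_rate_ratio} pushes "
                    f"P(ocular) above 1 at background rate "
                    f"{self.background_ocular_rate}"
                )
        for name in ("sex_probs", "age_band_probs", "reporter_probs", "country_probs"):
            probs = getattr(self, name)
            s = sum(probs.values())
            if not math.isclose(s, 1.0, abs_tol=1e-6):
                raise ValueError(f"{name} must sum to 1 (got {s:.4f})")
        return self

    def all_drugs(self) -> list[DrugSpec]:
        """Configured drugs plus the background pool filling the remainder."""
        rest = 1.0 - sum(d.report_share for d in self.drugs)
        k = self.n_background_drugs
        bg = []
        if rest > 1e-12 and k > 0:
            for i in range(k):
                letter = _ATC_CYCLE[i % len(_ATC_CYCLE)]
                bg.append(
                    DrugSpec(
                        inn=f"backgroundium-{i + 1:02d}",
                        atc_codes=[f"{letter}{90 + i // len(_ATC_CYCLE):02d}AA"],
                        report_share=rest / k,
                        ocular_rate_ratio=1.0,
                        weibull_alpha_days=180.0,
                        weibull_beta=1.0,
                    )
                )
        return list(self.drugs) + bg

    def dictionary_maps(self) -> DictionaryMaps:
        """Bundled mock dictionaries extended with this config's drugs."""
        maps = DictionaryMaps.bundled()
        extra = DictionaryMaps(
            name_to_inn={d.inn: d.inn for d in self.all_drugs()},
            inn_to_atc={d.inn: d.atc_codes for d in self.all_drugs() if d.atc_codes},
            pt_to_soc={},
        )
        return maps.merged_with(extra)


class SyntheticTruth(BaseModel):
    """Planted parameters and bookkeeping sufficient to score recovery."""

    seed: int
    n_reports: int
    n_duplicate_rows: int
    rate_ratio: dict[str, float]
    weibull: dict[str, tuple[float, float]]  # inn -> (alpha, beta)
    report_share: dict[str, float]
    duplicate_caseids: list[str]
    deleted_caseids: list[str]
    expected_marginals: dict[str, dict[str, float]]
    background_ocular_rate: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls.model_validate_json(Path(path).read_text(encoding="utf-8"))


def _quarter_start(label: str) -> _dt.date:
    year, q = int(label[:4]), int(label[-1])
    return _dt.date(year, 3 * (q - 1) + 1, 1)


def _fmt(d: _dt.date) -> str:
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


def _choice(rng: np.random.Generator, items: list[str], probs: list[float], n: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    return rng.choice(np.array(items, dtype=object), size=n, p=p / p.sum())


def generate(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> tuple[list[RawQuarter], SyntheticTruth]:
    """Draw a full synthetic quarterly file set (deterministic per seed).

    Returns the quarters in memory; when ``out_dir`` is given, also
    writes one subdirectory per quarter (FAERS-dialect tables plus
    deletion lists) and ``truth.json``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drugs = config.all_drugs()
    specs = pd.DataFrame(
        {
            "inn": [d.inn for d in drugs],
            "share": [d.report_share for d in drugs],
            "rr": [d.ocular_rate_ratio for d in drugs],
            "alpha": [d.weibull_alpha_days for d in drugs],
            "beta": [d.weibull_beta for d in drugs],
        }
    )

    maps = DictionaryMaps.bundled()
    # uppercase trade alias per INN where the mock dictionary has one
    alias_of: dict[str, str] = {}
    for verbatim, inn in maps.name_to_inn.items():
        if verbatim != inn:
            alias_of.setdefault(inn, verbatim.upper())

    ocular_pts = sorted(pt for pt, soc in maps.pt_to_soc.items() if soc == "Eye disorders")
    decoy_pts = sorted(pt for pt, soc in maps.pt_to_soc.items() if soc != "Eye disorders")
    # Zipf-ish weights mimic the skewed real PT frequency spectrum.
    oc_w = 1.0 / np.arange(1, len(ocular_pts) + 1)
    dc_w = 1.0 / np.arange(1, len(decoy_pts) + 1)

    didx = rng.choice(len(specs), size=n, p=specs["share"].to_numpy() / specs["share"].sum())
    inn = specs["inn"].to_numpy(dtype=object)[didx]
    rr = specs["rr"].to_numpy()[didx]
    alpha = specs["alpha"].to_numpy()[didx]
    beta = specs["beta"].to_numpy()[didx]

    p_ocular = np.clip(config.background_ocular_rate * rr, 0, 1)
    is_ocular = rng.random(n) < p_ocular

    qidx = rng.integers(0, len(config.quarters), size=n)
    qstarts = [_quarter_start(q) for q in config.quarters]
    start_offset = rng.integers(0, 89, size=n)
    tto = np.rint(alpha * rng.weibull(beta, size=n)).astype(int)
    fda_lag = rng.integers(0, 61, size=n)
    tto_missing = rng.random(n) < config.tto_missing_rate
    partial_event = rng.random(n) < 0.3  # among missing: partial year vs blank

    sex = _choice(rng, list(config.sex_probs), list(config.sex_probs.values()), n)
    sex = np.where(sex == "unspecified", "", sex)
    age_missing = rng.random(n) < config.age_missing_rate
    bands = list(config.age_band_probs)
    band_draw = _choice(rng, bands, list(config.age_band_probs.values()), n)
    band_lims = {"<18": (0, 17), "18-44": (18, 44), "45-64": (45, 64), ">=65": (65, 94)}
    age = np.array(
        [rng.integers(band_lims[b][0], band_lims[b][1] + 1) for b in band_draw]
    )
    occp = _choice(rng, list(config.reporter_probs), list(config.reporter_probs.values()), n)
    country = _choice(rng, list(config.country_probs), list(config.country_probs.values()), n)
    out_draws = {c: rng.random(n) < p for c, p in config.outcome_probs.items()}

    use_alias = rng.random(n) < config.alias_probability
    n_decoys_oc = rng.integers(0, 3, size=n)  # 0-2 decoys on ocular reports
    n_pts_nonoc = rng.integers(1, 4, size=n)  # 1-3 decoys otherwise
    oc_pick = rng.choice(len(ocular_pts), size=n, p=oc_w / oc_w.sum())
    # pre-draw a generous pool of decoy picks
    decoy_pool = rng.choice(len(decoy_pts), size=3 * n, p=dc_w / dc_w.sum())

    dup_count = int(round(config.duplicate_rate * n))
    dup_idx = set(rng.choice(n, size=dup_count, replace=False).tolist()) if dup_count else set()
    del_count = int(round(config.deletion_rate * n))
    del_idx = rng.choice(n, size=del_count, replace=False) if del_count else np.array([], dtype=int)

    per_q: dict[str, dict[str, list[list[str]]]] = {
        q: {t: [] for t in ("demo", "drug", "reac", "outc", "ther", "indi", "rpsr")}
        for q in config.quarters
    }
    dup_caseids: list[str] = []
    pool_ptr = 0

    for i in range(n):
        caseid = str(90000000 + i)
        qlabel = config.quarters[qidx[i]]
        start = qstarts[qidx[i]] + _dt.timedelta(days=int(start_offset[i]))
        event = start + _dt.timedelta(days=int(tto[i]))
        fda = event + _dt.timedelta(days=int(fda_lag[i]))
        if tto_missing[i]:
            event_str = f"{event.year:04d}" if partial_event[i] else ""
        else:
            event_str = _fmt(event)
        drug_inn = inn[i]
        verbatim = alias_of.get(drug_inn, drug_inn.upper()) if use_alias[i] else drug_inn.upper()
        pts = []
        if is_ocular[i]:
            pts.append(ocular_pts[oc_pick[i]])
            k = int(n_decoys_oc[i])
        else:
            k = int(n_pts_nonoc[i])
        for _ in range(k):
            pts.append(decoy_pts[decoy_pool[pool_ptr]])
            pool_ptr += 1
        pts = list(dict.fromkeys(pts))
        outs = [c for c in config.outcome_probs if out_draws[c][i]]

        versions = [(caseid + "1", _fmt(fda))]
        if i in dup_idx:
            fda2 = fda + _dt.timedelta(days=int(1 + (i % 30)))
            versions.append((caseid + "2", _fmt(fda2)))
            dup_caseids.append(caseid)
        for pid, fda_str in versions:
            tabs = per_q[qlabel]
            tabs["demo"].append(
                [pid, caseid, fda_str, event_str, str(int(age[i])) if not age_missing[i] else "",
                 "YR" if not age_missing[i] else "", str(sex[i]), str(occp[i]),
                 str(country[i]), str(country[i])]
            )
            tabs["drug"].append([pid, caseid, "1", "PS", verbatim])
            for pt in pts:
                # store PTs with original casing from the mock dictionary
                tabs["reac"].append([pid, caseid, pt.capitalize() if pt[0].islower() else pt])
            for c in outs:
                tabs["outc"].append([pid, caseid, c])
            tabs["ther"].append([pid, caseid, "1", _fmt(start), ""])
            tabs["indi"].append([pid, caseid, "1", "Product used for unknown indication"])
            tabs["rpsr"].append([pid, caseid, "FGN"])

    deleted_caseids = sorted(str(90000000 + int(i)) for i in del_idx)
    # deletion lists ride on post-2019 quarters (or the last quarter if none)
    carriers = [q for q in config.quarters if q >= "2019Q1"] or [config.quarters[-1]]
    del_assign: dict[str, list[str]] = {q: [] for q in config.quarters}
    for j, cid in enumerate(deleted_caseids):
        del_assign[carriers[j % len(carriers)]].append(cid)

    columns = {
        "demo": ["primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
                 "sex", "occp_cod", "reporter_country", "occr_country"],
        "drug": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname"],
        "reac": ["primaryid", "caseid", "pt"],
        "outc": ["primaryid", "caseid", "outc_cod"],
        "ther": ["primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"],
        "indi": ["primaryid", "caseid", "indi_drug_seq", "indi_pt"],
        "rpsr": ["primaryid", "caseid", "rpsr_cod"],
    }
    quarters_out: list[RawQuarter] = []
    for q in config.quarters:
        frames = {
            t: pd.DataFrame(per_q[q][t], columns=columns[t], dtype=str)
            if per_q[q][t] else pd.DataFrame({c: pd.Series(dtype=str) for c in columns[t]})
            for t in columns
        }
        rq = RawQuarter(
            demo=frames["demo"], drug=frames["drug"], reac=frames["reac"],
            outc=frames["outc"], ther=frames["ther"], indi=frames["indi"],
            rpsr=frames["rpsr"], quarter_label=q,
            deleted_caseids=list(del_assign[q]),
            report={t: TableReadReport(rows_in=len(frames[t]), rows_kept=len(frames[t]))
                    for t in columns},
        )
        quarters_out.append(rq)

    truth = SyntheticTruth(
        seed=config.seed,
        n_reports=n,
        n_duplicate_rows=len(dup_caseids),
        rate_ratio={d.inn: d.ocular_rate_ratio for d in drugs},
        weibull={d.inn: (d.weibull_alpha_days, d.weibull_beta) for d in drugs},
        report_share={d.inn: d.report_share for d in drugs},
        duplicate_caseids=sorted(dup_caseids),
        deleted_caseids=deleted_caseids,
        expected_marginals={
            "sex": dict(config.sex_probs),
            "reporter": dict(config.reporter_probs),
            "country": dict(config.country_probs),
            "outcome": dict(config.outcome_probs),
        },
        background_ocular_rate=config.background_ocular_rate,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        for rq in quarters_out:
            qdir = out_dir / rq.quarter_label
            qdir.mkdir(parents=True, exist_ok=True)
            for t in columns:
                write_faers_table(rq.table(t), qdir / f"{t.upper()}{rq.quarter_label}.txt")
            if rq.deleted_caseids:
                (qdir / f"DELETED{rq.quarter_label}.txt").write_text(
                    "\n".join(rq.deleted_caseids) + "\n", encoding="utf-8"
                )
        truth.to_json(out_dir / "truth.json")
    return quarters_out, truth


#: Planted drug panel of the "paper2024" preset: report shares and
#: Weibull onset parameters at the scale of the large published FAERS
#: ocular cohort; rate ratios are PRR-scale, clipped so that background
#: rate x ratio stays a probability.
_PAPER_DRUGS: list[dict] = [
    dict(inn="dupilumab", atc_codes=["A16AX", "D11AH", "R01", "R03DX"],
         report_share=0.0100, ocular_rate_ratio=4.0,
         weibull_alpha_days=156.34, weibull_beta=0.68),
    dict(inn="ciclosporin", atc_codes=["L04AD", "S01XA"],
         report_share=0.0043, ocular_rate_ratio=6.7,
         weibull_alpha_days=69.56, weibull_beta=0.44),
    dict(inn="ranibizumab", atc_codes=["S01LA"],
         report_share=0.0037, ocular_rate_ratio=15.0,
         weibull_alpha_days=200.10, weibull_beta=0.63),
    dict(inn="aflibercept", atc_codes=["L01XX", "S01LA"],
         report_share=0.0033, ocular_rate_ratio=15.0,
         weibull_alpha_days=280.61, weibull_beta=0.58),
    dict(inn="bimatoprost", atc_codes=["D11AX", "S01EE"],
         report_share=0.0030, ocular_rate_ratio=18.0,
         weibull_alpha_days=38.84, weibull_beta=0.45),
    dict(inn="fingolimod", atc_codes=["L04AE"],
         report_share=0.0027, ocular_rate_ratio=2.5,
         weibull_alpha_days=201.44, weibull_beta=0.59),
    dict(inn="insulin glargine", atc_codes=["A10AE"],
         report_share=0.0025, ocular_rate_ratio=2.8,
         weibull_alpha_days=560.80, weibull_beta=0.63),
    dict(inn="latanoprost", atc_codes=["S01EE"],
         report_share=0.0022, ocular_rate_ratio=14.0,
         weibull_alpha_days=559.18, weibull_beta=0.57),
    dict(inn="docetaxel", atc_codes=["L01CD"],
         report_share=0.0017, ocular_rate_ratio=2.5,
         weibull_alpha_days=152.58, weibull_beta=0.76),
    dict(inn="brolucizumab", atc_codes=["S01LA"],
         report_share=0.0013, ocular_rate_ratio=18.0,
         weibull_alpha_days=78.77, weibull_beta=0.85),
    dict(inn="pentosan polysulfate", atc_codes=["B01AB", "C05BA", "G04BX"],
         report_share=0.00083, ocular_rate_ratio=18.0,
         weibull_alpha_days=3313.91, weibull_beta=1.03),
    dict(inn="belantamab mafodotin", atc_codes=["L01FX"],
         report_share=0.00067, ocular_rate_ratio=18.0,
         weibull_alpha_days=62.78, weibull_beta=0.93),
]

PRESETS = ("paper2024", "uniform", "null")


def emulate_paper_marginals(
    config_preset: str, n_reports: int = 20000, seed: int = 0
) -> SyntheticConfig:
    """Named study conditions.

    ``paper2024`` reproduces the marginals of the published 2004–2024
    FAERS ocular-injury cohort (female 60.56%, age missing 38.65%, TTO
    missing 73.65%, consumer reporters 50.04%, ...) with the planted
    drug panel above. ``null`` keeps those marginals but sets every rate
    ratio to 1 (no true signals). ``uniform`` is a flat-marginal
    debugging preset.
    """
    if config_preset == "paper2024":
        return SyntheticConfig(
            seed=seed, n_reports=n_reports,
            quarters=["2023Q1", "2023Q2", "2023Q3", "2023Q4"],
            drugs=[DrugSpec(**d) for d in _PAPER_DRUGS],
        )
    if config_preset == "null":
        drugs = [DrugSpec(**{**d, "ocular_rate_ratio": 1.0}) for d in _PAPER_DRUGS]
        return SyntheticConfig(
            seed=seed, n_reports=n_reports,
            quarters=["2023Q1", "2023Q2", "2023Q3", "2023Q4"],
            drugs=drugs,
        )
    if config_preset == "uniform":
        third = 1.0 / 3.0
        return SyntheticConfig(
            seed=seed, n_reports=n_reports,
            quarters=["2023Q1", "2023Q2"],
            drugs=[DrugSpec(**d) for d in _PAPER_DRUGS[:4]],
            sex_probs={"F": third, "M": third, "unspecified": third},
            age_band_probs={"<18": 0.25, "18-44": 0.25, "45-64": 0.25, ">=65": 0.25},
            age_missing_rate=0.05, tto_missing_rate=0.2,
            reporter_probs={"CN": 0.2, "LW": 0.1, "": 0.1, "HP": 0.2, "PH": 0.2, "MD": 0.2},
            country_probs={"US": 0.25, "CA": 0.25, "GB": 0.25, "XX": 0.25},
        )
    raise ValueError(f"unknown preset {config_preset!r}; available: {PRESETS}")
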