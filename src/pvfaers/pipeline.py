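"""End-to-end run: generate/read -> clean -> map -> signal -> tto -> summarize.

The stage order mirrors the analysis procedure: quarters are assembled,
cases deduplicated once globally across quarters, deletion lists applied
(their union, to any quarter), drug names standardised, ocular cases
selected on primary SOC, and then disproportionality, time-to-onset and
descriptive outputs produced. Re-running with an identical config
reproduces identical outputs; a manifest records per-stage counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from pvfaers._version import __version__ as _version
from pvfaers.cleaning import build_case_table
from pvfaers.descriptives import summarize_cases
from pvfaers.dictionaries import DictionaryMaps, annotate_mentions, select_ocular_cases
from pvfaers.io_faers import RawQuarter, read_quarter, write_table
from pvfaers.signals import (
    atc_class_analysis,
    drug_level_analysis,
    pair_level_analysis,
    round2,
)
from pvfaers.synthetic import SyntheticConfig, emulate_paper_marginals, generate
from pvfaers.tto import TTOSample, build_tto_sample, fit_weibull, fits_frame, tto_summary

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One reproducible run, from YAML or constructed directly.

    Either ``preset``/``n_reports``/``seed`` (synthetic input) or
    ``quarter_dirs`` (real extract directories) must be given.
    """

    out_dir: str = "pv_out"
    preset: str | None = None
    n_reports: int = 20000
    seed: int = 0
    quarter_dirs: list[str] = field(default_factory=list)
    drug_dict: str | None = None
    atc_dict: str | None = None
    meddra: str | None = None
    min_a: int = 3
    min_tto_n: int = 30
    country_field: str = "occr_country"
    ic_variant: str = "noren"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = _version
    counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    completed: bool = False
    failed_stage: str | None = None

    def write(self, path: str | Path) -> None:
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2), encoding="utf-8")
        tmp.replace(path)  # atomic on POSIX


def _concat(quarters: list[RawQuarter], table: str) -> pd.DataFrame:
    frames = [q.table(table) for q in quarters if len(q.table(table))]
    if not frames:
        return quarters[0].table(table).iloc[0:0] if quarters else pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage and write the output CSVs plus manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed)
    stage = "input"
    try:
        if config.preset:
            syn = emulate_paper_marginals(config.preset, n_reports=config.n_reports,
                                          seed=config.seed)
            quarters, truth = generate(syn)
            truth.to_json(out / "truth.json")
            maps = syn.dictionary_maps()
        else:
            quarters = [read_quarter(d) for d in config.quarter_dirs]
            if config.drug_dict and config.atc_dict and config.meddra:
                maps = DictionaryMaps.from_files(config.drug_dict, config.atc_dict,
                                                 config.meddra)
            else:
                maps = DictionaryMaps.bundled()
        if not quarters:
            manifest.counts = {"rows_read": 0}
            manifest.completed = True
            manifest.write(out / "manifest.json")
            return manifest

        stage = "clean"
        demo = _concat(quarters, "demo")
        outc = _concat(quarters, "outc")
        deletions: set[str] = set()
        for q in quarters:
            deletions.update(q.deleted_caseids)
        cases, clean_rep = build_case_table(
            demo, outc, deleted_caseids=deletions, country_field=config.country_field
        )
        manifest.counts["rows_read"] = int(len(demo))
        manifest.counts["duplicates_removed"] = clean_rep.dedup.duplicates_removed
        manifest.counts["deleted"] = clean_rep.deletions_applied
        manifest.counts["deduplicated"] = int(len(cases))

        stage = "map"
        drug = _concat(quarters, "drug")
        reac = _concat(quarters, "reac")
        retained = set(cases["primaryid"])
        mentions = annotate_mentions(drug[drug["primaryid"].isin(retained)], maps)
        ps = mentions[mentions["role"] == "PS"].drop_duplicates("primaryid")
        drug_of_report = pd.Series(index=cases["primaryid"], dtype=object)
        drug_of_report.update(ps.set_index("primaryid")["inn"])

        ocular_ids, pairs = select_ocular_cases(
            reac[reac["primaryid"].isin(retained)], maps
        )
        ocular_flags = cases["primaryid"].isin(ocular_ids).to_numpy()
        manifest.counts["ocular_selected"] = int(ocular_flags.sum())

        stage = "signal"
        ev = pd.Series(ocular_flags, index=drug_of_report.index)
        sig_drug = drug_level_analysis(
            drug_of_report.reset_index(drop=True),
            pd.Series(ocular_flags), ic_variant=config.ic_variant,
        )
        sig_pair = pair_level_analysis(drug_of_report, pairs,
                                       ic_variant=config.ic_variant)
        sig_atc = atc_class_analysis(ps, drug_of_report, ev,
                                     ic_variant=config.ic_variant)
        manifest.counts["signals_drug"] = int(sig_drug["is_signal"].sum())
        manifest.counts["signals_pair"] = int(sig_pair["is_signal"].sum())
        manifest.counts["signals_atc"] = int(sig_atc["is_signal"].sum())

        stage = "tto"
        ther = _concat(quarters, "ther")
        fits, summaries = tto_stage(cases, ps, ther, drug_of_report, ocular_flags,
                                    min_n=config.min_tto_n)
        manifest.counts["tto_fits"] = sum(f.converged for f in fits)

        stage = "summarize"
        tto_per_case = tto_days_per_case(cases, ps, ther, drug_of_report, ocular_flags)
        oc_cases = cases.loc[pd.Series(ocular_flags).to_numpy()]
        summary = summarize_cases(oc_cases.reset_index(drop=True),
                                  tto_days=tto_per_case)

        stage = "write"
        for name, df in (
            ("signals_drug.csv", _present(sig_drug)),
            ("signals_pair.csv", _present(sig_pair)),
            ("signals_atc.csv", _present(sig_atc)),
            ("tto_fits.csv", fits_frame(fits, summaries)),
            ("summary.csv", summary),
        ):
            write_table(df, out / name)
            manifest.outputs[name] = str(out / name)
        manifest.completed = True
    except Exception:
        manifest.failed_stage = stage
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    manifest.outputs["manifest.json"] = str(out / "manifest.json")
    return manifest


def _present(df: pd.DataFrame) -> pd.DataFrame:
    """Presentation rounding (2 dp, half-up) of estimate columns."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(round2)
    return out


def _event_start_inputs(cases, ps, ther, drug_of_report, ocular_flags):
    """Per ocular report: (inn, event_dt, [start_dts of the PS drug])."""
    ther_i = ther.copy()
    ther_i["primaryid"] = ther_i["primaryid"].astype(str).str.strip()
    starts_by_pid: dict[str, dict[str, list[str]]] = {}
    seq_col = "dsg_drug_seq" if "dsg_drug_seq" in ther_i.columns else "drug_seq"
    for pid, seq, start in zip(ther_i["primaryid"], ther_i[seq_col], ther_i["start_dt"]):
        starts_by_pid.setdefault(pid, {}).setdefault(str(seq).strip(), []).append(start)
    ps_seq = ps.set_index("primaryid")["drug_seq"]
    rows = []
    flags = pd.Series(ocular_flags).to_numpy()
    for (pid, event_dt), flag in zip(zip(cases["primaryid"], cases["event_dt"]), flags):
        if not flag:
            continue
        inn = drug_of_report.get(pid)
        if inn is None or inn != inn:
            continue
        seq = str(ps_seq.get(pid, "")).strip()
        starts = starts_by_pid.get(pid, {}).get(seq, [])
        rows.append((pid, inn, event_dt, starts))
    return rows


def tto_stage(cases, ps, ther, drug_of_report, ocular_flags, min_n: int = 30):
    """Per-drug TTO samples, summaries, and Weibull fits."""
    rows = _event_start_inputs(cases, ps, ther, drug_of_report, ocular_flags)
    by_drug: dict[str, tuple[list, list]] = {}
    for _pid, inn, event_dt, starts in rows:
        ev_list, st_list = by_drug.setdefault(inn, ([], []))
        ev_list.append(event_dt)
        st_list.append(starts)
    fits, summaries = [], {}
    for inn in sorted(by_drug):
        ev_list, st_list = by_drug[inn]
        sample = build_tto_sample(inn, ev_list, st_list)
        if sample.n_valid >= min_n:
            summaries[inn] = tto_summary(sample)
            fits.append(fit_weibull(sample, min_n=min_n))
    return fits, summaries


def tto_days_per_case(cases, ps, ther, drug_of_report, ocular_flags) -> pd.Series:
    """TTO per ocular case (NaN = excluded), aligned to ocular cases."""
    from pvfaers.tto import compute_tto

    rows = _event_start_inputs(cases, ps, ther, drug_of_report, ocular_flags)
    per_pid = {}
    for pid, _inn, event_dt, starts in rows:
        t, _reason = compute_tto(event_dt, starts)
        per_pid[pid] = float("nan") if t is None else float(t)
    flags = pd.Series(ocular_flags).to_numpy()
    oc_pids = cases.loc[flags, "primaryid"]
    return pd.Series([per_pid.get(p, float("nan")) for p in oc_pids])
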