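import numpy as np
import pandas as pd
import pytest

from pvfaers.cleaning import deduplicate
from pvfaers.dictionaries import select_ocular_cases
from pvfaers.synthetic import (
    DrugSpec,
    SyntheticConfig,
    emulate_paper_marginals,
    generate,
)


def small_config(seed=42, n=1000, **kw):
    defaults = dict(
        seed=seed,
        n_reports=n,
        quarters=["2019Q1", "2019Q2"],
        drugs=[
            DrugSpec(inn="bimatoprost", atc_codes=["D11AX", "S01EE"],
                     report_share=0.05, ocular_rate_ratio=10.0,
                     weibull_alpha_days=40.0, weibull_beta=0.45),
            DrugSpec(inn="docetaxel", atc_codes=["L01CD"],
                     report_share=0.05, ocular_rate_ratio=1.0,
                     weibull_alpha_days=150.0, weibull_beta=1.0),
        ],
        duplicate_rate=0.1,
        deletion_rate=0.01,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestConfigValidation:
    def test_infeasible_rate_ratio_rejected(self):
        with pytest.raises(ValueError, match="above 1"):
            SyntheticConfig(
                background_ocular_rate=0.2,
                drugs=[DrugSpec(inn="x", report_share=0.1, ocular_rate_ratio=10.0)],
            )

    def test_shares_above_one_rejected(self):
        with pytest.raises(ValueError, match="shares"):
            SyntheticConfig(
                drugs=[DrugSpec(inn="x", report_share=0.6),
                       DrugSpec(inn="y", report_share=0.6)]
            )

    def test_unknown_preset_lists_presets(self):
        with pytest.raises(ValueError, match="paper2024"):
            emulate_paper_marginals("nope")


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = small_config()
        generate(cfg, out_dir=tmp_path / "a")
        generate(cfg, out_dir=tmp_path / "b")
        files_a = sorted(p.relative_to(tmp_path / "a")
                         for p in (tmp_path / "a").rglob("*") if p.is_file())
        files_b = sorted(p.relative_to(tmp_path / "b")
                         for p in (tmp_path / "b").rglob("*") if p.is_file())
        assert files_a == files_b
        for rel in files_a:
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()

    def test_different_seed_differs(self):
        qa, _ = generate(small_config(seed=1))
        qb, _ = generate(small_config(seed=2))
        assert not qa[0].demo.equals(qb[0].demo)


class TestBookkeeping:
    def test_duplicate_accounting_matches_truth(self):
        cfg = small_config(seed=7, n=1000)
        quarters, truth = generate(cfg)
        demo = pd.concat([q.demo for q in quarters], ignore_index=True)
        assert len(demo) == truth.n_reports + truth.n_duplicate_rows
        kept, _, acc = deduplicate(demo)
        assert acc.duplicates_removed == truth.n_duplicate_rows
        assert len(kept) == truth.n_reports
        # the retained version of each duplicated case is version 2
        kept_ids = kept.set_index("caseid")["primaryid"]
        for cid in truth.duplicate_caseids[:20]:
            assert kept_ids[cid].endswith("2")

    def test_deletion_lists_on_post_2019_quarters(self):
        cfg = small_config(seed=9, n=1000, quarters=["2018Q4", "2019Q1"])
        quarters, truth = generate(cfg)
        assert quarters[0].deleted_caseids == []
        assert sorted(quarters[1].deleted_caseids) == truth.deleted_caseids
        assert len(truth.deleted_caseids) == 10

    def test_truth_roundtrip_json(self, tmp_path):
        cfg = small_config(n=200)
        _, truth = generate(cfg, out_dir=tmp_path)
        from pvfaers.synthetic import SyntheticTruth

        back = SyntheticTruth.from_json(tmp_path / "truth.json")
        assert back == truth

    def test_files_readable_by_io_layer(self, tmp_path):
        from pvfaers.io_faers import read_quarter

        cfg = small_config(n=300)
        quarters, _ = generate(cfg, out_dir=tmp_path)
        rq = read_quarter(tmp_path / "2019Q1")
        pd.testing.assert_frame_equal(rq.demo, quarters[0].demo)
        assert rq.deleted_caseids == quarters[0].deleted_caseids


class TestPlantedStructure:
    def test_planted_drug_enriched_for_ocular_pts(self):
        cfg = small_config(seed=11, n=8000)
        quarters, truth = generate(cfg)
        demo = pd.concat([q.demo for q in quarters], ignore_index=True)
        drug = pd.concat([q.drug for q in quarters], ignore_index=True)
        reac = pd.concat([q.reac for q in quarters], ignore_index=True)
        kept, _, _ = deduplicate(demo)
        keep_ids = set(kept["primaryid"])
        maps = cfg.dictionary_maps()
        ocular_ids, _ = select_ocular_cases(reac[reac["primaryid"].isin(keep_ids)], maps)
        drug = drug[drug["primaryid"].isin(keep_ids)]
        inn = drug["drugname"].str.casefold().map(maps.name_to_inn)
        by_drug = pd.DataFrame(
            {"inn": inn.values, "ocular": drug["primaryid"].isin(ocular_ids).values}
        ).groupby("inn")["ocular"].mean()
        p_bim = by_drug["bimatoprost"]
        p_doc = by_drug["docetaxel"]
        assert p_bim > 4 * p_doc  # planted ratio 10 vs 1
        assert abs(p_bim - 0.5) < 0.1  # 0.05 x 10

    def test_tto_missing_rate_honoured(self):
        cfg = small_config(seed=13, n=5000, tto_missing_rate=0.5)
        quarters, _ = generate(cfg)
        demo = pd.concat([q.demo for q in quarters], ignore_index=True)
        valid = demo["event_dt"].str.fullmatch(r"\d{8}").fillna(False)
        assert abs((~valid).mean() - 0.5) < 0.03


class TestPaperPreset:
    def test_paper2024_marginals_recovered(self):
        cfg = emulate_paper_marginals("paper2024", n_reports=100_000, seed=7)
        quarters, _ = generate(cfg)
        demo = pd.concat([q.demo for q in quarters], ignore_index=True)
        kept, _, _ = deduplicate(demo)
        female = (kept["sex"] == "F").mean() * 100
        assert abs(female - 60.56) < 0.5
        tto_missing = (~kept["event_dt"].str.fullmatch(r"\d{8}").fillna(False)).mean() * 100
        assert abs(tto_missing - 73.65) < 1.0
        age_missing = (kept["age"] == "").mean() * 100
        assert abs(age_missing - 38.65) < 0.5
        consumer = (kept["occp_cod"] == "CN").mean() * 100
        assert abs(consumer - 50.04) < 0.5

    def test_uniform_preset_equal_sex_shares(self):
        cfg = emulate_paper_marginals("uniform", n_reports=30_000, seed=3)
        quarters, _ = generate(cfg)
        demo = pd.concat([q.demo for q in quarters], ignore_index=True)
        shares = demo["sex"].replace("", "U").value_counts(normalize=True)
        assert abs(shares["F"] - 1 / 3) < 0.02
        assert abs(shares["M"] - 1 / 3) < 0.02

    def test_null_preset_has_unit_rate_ratios(self):
        cfg = emulate_paper_marginals("null", n_reports=100, seed=1)
        assert all(d.ocular_rate_ratio == 1.0 for d in cfg.drugs)
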