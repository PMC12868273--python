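import math
import types
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from pvfaers.signals import (
    ContingencyTable,
    atc_class_analysis,
    build_contingency,
    compute_metrics,
    drug_level_analysis,
    ebgm,
    evaluate_signal,
    ic,
    mgps_full,
    pair_level_analysis,
    prr,
    ror,
)

Z = 1.959963984540054


class TestBuildContingency:
    def test_brute_force_set_intersection(self):
        drug = [i in {1, 2, 3, 4} for i in range(10)]
        event = [i in {3, 4, 5, 6} for i in range(10)]
        ct = build_contingency(drug, event)
        assert (ct.a, ct.b, ct.c, ct.d) == (2, 2, 2, 4)

    def test_no_drug_reports(self):
        ct = build_contingency([False] * 10, [True] * 3 + [False] * 7)
        assert (ct.a, ct.b, ct.c, ct.d) == (0, 0, 3, 7)

    def test_degenerate_full_overlap(self):
        ct = build_contingency([True] * 5, [True] * 5)
        assert (ct.a, ct.b, ct.c, ct.d) == (5, 0, 0, 0)

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError):
            build_contingency([True] * 3, [True] * 4)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)


class TestPointEstimates:
    def test_symmetric_table_is_null(self):
        ct = ContingencyTable(25, 25, 25, 25)
        r, lo, hi = ror(ct)
        assert r == pytest.approx(1.0)
        assert lo < 1 < hi
        p, plo, phi = prr(ct)
        assert p == pytest.approx(1.0)

    def test_hand_arithmetic_example(self):
        ct = ContingencyTable(10, 90, 100, 9900)
        r, lo, hi = ror(ct)
        assert r == pytest.approx(11.0)
        se = math.sqrt(0.1 + 1 / 90 + 0.01 + 1 / 9900)
        assert lo == pytest.approx(math.exp(math.log(11.0) - Z * se))
        assert hi == pytest.approx(math.exp(math.log(11.0) + Z * se))
        p, _, _ = prr(ct)
        assert p == pytest.approx((10 / 100) / (100 / 10000))
        e, e05 = ebgm(ct)
        assert e == pytest.approx(10 * 10100 / (100 * 110))
        assert e05 == pytest.approx(e * math.exp(-1.6448536269514722 * se))

    def test_zero_cell_flags_undefined_ror(self):
        assert all(math.isnan(v) for v in ror(ContingencyTable(0, 5, 5, 5)))

    def test_haldane_correction_optional(self):
        r, lo, hi = ror(ContingencyTable(0, 5, 5, 5), haldane=True)
        assert r == pytest.approx(0.5 * 5.5 / (5.5 * 5.5))

    def test_prr_zero_a(self):
        p, _, _ = prr(ContingencyTable(0, 10, 10, 100))
        assert p == 0.0

    def test_ic_independence_is_zero(self):
        # a == E exactly: 2x2 with all margins equal
        ct = ContingencyTable(10, 10, 10, 10)
        i, i025 = ic(ct)
        assert i == pytest.approx(0.0)
        assert i025 < 0

    def test_ic_hand_arithmetic(self):
        # construct a=10 with E=1: margins (a+b)=20, (a+c)=50, N=1000
        ct = ContingencyTable(10, 10, 40, 940)
        assert ct.expected == pytest.approx(1.0)
        i, i025 = ic(ct)
        assert i == pytest.approx(math.log2(10.5 / 1.5))
        assert i025 == pytest.approx(i - 3.3 / math.sqrt(10.5) - 2.0 / 10.5**1.5)

    def test_ic_penalty_vanishes_for_large_a(self):
        small = ContingencyTable(10, 10, 40, 940)
        big = ContingencyTable(10000, 10000, 40000, 940000)
        i_s, lo_s = ic(small)
        i_b, lo_b = ic(big)
        assert (i_b - lo_b) < (i_s - lo_s)
        assert i_b - lo_b < 0.05

    def test_bate_variant_agrees_with_noren_for_a_ge_3(self):
        # the beta-prior form shrinks slightly harder at small a, but the
        # two variants agree in direction and converge as a grows
        for ct in [ContingencyTable(10, 90, 100, 9900),
                   ContingencyTable(50, 500, 1000, 100000),
                   ContingencyTable(5, 20, 200, 5000),
                   ContingencyTable(500, 5000, 10000, 1000000)]:
            i_n, lo_n = ic(ct, variant="noren")
            i_b, lo_b = ic(ct, variant="bate")
            assert math.copysign(1, i_n) == math.copysign(1, i_b)
            assert abs(i_n - i_b) < 0.5
            assert (lo_n > 0) == (lo_b > 0)

    def test_ebgm_independence_is_one(self):
        e, _ = ebgm(ContingencyTable(10, 10, 10, 10))
        assert e == pytest.approx(1.0)

    def test_ebgm_scale_invariance_and_tightening(self):
        ct = ContingencyTable(10, 90, 100, 9900)
        big = ContingencyTable(100, 900, 1000, 99000)
        e1, lo1 = ebgm(ct)
        e2, lo2 = ebgm(big)
        assert e1 == pytest.approx(e2)
        assert lo2 > lo1  # lower bound approaches the estimate


class TestSmallTableOracle:
    def test_brute_force_equivalence_all_tables(self):
        """ROR/PRR equal exact rational arithmetic on every table N<=40."""
        checked = 0
        for N in range(1, 41):
            for a in range(N + 1):
                for b in range(N - a + 1):
                    for c in range(N - a - b + 1):
                        d = N - a - b - c
                        ct = ContingencyTable(a, b, c, d)
                        if min(a, b, c, d) > 0:
                            want = Fraction(a * d, b * c)
                            got, _, _ = ror(ct)
                            assert abs(got - float(want)) < 1e-12
                        if a > 0 and c > 0:
                            want = Fraction(a, a + b) / Fraction(c, c + d)
                            got, _, _ = prr(ct)
                            assert abs(got - float(want)) < 1e-12
                        checked += 1
        assert checked > 100_000


class TestInvariancesAndMonotonicity:
    def test_cell_permutation_leaves_ror_invariant(self):
        for (a, b, c, d) in [(3, 7, 11, 13), (10, 90, 100, 9900), (1, 1, 2, 5)]:
            r1, _, _ = ror(ContingencyTable(a, b, c, d))
            r2, _, _ = ror(ContingencyTable(d, c, b, a))
            assert r1 == pytest.approx(r2)

    def test_ror_prr_straddle_one_jointly(self):
        for (a, b, c, d) in [(3, 7, 11, 13), (10, 90, 100, 9900),
                             (5, 500, 100, 1000), (50, 50, 10, 890)]:
            r, _, _ = ror(ContingencyTable(a, b, c, d))
            p, _, _ = prr(ContingencyTable(a, b, c, d))
            i, _ = ic(ContingencyTable(a, b, c, d))
            if a >= 3:
                assert math.copysign(1, math.log(r)) == math.copysign(1, math.log(p))

    def test_increasing_a_with_margins_fixed_increases_all(self):
        # margins fixed: (a+b), (a+c), N constant => a+1, b-1, c-1, d+1
        a, b, c, d = 10, 90, 100, 9900
        m0 = compute_metrics(ContingencyTable(a, b, c, d))
        m1 = compute_metrics(ContingencyTable(a + 1, b - 1, c - 1, d + 1))
        assert m1.ror > m0.ror
        assert m1.prr > m0.prr
        assert m1.ic > m0.ic
        assert m1.ebgm > m0.ebgm


class TestEvaluateSignal:
    def test_two_reports_never_signal(self):
        # extreme disproportionality but a = 2
        m = compute_metrics(ContingencyTable(2, 1, 1, 100000))
        assert m.ror > 100 and not m.is_signal

    def test_boundary_ror_lo_exactly_one(self):
        m = compute_metrics(ContingencyTable(10, 90, 100, 9900))
        m.ror_lo = 1.0
        assert not evaluate_signal(m)

    def test_large_pair_all_bounds_clear(self):
        # a=426-scale pair with overwhelming disproportionality
        m = compute_metrics(ContingencyTable(426, 5000, 50, 1_000_000),
                            name="pentosan polysulfate",
                            event="Pigmentary maculopathy", level="drug_pt")
        assert m.is_signal
        assert m.ror_lo > 1 and m.prr_lo > 1 and m.ic025 > 0 and m.ebgm05 > 2

    def test_undefined_statistic_fails(self):
        m = compute_metrics(ContingencyTable(5, 0, 10, 100))
        assert not m.is_signal


class TestMgpsFull:
    def _null_tables(self, n_pairs, seed, lam=1.0):
        rng = np.random.default_rng(seed)
        E = rng.lognormal(1.0, 1.0, size=n_pairs) + 0.5
        a = rng.poisson(lam * E)
        return [types.SimpleNamespace(a=int(ai), expected=float(Ei))
                for ai, Ei in zip(a, E)]

    def test_null_simulation_prior_concentrates_near_one(self):
        tabs = self._null_tables(400, seed=5)
        res = mgps_full(tabs)
        assert res.converged
        med = float(np.median(res.ebgm))
        assert 0.8 <= med <= 1.25

    def _mixed_tables(self, n_pairs, seed):
        # heterogeneous truth (the gamma-Poisson model's own premise):
        # most pairs null-ish, a minority with elevated reporting rates
        rng = np.random.default_rng(seed)
        E = rng.lognormal(1.0, 1.0, size=n_pairs) + 0.5
        lam = np.where(rng.random(n_pairs) < 0.8,
                       rng.gamma(20.0, 1 / 20.0, size=n_pairs),
                       rng.gamma(2.0, 1.0, size=n_pairs))
        a = rng.poisson(lam * E)
        return [types.SimpleNamespace(a=int(ai), expected=float(Ei))
                for ai, Ei in zip(a, E)]

    def test_zero_count_pairs_shrink_below_prior_mean(self):
        tabs = self._mixed_tables(300, seed=7)
        res = mgps_full(tabs)
        assert res.converged
        zeros = [i for i, t in enumerate(tabs) if t.a == 0]
        assert zeros
        assert all(res.ebgm[i] < 1.0 for i in zeros)

    def test_strong_pair_among_mixed_has_high_eb05(self):
        tabs = self._mixed_tables(300, seed=11)
        tabs.append(types.SimpleNamespace(a=100, expected=1.0))
        res = mgps_full(tabs)
        assert res.converged
        assert res.eb05[-1] > 10
        # and the strong pair's EBGM exceeds every null-drawn pair's
        assert res.ebgm[-1] == max(res.ebgm)

    def test_requires_enough_tables(self):
        with pytest.raises(ValueError):
            mgps_full(self._null_tables(10, seed=1))


class TestAnalysisLevels:
    def test_atc_repeated_counting(self):
        # one drug in classes L and S with 7 ocular reports among 100
        n = 100
        inn = pd.Series(["ciclosporin"] * 10 + [None] * (n - 10))
        ocular = pd.Series([True] * 7 + [False] * 3 + [True] * 5 + [False] * (n - 15))
        mentions = pd.DataFrame(
            {"inn": ["ciclosporin"], "atc_level1": [{"L", "S"}]}
        )
        out = atc_class_analysis(mentions, inn, ocular)
        byname = out.set_index("name")
        assert byname.loc["L", "a"] == 7
        assert byname.loc["S", "a"] == 7

    def test_single_class_universe_matches_drug_level(self):
        n = 60
        inn = pd.Series(["latanoprost"] * 12 + [None] * (n - 12))
        ocular = pd.Series([True] * 8 + [False] * 4 + [True] * 6 + [False] * (n - 18))
        drug = drug_level_analysis(inn, ocular)
        mentions = pd.DataFrame({"inn": ["latanoprost"], "atc_level1": [{"S"}]})
        cls = atc_class_analysis(mentions, inn, ocular)
        assert drug.loc[0, "a"] == cls.loc[0, "a"]
        assert drug.loc[0, "ror"] == pytest.approx(cls.loc[0, "ror"])

    def test_pair_level_counts_each_report_pt_once(self):
        inn = pd.Series(["x", "x", None, None, None],
                        index=["1", "2", "3", "4", "5"])
        pairs = pd.DataFrame(
            {"primaryid": ["1", "1", "2", "3"],
             "pt": ["Dry eye", "Dry eye", "Dry eye", "Dry eye"]}
        )
        out = pair_level_analysis(inn, pairs)
        assert len(out) == 1
        assert out.loc[0, "a"] == 2  # reports 1 and 2; duplicate pair ignored
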