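"""Friedman omnibus, Wilcoxon signed-rank, effect sizes, contrast runner."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import posturo as po
from oracles import enumerate_signed_rank_p
from posturo.stats import CohortMeasureTable


def make_table(values, participants=None):
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    df = pd.DataFrame(values, columns=range(1, k + 1),
                      index=participants or range(1, n + 1))
    return CohortMeasureTable(df)


class TestWilcoxon:
    def test_exact_enumeration_example(self):
        # d = [1..5]: all positive, W+ = 15, two-sided p = 2/32
        res = po.wilcoxon_signed_rank([2, 4, 6, 8, 10], [1, 2, 3, 4, 5])
        assert res.w_statistic == 15.0
        assert res.p_value == pytest.approx(0.0625)
        assert res.method == "exact"

    def test_identical_samples_degenerate(self):
        a = [1.0, 2.0, 3.0]
        res = po.wilcoxon_signed_rank(a, a)
        assert res.degenerate and res.p_value == 1.0 and res.effect_r == 0.0

    def test_sign_flip_symmetry(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0, 1, 12)
        r1 = po.wilcoxon_signed_rank(a, b)
        r2 = po.wilcoxon_signed_rank(b, a)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert abs(r1.z_value) == pytest.approx(abs(r2.z_value))

    @pytest.mark.parametrize("n", [6, 9, 12])
    @pytest.mark.parametrize("seed", range(3))
    def test_exact_matches_full_enumeration(self, n, seed):
        r = np.random.default_rng(seed)
        a = r.normal(0.3, 1, n)
        b = r.normal(0, 1, n)
        res = po.wilcoxon_signed_rank(a, b, mode="exact")
        assert res.p_value == pytest.approx(
            enumerate_signed_rank_p(a - b), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_vs_approx_consistency(self, seed):
        """The continuity-corrected normal approximation tracks the exact
        sign-flip distribution closely at small n."""
        r = np.random.default_rng(seed)
        n = int(r.integers(8, 16))
        a = r.normal(0.4, 1, n)
        b = r.normal(0, 1, n)
        p_exact = po.wilcoxon_signed_rank(a, b, mode="exact").p_value
        p_approx = po.wilcoxon_signed_rank(a, b, mode="approx",
                                           continuity=True).p_value
        assert abs(p_exact - p_approx) <= 0.03

    def test_matches_scipy_approx(self, rng):
        a = rng.normal(0.5, 1, 30)
        b = rng.normal(0, 1, 30)
        res = po.wilcoxon_signed_rank(a, b, mode="approx")
        ref = sps.wilcoxon(a, b, correction=False, method="approx")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)
        assert abs(res.z_value) == pytest.approx(abs(ref.zstatistic), rel=1e-9)

    def test_matches_scipy_exact(self, rng):
        a = rng.normal(0.5, 1, 11)
        b = rng.normal(0, 1, 11)
        res = po.wilcoxon_signed_rank(a, b, mode="exact")
        ref = sps.wilcoxon(a, b, method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zeros_discarded_by_default(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [1.0, 2.0, 1.0, 2.0, 3.0]
        res = po.wilcoxon_signed_rank(a, b)
        assert res.n_effective == 3 and res.n_excluded == 2

    def test_pratt_differs_from_discard_with_zeros(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        b = a - np.array([0, 0, 0, 1, 2, 3, 4, 5.0])
        d1 = po.wilcoxon_signed_rank(a, b, zero_method="discard")
        d2 = po.wilcoxon_signed_rank(a, b, zero_method="pratt")
        assert d1.w_statistic != d2.w_statistic


class TestEffectSize:
    def test_direct_formula(self):
        assert po.effect_size_r(2.4, 16) == pytest.approx(0.6)
        assert po.effect_size_r(0.0, 23) == 0.0
        assert po.effect_size_r(-2.973, 23) == pytest.approx(0.620, abs=5e-4)

    def test_zero_n_rejected(self):
        with pytest.raises(po.StructuralError):
            po.effect_size_r(1.0, 0)

    def test_never_exceeds_enumerable_maximum(self, rng):
        # |Z| is maximal when W+ hits an end of its range
        for n in (5, 10, 20):
            mean = n * (n + 1) / 4
            var = n * (n + 1) * (2 * n + 1) / 24
            z_max = mean / np.sqrt(var)
            for _ in range(20):
                a = rng.normal(1, 1, n)
                b = rng.normal(0, 1, n)
                res = po.wilcoxon_signed_rank(a, b)
                if not res.degenerate:
                    assert res.effect_r <= z_max / np.sqrt(n) + 1e-12


class TestFriedman:
    def test_concordant_hand_value(self):
        # identical ordering in every block, n=3, k=3 -> chi2 = 6
        table = make_table([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        res = po.friedman_test(table, permutation_threshold=0)
        assert res.statistic == pytest.approx(6.0)
        assert res.df == 2

    def test_fully_tied_blocks(self):
        table = make_table([[2, 2, 2], [5, 5, 5], [1, 1, 1]])
        res = po.friedman_test(table, permutation_threshold=0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_column_permutation_invariance(self, rng):
        vals = rng.normal(0, 1, (10, 4))
        r1 = po.friedman_test(make_table(vals))
        r2 = po.friedman_test(make_table(vals[:, [2, 0, 3, 1]]))
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_monotone_transform_invariance(self, rng):
        vals = rng.normal(0, 1, (9, 5))
        r1 = po.friedman_test(make_table(vals))
        r2 = po.friedman_test(make_table(np.exp(vals)))
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_matches_scipy(self, rng):
        vals = rng.normal(0, 1, (15, 6))
        res = po.friedman_test(make_table(vals))
        ref = sps.friedmanchisquare(*[vals[:, j] for j in range(6)])
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_small_n_uses_permutation(self, rng):
        vals = rng.normal(0, 1, (5, 3))
        res = po.friedman_test(make_table(vals), n_permutations=2000, seed=1)
        assert res.method == "permutation"
        assert 0 < res.p_value <= 1

    def test_incomplete_blocks_listed(self):
        df = pd.DataFrame({1: [1.0, 2.0], 2: [1.0, np.nan], 3: [0.5, 1.5]},
                          index=["a", "b"])
        with pytest.raises(po.StructuralError, match="missing"):
            CohortMeasureTable(df)


class TestNormalityScreen:
    def test_gaussian_rarely_rejected(self):
        hits = sum(
            po.normality_screen(
                np.random.default_rng(s).normal(0, 1, 23))[1] > 0.05
            for s in range(100)
        )
        assert hits >= 90

    def test_bimodal_spikes_rejected(self):
        hits = 0
        for s in range(100):
            r = np.random.default_rng(s)
            x = np.concatenate([r.normal(-10, 0.5, 12), r.normal(10, 0.5, 11)])
            hits += po.normality_screen(x)[1] < 0.05
        assert hits >= 90

    def test_constant_sample_rejected(self):
        with pytest.raises(po.StructuralError):
            po.normality_screen([1.0] * 23)


class TestPermutationOracle:
    def test_full_enumeration_example(self):
        assert po.permutation_oracle([2, 4, 6, 8, 10],
                                     [1, 2, 3, 4, 5]) == pytest.approx(0.0625)

    def test_identical_samples(self):
        assert po.permutation_oracle([1.0, 2.0], [1.0, 2.0]) == 1.0

    def test_null_p_values_uniform(self):
        ps = []
        for s in range(200):
            r = np.random.default_rng(s)
            a = r.normal(0, 1, 10)
            b = r.normal(0, 1, 10)
            ps.append(po.permutation_oracle(a, b, n_perm=2000, seed=s))
        stat, p = sps.kstest(ps, "uniform")
        assert p > 0.01


def _long_df_from_wide(wide: np.ndarray) -> pd.DataFrame:
    rows = []
    n, k = wide.shape
    for p in range(n):
        for c in range(k):
            for m in po.MEASURE_NAMES:
                rows.append({"participant": p + 1, "condition": c + 1,
                             "trial": "agg", "measure": m,
                             "value": wide[p, c], "flag": ""})
    return pd.DataFrame(rows)


class TestRunContrasts:
    def test_full_table_yields_28_results(self, rng):
        wide = rng.normal(10, 2, (23, 6))
        reports = po.run_contrasts(_long_df_from_wide(wide))
        assert len(reports) == 7
        assert sum(len(r.contrasts) for r in reports) == 28

    def test_duplicate_condition_degenerate(self, rng):
        wide = rng.normal(10, 2, (10, 6))
        wide[:, 1] = wide[:, 0]  # condition 2 duplicates condition 1
        reports = po.run_contrasts(_long_df_from_wide(wide))
        for rep in reports:
            res = next(r for r in rep.contrasts if r.contrast == (2, 1))
            assert res.degenerate

    def test_shifted_condition_detected(self, rng):
        wide = rng.normal(10, 1, (23, 6))
        wide[:, 3] += 5.0  # strong condition-4 shift
        reports = po.run_contrasts(_long_df_from_wide(wide))
        for rep in reports:
            res = next(r for r in rep.contrasts if r.contrast == (4, 1))
            assert res.p_value < 0.05 and res.effect_r > 0.5

    def test_missing_condition_rejected(self, rng):
        wide = rng.normal(10, 2, (8, 6))
        df = _long_df_from_wide(wide)
        df = df[df["condition"] != 5]
        with pytest.raises(po.StructuralError, match="condition 5"):
            po.run_contrasts(df)

    def test_flagged_values_excluded_listwise(self, rng):
        wide = rng.normal(10, 1, (12, 6))
        df = _long_df_from_wide(wide)
        mask = ((df["participant"] == 1) & (df["condition"] == 2)
                & (df["measure"] == "mf_ml"))
        df.loc[mask, "flag"] = "undefined"
        reports = po.run_contrasts(df)
        rep = next(r for r in reports if r.measure == "mf_ml")
        res = next(r for r in rep.contrasts if r.contrast == (2, 1))
        assert res.n_effective <= 11
        assert rep.n_flag_excluded[(2, 1)] == 1
        other = next(r for r in reports if r.measure == "mean_ap")
        assert other.omnibus.n == 12
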