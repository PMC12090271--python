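"""Group-size calibration and rank-based statistics."""

import math
from itertools import combinations

import numpy as np
import pytest

from dart2.calibration import (
    ReplicateSet,
    calibrate_group_size,
    effect_size,
    kruskal_dunn,
    mann_whitney,
    temporal_variance,
    variance_of_means,
    wilcoxon_paired,
)
from dart2.simulate import AssaySimConfig
from dart2.timeseries import CoMSeries, OdorWindow


def reps(values, condition="x", group_size=16):
    return ReplicateSet(condition, group_size, np.asarray(values, dtype=float))


class TestVarianceAndEffect:
    def test_identical_means_zero_variance(self):
        assert variance_of_means(reps([0.7, 0.7, 0.7])) == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_variance(self):
        # {0.6, 0.8}: mean 0.7, (n-1) variance = 0.02
        assert variance_of_means(reps([0.6, 0.8])) == pytest.approx(0.02, abs=1e-15)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            variance_of_means(reps([0.5]))

    def test_identical_groups_zero_effect(self):
        a = reps([0.4, 0.5, 0.6])
        assert effect_size(a, a) == 0.0

    def test_unit_pooled_sd_gives_shift(self):
        # two-point groups with pooled SD exactly computable
        a = reps([0.6, 0.8])
        b = reps([0.2, 0.4])
        d = effect_size(a, b)
        pooled = math.sqrt((0.02 + 0.02) / 2)
        assert d == pytest.approx(0.4 / pooled, abs=1e-12)

    def test_hand_computed_cohen_d(self):
        # treated {0.7,0.8,0.9}, control {0.5,0.5,0.5}:
        # pooled var = (2*0.01 + 2*0)/4 = 0.005, d = 0.3/sqrt(0.005)
        d = effect_size(reps([0.7, 0.8, 0.9]), reps([0.5, 0.5, 0.5]))
        assert d == pytest.approx(0.3 / math.sqrt(0.005), abs=1e-12)

    def test_zero_pooled_sd_flagged_undefined(self):
        assert math.isnan(effect_size(reps([0.5, 0.5]), reps([0.6, 0.6])))

    def test_temporal_variance_secondary_output(self):
        series = CoMSeries(times=np.arange(6) * 600.0, values=[0.5, 0.6, 0.7, 0.7, 0.7, 0.7], cadence_s=600.0)
        v = temporal_variance(series, OdorWindow("x", 0, 60))
        assert v == pytest.approx(np.var([0.5, 0.6, 0.7, 0.7, 0.7, 0.7], ddof=1))


class TestCalibrationSweep:
    def test_null_calibration_effects_near_zero(self):
        cfg = AssaySimConfig(drift_mm_s=0.0, duration_s=1200, crowding_radius_mm=0.0, seed=5)
        res = calibrate_group_size(cfg, group_sizes=(4, 16), n_reps=12, window=OdorWindow("x", 10, 20))
        # both arms are drift-free; Cohen's d fluctuates around 0
        assert np.all(np.abs(res.effect_sizes) < 1.5)

    def test_fixed_seed_reproducible(self):
        cfg = AssaySimConfig(duration_s=600, seed=9)
        kw = dict(group_sizes=(2, 8), n_reps=4, window=OdorWindow("x", 5, 10))
        a = calibrate_group_size(cfg, **kw)
        b = calibrate_group_size(cfg, **kw)
        assert np.array_equal(a.variances, b.variances)
        assert np.array_equal(a.effect_sizes, b.effect_sizes)
        assert np.array_equal(a.mean_coms, b.mean_coms)

    def test_dataframe_shape(self):
        cfg = AssaySimConfig(duration_s=600, seed=9)
        res = calibrate_group_size(cfg, group_sizes=(2, 8), n_reps=4, window=OdorWindow("x", 5, 10))
        df = res.to_dataframe()
        assert list(df["group_size"]) == [2, 8]
        assert set(df.columns) >= {"variance", "effect_size", "mean_com"}


class TestMannWhitney:
    def test_identical_samples_u_half(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.statistic == 4.5  # n1*n2/2

    def test_fully_separated_exact_p(self):
        # all C(6,3)=20 labelings; the observed split is one of 2 extremes
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(0.1, abs=1e-12)

    def test_exact_branch_matches_enumeration(self, rng):
        for _ in range(20):
            n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 9))
            pooled = rng.normal(size=n1 + n2)
            a, b = pooled[:n1], pooled[n1:]
            res = mann_whitney(a, b)
            assert res.method == "exact"
            # enumeration oracle: U statistic for every group labeling
            u_obs = sum(1 for x in a for y in b if x > y)
            us = []
            idx = range(n1 + n2)
            for comb in combinations(idx, n1):
                grp = set(comb)
                aa = pooled[list(comb)]
                bb = pooled[[i for i in idx if i not in grp]]
                us.append(sum(1 for x in aa for y in bb if x > y))
            us = np.asarray(us)
            mu = n1 * n2 / 2
            p_exact = np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)
            assert res.pvalue == pytest.approx(p_exact, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney([], [1.0])

    def test_exact_and_asymptotic_agree_at_branch_boundary(self, rng):
        # min(n) = 8 sits on the exact side; the continuity-corrected
        # normal approximation tracks it closely there (worst case just
        # above 0.01 at n1 = n2 = 8, typically a few thousandths)
        from scipy import stats

        diffs = []
        for _ in range(200):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            p_exact = mann_whitney(a, b).pvalue
            p_asym = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
            diffs.append(abs(p_exact - p_asym))
        assert max(diffs) < 0.015
        assert np.median(diffs) < 0.01

    def test_wilcoxon_exact_matches_scipy_on_tie_free_data(self, rng):
        from scipy import stats

        for _ in range(30):
            n = int(rng.integers(4, 14))
            d = rng.normal(size=n)
            res = wilcoxon_paired(d, np.zeros(n))
            ref = stats.wilcoxon(d, alternative="two-sided", method="exact")
            assert res.pvalue == pytest.approx(float(ref.pvalue), abs=1e-12)
            assert res.statistic == pytest.approx(float(ref.statistic), abs=1e-12)


class TestWilcoxon:
    def test_constant_shift_exact_p(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = wilcoxon_paired(a + 1.0, a)
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(0.03125, abs=1e-12)  # 2/2^6

    def test_swap_preserves_p(self, rng):
        a = rng.normal(size=10)
        b = a + rng.normal(size=10)
        r1 = wilcoxon_paired(a, b)
        r2 = wilcoxon_paired(b, a)
        assert r1.pvalue == pytest.approx(r2.pvalue, abs=1e-12)

    def test_exact_branch_matches_sign_enumeration(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 9))
            d = rng.normal(size=n)
            res = wilcoxon_paired(d, np.zeros(n))
            assert res.method == "exact"
            # enumeration over all 2^n sign assignments of |d| ranks
            from scipy.stats import rankdata

            ranks = rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            tot = ranks.sum()
            ws = []
            for bits in range(2**n):
                w = sum(ranks[i] for i in range(n) if bits >> i & 1)
                ws.append(w)
            ws = np.asarray(ws)
            p = np.mean(np.minimum(ws, tot - ws) <= min(w_obs, tot - w_obs) + 1e-12)
            assert res.pvalue == pytest.approx(min(1.0, p), abs=1e-12)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_paired([1.0, 2.0], [1.0, 2.0])


class TestKruskalDunn:
    def test_shifted_group_has_smallest_adjusted_p(self, rng):
        g1 = rng.normal(0, 1, size=12)
        g2 = rng.normal(0, 1, size=12)
        g3 = rng.normal(4, 1, size=12)
        res = kruskal_dunn([g1, g2, g3], labels=["a", "b", "c"])
        assert res.p_omnibus < 0.01
        tab = res.pairwise.set_index(["group_a", "group_b"])
        assert tab.loc[("a", "c"), "p_adjusted"] < tab.loc[("a", "b"), "p_adjusted"]
        assert tab.loc[("b", "c"), "p_adjusted"] < tab.loc[("a", "b"), "p_adjusted"]

    def test_two_group_call_orders_like_mann_whitney(self, rng):
        # rank ordering of p-values across datasets agrees between the
        # two-group degenerate call and the Mann-Whitney test
        p_dunn, p_mw = [], []
        for _ in range(12):
            a = rng.normal(0, 1, size=9)
            b = rng.normal(rng.uniform(0, 2), 1, size=9)
            p_dunn.append(kruskal_dunn([a, b]).pairwise["p_raw"][0])
            p_mw.append(mann_whitney(a, b).pvalue)
        assert np.array_equal(np.argsort(p_dunn), np.argsort(p_mw))

    def test_null_raw_pvalues_roughly_uniform(self, rng):
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            groups = [rng.normal(size=8) for _ in range(3)]
            tab = kruskal_dunn(groups).pairwise
            hits += int((tab["p_raw"] < 0.05).sum())
        frac = hits / (3 * n_rep)
        assert 0.02 < frac < 0.08

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            kruskal_dunn([[1.0, 2.0], []])

    def test_bonferroni_never_below_raw(self, rng):
        groups = [rng.normal(size=6) for _ in range(4)]
        tab = kruskal_dunn(groups).pairwise
        assert np.all(tab["p_adjusted"] >= tab["p_raw"] - 1e-15)
        assert np.all(tab["p_adjusted"] <= 1.0)


class TestMonotoneInvariance:
    def test_rank_tests_invariant_under_monotone_transform(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(1, 1, size=10)
        f = lambda x: np.exp(3 * x) + 5  # strictly monotone
        r1, r2 = mann_whitney(a, b), mann_whitney(f(a), f(b))
        assert r1.statistic == r2.statistic
        assert r1.pvalue == pytest.approx(r2.pvalue, abs=1e-12)
        k1 = kruskal_dunn([a, b, rng.normal(size=10)])
        # note: kruskal on transformed data needs the same third group
        # transformed as well, so regenerate deterministically
        rng2 = np.random.default_rng(99)
        c = rng2.normal(size=10)
        k1 = kruskal_dunn([a, b, c])
        k2 = kruskal_dunn([f(a), f(b), f(c)])
        assert k1.h_statistic == pytest.approx(k2.h_statistic, abs=1e-12)
        assert np.allclose(k1.pairwise["z"], k2.pairwise["z"])
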