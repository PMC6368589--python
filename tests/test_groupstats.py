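"""Group statistics against hand formulas and exhaustive enumerations."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from spinecoupling import (
    SpineRecord,
    ancova_compare,
    kruskal_dunn,
    loglog_fit,
    mann_whitney,
    ratio_metrics,
    relative_change,
    spearman_global,
    summarize,
    t_test_unpaired,
    volume_histogram,
)


def spine(v, a, vp=None, ser=False, condition="control", i=0):
    return SpineRecord(
        id=f"r{i}", sample_id="s1", condition=condition,
        volume=v, psd_area=a, psd_core_volume=vp if vp is not None else a * 0.03,
        has_ser=ser,
    )


class TestMannWhitney:
    def test_identical_samples_u_is_half_product(self):
        res = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.U == pytest.approx(8.0)  # n1*n2/2

    def test_complete_separation(self):
        res = mann_whitney([1, 2, 3], [10, 11, 12])
        assert {res.U, res.U_other} == {0.0, 9.0}

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney([], [1.0])

    def test_exact_p_matches_enumeration(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=6) + 0.8
        res = mann_whitney(a, b)
        assert res.method == "exact"
        ranks = stats.rankdata(np.concatenate([a, b]))
        u_obs = ranks[:6].sum() - 6 * 7 / 2
        mid = 6 * 6 / 2
        us = np.array(
            [
                ranks[list(comb)].sum() - 6 * 7 / 2
                for comb in itertools.combinations(range(12), 6)
            ]
        )
        p_exact = np.mean(np.abs(us - mid) >= abs(u_obs - mid) - 1e-12)
        assert res.p == pytest.approx(p_exact)


class TestTTest:
    def test_df_for_four_slices_per_group(self, rng):
        res = t_test_unpaired(rng.normal(size=4), rng.normal(size=4))
        assert res.df == 6

    def test_equal_samples_give_zero_t(self):
        res = t_test_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_textbook_values(self):
        res = t_test_unpaired([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == 4


class TestLogLogFit:
    def test_exact_power_law(self):
        x = np.array([0.1, 0.5, 1.0, 2.0, 7.0])
        fit = loglog_fit(x, 10 * x**2)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-12)

    def test_residual_ss_matches_brute_force(self, rng):
        x = rng.uniform(0.05, 2.0, 40)
        y = 2 * x**1.3 * np.exp(rng.normal(0, 0.2, 40))
        fit = loglog_fit(x, y)
        pred = fit.slope * np.log10(x) + fit.intercept
        assert fit.residual_ss == pytest.approx(
            float(((np.log10(y) - pred) ** 2).sum())
        )

    def test_outlier_moves_slope(self, rng):
        x = rng.uniform(0.05, 2.0, 30)
        y = x**1.0
        y_out = y.copy()
        y_out[0] *= 50
        assert loglog_fit(x, y_out).slope != pytest.approx(loglog_fit(x, y).slope)

    def test_nonpositive_value_names_index(self):
        with pytest.raises(ValueError, match="index 1"):
            loglog_fit([1.0, -1.0, 2.0], [1.0, 1.0, 1.0])


class TestAncova:
    def test_df_match_group_sizes(self, rng):
        x1, x2 = rng.uniform(0.1, 1, 119), rng.uniform(0.1, 1, 138)
        res = ancova_compare(x1, x1**1.1, x2, x2**1.3)
        assert res.df_slope == (1, 253)
        assert res.df_elev == (1, 254)

    def test_duplicated_dataset_gives_zero_slope_f(self, rng):
        x = rng.uniform(0.1, 1, 50)
        y = x**1.2 * np.exp(rng.normal(0, 0.1, 50))
        res = ancova_compare(x, y, x, y)
        assert res.F_slope == pytest.approx(0.0, abs=1e-9)

    def test_null_data_not_flagged(self, rng):
        x1, x2 = rng.uniform(0.1, 1, 100), rng.uniform(0.1, 1, 100)
        noise = rng.normal(0, 0.1, 200)
        y1 = 10 ** (1.2 * np.log10(x1) + noise[:100])
        y2 = 10 ** (1.2 * np.log10(x2) + noise[100:])
        res = ancova_compare(x1, y1, x2, y2)
        assert res.p_slope > 0.05
        assert res.slopes_homogeneous

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="x-variance"):
            ancova_compare([1, 1, 1], [1, 2, 3], [1, 2, 3], [1, 2, 3])


class TestSpearmanGlobal:
    def test_perfect_monotone(self):
        rho, _ = spearman_global([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_global([1, 2, 3, 4], [40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_exact_p_matches_permutation_enumeration(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        rho, p = spearman_global(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        rhos = []
        for perm in itertools.permutations(range(5)):
            rhos.append(np.corrcoef(rx, ry[list(perm)])[0, 1])
        p_exact = np.mean(np.abs(rhos) >= abs(rho) - 1e-12)
        assert p == pytest.approx(p_exact)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_global([1, 1, 1], [1, 2, 3])


class TestKruskalDunn:
    def test_identical_groups(self):
        res = kruskal_dunn([[1, 2, 3]] * 4)
        assert res.H == pytest.approx(0.0, abs=1e-9)

    def test_all_identical_values(self):
        res = kruskal_dunn([[2.0, 2.0], [2.0, 2.0], [2.0]])
        assert res.H == 0.0 and res.p == 1.0

    def test_dunn_z_matches_hand_formula(self, rng):
        groups = [rng.integers(0, 8, size=n).astype(float) for n in (9, 12, 7)]
        res = kruskal_dunn(groups)
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)
        n_total = pooled.size
        _, counts = np.unique(pooled, return_counts=True)
        tie = float(np.sum(counts**3 - counts)) / (12 * (n_total - 1))
        bounds = np.cumsum([0] + [g.size for g in groups])
        mean_ranks = [ranks[bounds[i]: bounds[i + 1]].mean() for i in range(3)]
        for comp in res.comparisons:
            se = math.sqrt(
                (n_total * (n_total + 1) / 12 - tie)
                * (1 / groups[comp.i].size + 1 / groups[comp.j].size)
            )
            z_hand = (mean_ranks[comp.i] - mean_ranks[comp.j]) / se
            assert comp.z == pytest.approx(z_hand)

    def test_singleton_group_warns(self):
        with pytest.warns(UserWarning, match="singleton"):
            kruskal_dunn([[1.0, 2.0], [3.0, 4.0], [5.0]])


class TestSpineMetrics:
    def test_ratios(self):
        frame = ratio_metrics([spine(0.1, 0.05, vp=0.005), spine(0.2, 0.05, vp=0.01, i=1)])
        assert frame["area_ratio_per_um"].iloc[0] == pytest.approx(0.5)
        assert frame["core_ratio"].iloc[1] == pytest.approx(0.05)

    def test_ratio_linearity(self):
        lo = ratio_metrics([spine(0.1, 0.05)])["area_ratio_per_um"].iloc[0]
        hi = ratio_metrics([spine(0.1, 0.10)])["area_ratio_per_um"].iloc[0]
        assert hi == pytest.approx(2 * lo)

    def test_relative_change_against_stratum_median(self):
        control = [
            spine(0.1, 0.05, i=1), spine(0.2, 0.05, i=2), spine(0.3, 0.05, i=3),
            spine(0.2, 0.05, ser=True, i=4), spine(0.4, 0.05, ser=True, i=5),
        ]
        cltp = [
            spine(0.2, 0.05, condition="cltp", i=6),  # = control no-SER median
            spine(0.6, 0.05, ser=True, condition="cltp", i=7),  # 2× SER median
        ]
        res = relative_change(cltp, control, attribute="volume")
        by = res.per_spine.set_index("stratum")["relative_value"]
        assert by["no_ser"] == pytest.approx(1.0)
        assert by["ser"] == pytest.approx(2.0)

    def test_relative_change_empty_stratum_rejected(self):
        control = [spine(0.1, 0.05, i=1), spine(0.2, 0.05, i=2)]
        cltp = [spine(0.2, 0.05, condition="cltp", i=3)]
        with pytest.raises(ValueError, match="stratum"):
            relative_change(cltp, control)

    def test_volume_histogram(self):
        records = [spine(0.01, 0.05, i=1), spine(0.02, 0.05, i=2),
                   spine(0.07, 0.05, i=3)]
        hist = volume_histogram(records)
        assert hist["frequency_pct"].iloc[0] == pytest.approx(200 / 3)
        assert hist["frequency_pct"].iloc[1] == pytest.approx(100 / 3)
        assert hist["frequency_pct"].sum() == pytest.approx(100.0)

    def test_histogram_matches_naive_binning(self, rng):
        volumes = rng.uniform(0.005, 0.6, 200)
        records = [spine(v, 0.05, i=i) for i, v in enumerate(volumes)]
        hist = volume_histogram(records, bin_width=0.05)
        for _, row in hist.iterrows():
            naive = sum(
                1 for v in volumes if row["bin_lo_um3"] <= v < row["bin_hi_um3"]
            )
            assert row["count"] == naive


class TestSummarize:
    def test_small_sample(self):
        s = summarize([1, 2, 3])
        assert s.mean == pytest.approx(2.0)
        assert s.median == pytest.approx(2.0)
        assert s.sem == pytest.approx(0.5774, abs=1e-4)

    def test_constant_sample(self):
        s = summarize([4.0, 4.0, 4.0])
        assert s.sem == 0.0 and s.iqr == 0.0

    def test_iqr_matches_quantile_oracle(self, rng):
        v = rng.normal(size=1000)
        s = summarize(v)
        assert s.iqr == pytest.approx(
            np.percentile(v, 75) - np.percentile(v, 25)
        )
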