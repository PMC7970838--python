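"""Survey statistics: densities, ANOVA/Tukey, correlations, leverage, overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from driftquant.errors import DataError
from driftquant.surveys import (
    CorrelationResult,
    PlanktonStation,
    TrawlStation,
    VisualRecord,
    larval_density,
    leverage,
    log_copies,
    overlap_summary,
    pearson_predictor_cor,
    schoeners_d,
    simulate_anova_rejection_rate,
    station_anova,
    swept_area_density,
    tukey_hsd,
    visual_vs_molecular,
)


class TestDensities:
    def test_larval_density_per_10m3(self):
        st_ = PlanktonStation("A", 10.0, 68.0, "2017-06-12", 50, 100.0)
        assert larval_density(st_) == 5.0

    def test_zero_larvae_zero_density(self):
        st_ = PlanktonStation("A", 10.0, 68.0, "2017-06-12", 0, 250.0)
        assert larval_density(st_) == 0.0

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            PlanktonStation("A", 10.0, 68.0, "2017-06-12", 10, 0.0)

    def test_swept_area_density(self):
        st_ = TrawlStation("A", 10.0, 68.0, "2017-06-12", 100.0, 1.0, 0.01)
        assert swept_area_density(st_) == 10_000.0

    def test_zero_catch_zero_density(self):
        st_ = TrawlStation("A", 10.0, 68.0, "2017-06-12", 0.0, 2.0, 0.01)
        assert swept_area_density(st_) == 0.0

    def test_bad_tow_geometry_rejected(self):
        with pytest.raises(ValueError):
            TrawlStation("A", 10.0, 68.0, "2017-06-12", 10.0, 0.0, 0.01)


class TestStationAnova:
    def _data(self, k=4, n=8, effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        stations = np.repeat([f"S{i}" for i in range(k)], n)
        mu = rng.normal(0, effect, size=k) if effect else np.zeros(k)
        y = 10 ** (6 + np.repeat(mu, n) + rng.normal(0, 0.5, k * n)) - 1
        return y, stations

    def test_identical_means_give_f_near_zero(self):
        y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        s = np.array(["A"] * 3 + ["B"] * 3)
        res = station_anova(10**y - 1, s)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-9)

    def test_df_bookkeeping(self):
        # 11 stations, 84 stomachs: df = (10, 73)
        rng = np.random.default_rng(1)
        sizes = [8] * 7 + [7] * 4  # 84 total over 11 stations
        stations = np.concatenate([[f"S{i}"] * n for i, n in enumerate(sizes)])
        y = rng.lognormal(10, 1, size=84)
        res = station_anova(y, stations)
        assert (res.df_between, res.df_within) == (10, 73)

    def test_response_is_log10_plus_one(self):
        y, s = self._data()
        res1 = station_anova(y, s)
        # multiplying the log-scale response by adding a constant:
        # (10^(log10(y+1)+c)) - 1 shifts every log response by exactly c
        shifted = 10 ** (np.log10(np.asarray(y) + 1) + 2.0) - 1
        res2 = station_anova(shifted, s)
        assert res2.F == pytest.approx(res1.F, rel=1e-9)

    def test_all_identical_values_error(self):
        with pytest.raises(DataError):
            station_anova([5.0] * 8, ["A"] * 4 + ["B"] * 4)

    def test_single_observation_station_excluded_with_warning(self):
        y, s = self._data(k=3)
        y = np.append(y, 100.0)
        s = np.append(s, "lonely")
        with pytest.warns(UserWarning, match="lonely"):
            res = station_anova(y, s)
        assert res.diagnostics["k"] == 3

    def test_fewer_than_two_stations_error(self):
        with pytest.raises(DataError):
            station_anova([1.0, 2.0, 3.0], ["A", "A", "A"])

    def test_tukey_matrix_symmetric(self):
        y, s = self._data(k=5, effect=0.5, seed=3)
        res = station_anova(y, s)
        m = res.tukey_p.to_numpy()
        assert np.allclose(m, m.T, equal_nan=True)
        assert np.all(np.isnan(np.diag(m)))

    def test_two_group_tukey_equals_anova_p(self):
        y, s = self._data(k=2, effect=0.4, seed=4)
        res = station_anova(y, s)
        assert res.tukey_p.iloc[0, 1] == pytest.approx(res.p, abs=1e-6)

    def test_tukey_agrees_with_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        y, s = self._data(k=4, effect=0.6, seed=5)
        res = station_anova(y, s)
        from itertools import combinations

        sm = pairwise_tukeyhsd(log_copies(y), s)
        pairs = list(combinations(sm.groupsunique, 2))
        ours = [res.tukey_p.loc[g1, g2] for g1, g2 in pairs]
        assert np.allclose(ours, sm.pvalues, atol=2e-3)

    def test_type_one_error_calibrated(self):
        rate = simulate_anova_rejection_rate(n_sims=2000, station_sd=0.0, seed=7)
        assert 0.03 <= rate <= 0.07

    def test_power_under_tenfold_station_effect(self):
        rate = simulate_anova_rejection_rate(n_sims=500, station_sd=0.5,
                                             noise_sd=0.5, seed=8)
        assert rate > 0.9


class TestCorrelation:
    def test_collinear_data_r_one(self):
        x = np.arange(10.0)
        res = pearson_predictor_cor(2 * x + 1, x)
        assert res.r == pytest.approx(1.0)

    def test_df_is_n_minus_2(self):
        rng = np.random.default_rng(0)
        res = pearson_predictor_cor(rng.normal(size=90), rng.normal(size=90))
        assert res.df == 88

    def test_t_statistic_relation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        res = pearson_predictor_cor(y, x, "x")
        assert res.t == pytest.approx(res.r * np.sqrt(res.df) / np.sqrt(1 - res.r**2))

    def test_p_value_matches_permutation_null(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = 0.4 * x + rng.normal(size=30)
        res = pearson_predictor_cor(y, x)
        perm = stats.permutation_test(
            (x, y), lambda a, b: stats.pearsonr(a, b).statistic,
            permutation_type="pairings", n_resamples=10_000,
            alternative="two-sided", rng=np.random.default_rng(3),
        )
        se = np.sqrt(res.p * (1 - res.p) / 10_000)
        assert abs(perm.pvalue - res.p) < max(5 * se, 0.01)

    def test_constant_predictor_rejected(self):
        with pytest.raises(DataError):
            pearson_predictor_cor([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_too_few_observations_rejected(self):
        with pytest.raises(DataError):
            pearson_predictor_cor([1.0, 2.0], [1.0, 2.0])


class TestLeverage:
    def test_leverage_sums_to_two(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=25)
        assert leverage(x).sum() == pytest.approx(2.0)

    def test_matches_full_hat_matrix(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=15)
        X = np.column_stack([np.ones_like(x), x])
        H = X @ np.linalg.solve(X.T @ X, X.T)
        assert np.allclose(leverage(x), np.diag(H))

    def test_constant_predictor_rejected(self):
        with pytest.raises(DataError):
            leverage(np.ones(5))

    def test_extreme_point_flagged_high_leverage(self):
        visual = [VisualRecord("A", f"s{i}", 0, 0) for i in range(9)]
        visual.append(VisualRecord("I", "s9", 19, 12))  # one dominant stomach
        copies = {f"s{i}": float(i) for i in range(9)}
        copies["s9"] = 9e8
        out = visual_vs_molecular(visual, copies)
        tab = out["table"].set_index("stomach")
        assert tab.loc["s9", "high_leverage"]
        assert tab.loc["s9", "leverage"] > 0.843
        assert not tab.drop("s9")["high_leverage"].any()

    def test_empty_join_rejected(self):
        with pytest.raises(DataError):
            visual_vs_molecular([VisualRecord("A", "s1", 1, 0)], {"other": 1.0})


class TestOverlap:
    def test_disjoint_distributions_d_zero(self):
        assert schoeners_d([1, 0, 0], [0, 0, 1]) == pytest.approx(0.0)

    def test_identical_distributions_d_one(self):
        assert schoeners_d([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]) == pytest.approx(1.0)

    def test_three_cell_hand_computation(self):
        # p = (.5,.3,.2), q = (.2,.3,.5): D = 1 - .5(.3 + 0 + .3) = 0.7
        assert schoeners_d([0.5, 0.3, 0.2], [0.2, 0.3, 0.5]) == pytest.approx(0.7)

    def test_normalisation_is_internal(self):
        assert schoeners_d([5, 3, 2], [2, 3, 5]) == pytest.approx(0.7)

    def test_summary_joins_on_station(self):
        tab = overlap_summary({"A": 5.0, "B": 1.0}, {"A": 100.0}, {"A": 1e6, "B": 2e6})
        assert list(tab.index) == ["A", "B"]
        assert np.isnan(tab.loc["B", "mackerel_density"])

    def test_no_common_keys_rejected(self):
        with pytest.raises(DataError):
            overlap_summary({"A": 1.0}, {"B": 1.0}, {"C": 1.0})


def test_tukey_hsd_direct_two_groups_matches_t_test():
    rng = np.random.default_rng(6)
    a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 12)
    p_tukey = tukey_hsd({"a": a, "b": b}).loc["a", "b"]
    p_t = stats.ttest_ind(a, b).pvalue
    assert p_tukey == pytest.approx(p_t, abs=1e-6)
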