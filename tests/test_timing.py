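"""Timing inference: mixed-model marginal means, latitude regressions, arrival
estimators and maximally selected cutpoints."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from marshwave import timing as tm


def simulate_records(rng, site_means=(127.0, 139.0, 146.0), n_per_site=(8, 6, 7),
                     n_repeat=(3, 2, 2), sd_indiv=2.0, sd_resid=3.0):
    rows = []
    for s, (mu, n, nrep) in enumerate(zip(site_means, n_per_site, n_repeat)):
        for i in range(n):
            u = rng.normal(0, sd_indiv)
            for _y in range(2 if i < nrep else 1):
                rows.append({"individual_id": f"s{s}_i{i}", "site": f"site{s}",
                             "doy": mu + u + rng.normal(0, sd_resid)})
    return pd.DataFrame(rows)


def statsmodels_marginal_means(df):
    import statsmodels.api as sm

    X = pd.get_dummies(df["site"]).astype(float)
    md = sm.MixedLM(df["doy"], X, groups=df["individual_id"])
    res = md.fit(reml=True, method="powell", maxiter=5000)
    # second refinement pass: powell alone can stall ~1e-5 short of the optimum
    res = md.fit(reml=True, method="nm", maxiter=5000,
                 start_params=res.params_object, xtol=1e-12, ftol=1e-12)
    return res.params[: X.shape[1]].to_numpy()


class TestRandomIntercept:
    def test_balanced_single_records_reduce_to_group_means(self):
        rng = np.random.default_rng(0)
        rows = [{"individual_id": f"{s}{i}", "site": s, "doy": float(rng.normal(100 + 10 * j, 3))}
                for j, s in enumerate("AB") for i, s2 in enumerate([s] * 6) for _ in [0]]
        df = pd.DataFrame(rows)
        est, _vc = tm.fit_random_intercept(df)
        for _i, row in est.iterrows():
            grp = df[df["site"] == row["site"]]["doy"]
            assert row["marginal_mean"] == pytest.approx(grp.mean(), abs=1e-8)

    def test_matches_reference_mixed_model_implementation(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            df = simulate_records(rng)
            est, _vc = tm.fit_random_intercept(df)
            ref = statsmodels_marginal_means(df)
            assert np.max(np.abs(est["marginal_mean"].to_numpy() - ref)) < 1e-6

    def test_duplicated_records_match_reference_implementation(self):
        # duplication legitimately reweights a REML mixed model (cluster sizes
        # double while the variance ratio re-balances), so the check is
        # agreement with the reference fit on the duplicated data
        rng = np.random.default_rng(5)
        df = pd.concat([simulate_records(rng)] * 2, ignore_index=True)
        est, _ = tm.fit_random_intercept(df)
        ref = statsmodels_marginal_means(df)
        assert np.max(np.abs(est["marginal_mean"].to_numpy() - ref)) < 1e-6

    def test_single_site_returns_plain_mean_with_warning(self):
        df = pd.DataFrame({"individual_id": list("abcd"), "site": "only",
                           "doy": [100.0, 102.0, 104.0, 106.0]})
        with pytest.warns(UserWarning):
            est, _vc = tm.fit_random_intercept(df)
        assert est["marginal_mean"].iloc[0] == pytest.approx(103.0)
        assert est["se"].iloc[0] == pytest.approx(np.std([100, 102, 104, 106], ddof=1) / 2)


class TestLatitudeRegression:
    def test_collinear_points_give_r2_one(self):
        df = pd.DataFrame({"latitude": [39.0, 41.0, 43.0], "marginal_mean": [100.0, 110.0, 120.0]})
        res = tm.latitude_regression(df)
        assert res["r2"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(5.0)

    def test_published_breeding_arrival_gradient_matches_normal_equations(self):
        # geolocator-study breeding-arrival marginal means at the three site groups
        lats = np.array([39.2, 41.38, 43.03])
        means = np.array([107.1, 121.2, 127.0])
        res = tm.latitude_regression(pd.DataFrame({"latitude": lats, "marginal_mean": means}))
        slope_oracle = (np.sum((lats - lats.mean()) * (means - means.mean()))
                        / np.sum((lats - lats.mean()) ** 2))
        assert res["slope"] == pytest.approx(slope_oracle, abs=1e-12)
        assert res["r2"] > 0.95

    def test_translation_changes_intercept_only(self):
        df = pd.DataFrame({"latitude": [39.0, 41.0, 43.0, 45.0],
                           "marginal_mean": [100.0, 111.0, 118.0, 131.0]})
        a = tm.latitude_regression(df)
        df2 = df.assign(marginal_mean=df["marginal_mean"] + 7.0)
        b = tm.latitude_regression(df2)
        assert b["slope"] == pytest.approx(a["slope"])
        assert b["intercept"] == pytest.approx(a["intercept"] + 7.0)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            tm.latitude_regression(pd.DataFrame({"latitude": [39.0, 41.0],
                                                 "marginal_mean": [1.0, 2.0]}))


class TestSlopeHomogeneity:
    def _series(self, slope, intercept, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        lats = np.array([32.0, 35.0, 38.0, 41.0, 44.0])
        return pd.DataFrame({"latitude": lats,
                             "marginal_mean": intercept + slope * lats + rng.normal(0, noise, 5)})

    def test_identical_slopes_zero_interaction(self):
        res = tm.slope_homogeneity(self._series(3.0, 10.0), self._series(3.0, 30.0))
        assert abs(res["interaction"]) < 1e-10

    def test_different_slopes_detected(self):
        res = tm.slope_homogeneity(self._series(3.0, 10.0, noise=0.1, seed=1),
                                   self._series(8.0, 10.0, noise=0.1, seed=2))
        assert res["interaction"] == pytest.approx(5.0, abs=0.3)
        assert res["p"] < 0.01

    def test_label_swap_flips_sign(self):
        a, b = self._series(3.0, 10.0, 0.5, 3), self._series(5.0, 20.0, 0.5, 4)
        assert tm.slope_homogeneity(a, b)["interaction"] == pytest.approx(
            -tm.slope_homogeneity(b, a)["interaction"])


class TestTailAlign:
    def test_offset_arithmetic(self):
        res = tm.tail_align_estimate([5.0, 6.0, 7.0], 10.0)
        assert res["estimate"] == pytest.approx(11.0)

    def test_earliest_at_reference_minimum_returns_reference_mean(self):
        ref = [100.0, 104.0, 112.0]
        res = tm.tail_align_estimate(ref, 100.0)
        assert res["estimate"] == pytest.approx(np.mean(ref))

    def test_nj_like_sample_span_reported(self):
        rng = np.random.default_rng(8)
        ref = rng.normal(107.1, 3.0, 20)
        ref = (ref - ref.min()) / (ref.max() - ref.min()) * 12.0 + 101.0  # observed span 12 d
        res = tm.tail_align_estimate(ref, 95.0)
        assert res["reference_span"] == pytest.approx(12.0)
        assert res["estimate"] - 95.0 == pytest.approx(ref.mean() - ref.min())

    @given(k=st.floats(-50, 50))
    def test_shift_equivariance(self, k):
        ref = np.array([100.0, 104.0, 112.0])
        base = tm.tail_align_estimate(ref, 98.0)["estimate"]
        shifted = tm.tail_align_estimate(ref + k, 98.0 + k)["estimate"]
        assert shifted == pytest.approx(base + k, abs=1e-9)

    def test_short_reference_rejected(self):
        with pytest.raises(ValueError):
            tm.tail_align_estimate([1.0, 2.0], 5.0)


class TestArrivalFromObservations:
    def test_uniform_observations_cross_two_percent_on_day_two(self):
        df = pd.DataFrame({"doy": np.arange(1, 101), "n_reporting": 1})
        res = tm.arrival_from_observations(df, fraction=0.02, season_window=(1, 100))
        assert res["arrival_doy"].iloc[0] == 2.0

    def test_point_mass_returns_that_day(self):
        df = pd.DataFrame({"doy": np.arange(1, 101), "n_reporting": 0})
        df.loc[df["doy"] == 57, "n_reporting"] = 40
        res = tm.arrival_from_observations(df, season_window=(1, 100))
        assert res["arrival_doy"].iloc[0] == 57.0

    def test_invariant_to_count_scaling(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"doy": np.arange(30, 180),
                           "n_reporting": rng.poisson(5, 150) + 1})
        a = tm.arrival_from_observations(df, season_window=(30, 179))
        df5 = df.assign(n_reporting=df["n_reporting"] * 5)
        b = tm.arrival_from_observations(df5, season_window=(30, 179))
        assert a["arrival_doy"].iloc[0] == b["arrival_doy"].iloc[0]

    def test_between_year_se(self):
        df = pd.concat([
            pd.DataFrame({"year": y, "doy": np.arange(1, 101), "n_reporting": 1})
            for y in (1, 2, 3)
        ])
        df.loc[(df["year"] == 2) & (df["doy"] < 5), "n_reporting"] = 0
        res = tm.arrival_from_observations(df, season_window=(1, 100))
        assert res["n_years"].iloc[0] == 3
        assert res["se"].iloc[0] > 0


def brute_force_maxstat(x, y, min_prop=0.1):
    """Exhaustive enumeration over all admissible two-group partitions."""
    n = len(x)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    ybar, ssy = ys.mean(), ((ys - ys.mean()) ** 2).sum()
    best_cut, best_t = None, -np.inf
    for k in range(1, n):
        if xs[k - 1] == xs[k] or k < min_prop * n or n - k < min_prop * n:
            continue
        S, E = ys[:k].sum(), k * ybar
        V = k * (n - k) / (n * (n - 1)) * ssy
        t = abs((S - E) / np.sqrt(V))
        if t > best_t + 1e-15:
            best_cut, best_t = (xs[k - 1] + xs[k]) / 2.0, t
    return best_cut, best_t


class TestMaxstat:
    def test_constant_response_gives_zero_statistic(self):
        x = np.linspace(31, 45, 12)
        res = tm.maxstat_cutpoint(x, np.full(12, 3.0), n_perm=99, seed=0)
        assert res.t_max == 0.0 and res.p_perm == 1.0

    def test_exact_match_with_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.uniform(31, 45, 12)
            y = rng.integers(0, 10, 12).astype(float)
            res = tm.maxstat_cutpoint(x, y, n_perm=0)
            cut, t = brute_force_maxstat(x, y)
            assert res.t_max == pytest.approx(t, abs=1e-12)
            assert res.cutpoint == pytest.approx(cut, abs=1e-12)

    def test_clear_step_found_with_significant_p(self):
        rng = np.random.default_rng(2)
        x = np.linspace(32, 44, 30)
        y = np.where(x < 36.0, 12.0, 3.9) + rng.normal(0, 1.0, 30)
        res = tm.maxstat_cutpoint(x, y, n_perm=999, seed=5)
        assert abs(res.cutpoint - 36.0) < (44 - 32) / 29 + 1e-9
        assert res.p_perm < 0.01
        assert res.mean_below == pytest.approx(12.0, abs=1.5)
        assert res.mean_above == pytest.approx(3.9, abs=1.5)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            tm.maxstat_cutpoint(np.arange(5), np.arange(5))
        with pytest.raises(ValueError):
            tm.maxstat_cutpoint(np.arange(12), np.arange(12), min_prop=0.6)
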