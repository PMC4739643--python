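"""Step construction, random-step kernel, conditional logit, validation."""

import numpy as np
import pandas as pd
import pytest

from energyscape.ssf import (
    _wrap_angle,
    draw_random_steps,
    estimate_kernel,
    fit_conditional_logit,
    make_steps,
    predict_suitability,
    validate_split,
    attach_endpoint_covariates,
)
from energyscape.synthetic import simulate_choice_steps, simulate_ssf_track

T0 = pd.Timestamp("2021-03-01 00:00:00+00:00")


def track_from_points(points, minutes=10):
    return pd.DataFrame(
        {
            "timestamp": [T0 + pd.Timedelta(minutes=minutes * i) for i in range(len(points))],
            "x": [p[0] for p in points],
            "y": [p[1] for p in points],
        }
    )


class TestMakeSteps:
    def test_collinear_zero_angles(self):
        tr = track_from_points([(0, 0), (100, 0), (200, 0), (300, 0)])
        st = make_steps(tr)
        np.testing.assert_allclose(st["turning_angle"].iloc[1:], 0.0, atol=1e-12)
        assert np.isnan(st["turning_angle"].iloc[0])

    def test_right_angle(self):
        tr = track_from_points([(0, 0), (100, 0), (100, 100)])
        st = make_steps(tr)
        assert abs(st["turning_angle"].iloc[1]) == pytest.approx(np.pi / 2)

    def test_speed_hand_computed(self):
        tr = track_from_points([(0, 0), (300, 400), (300, 1000)], minutes=10)
        st = make_steps(tr)
        assert st["step_length"].iloc[0] == pytest.approx(500.0)
        assert st["speed"].iloc[0] == pytest.approx(500.0 / 600.0)
        assert st["speed"].iloc[1] == pytest.approx(1.0)

    def test_duplicate_timestamps_rejected(self):
        tr = track_from_points([(0, 0), (1, 1), (2, 2)])
        tr.loc[1, "timestamp"] = tr.loc[0, "timestamp"]
        with pytest.raises(ValueError):
            make_steps(tr)


def synthetic_steps(rng, n=200, mean=(0.5, 0.0), cov=((0.12**2, 0.0), (0.0, 0.8**2))):
    sp_ang = rng.multivariate_normal(mean, cov, n)
    sp_ang[sp_ang[:, 0] <= 0, 0] = 0.01
    return pd.DataFrame(
        {
            "start_x": rng.uniform(0, 1000, n),
            "start_y": rng.uniform(0, 1000, n),
            "end_x": 0.0,
            "end_y": 0.0,
            "dt": 600.0,
            "step_length": sp_ang[:, 0] * 600.0,
            "speed": sp_ang[:, 0],
            "prev_bearing": rng.uniform(-np.pi, np.pi, n),
            "turning_angle": sp_ang[:, 1],
        }
    )


class TestDrawRandomSteps:
    def test_stratum_structure_and_determinism(self, rng):
        steps = synthetic_steps(rng)
        a = draw_random_steps(steps, K=5, seed=3)
        b = draw_random_steps(steps, K=5, seed=3)
        pd.testing.assert_frame_equal(a, b)
        counts = a.groupby("stratum_id")["observed"].agg(["sum", "count"])
        assert (counts["sum"] == 1).all() and (counts["count"] == 6).all()

    def test_moments_match_fitted_kernel(self, rng):
        steps = synthetic_steps(rng, n=500)
        mean, cov = estimate_kernel(steps)
        strata = draw_random_steps(steps, K=20, seed=5)
        rnd = strata.loc[~strata["observed"]]
        sp = rnd["step_length"].to_numpy() / rnd["dt"].to_numpy()
        ang = rnd["turning_angle"].to_numpy()
        assert len(sp) >= 10**4
        assert sp.mean() == pytest.approx(mean[0], rel=0.02)
        assert ang.std() == pytest.approx(np.sqrt(cov[1, 1]), rel=0.02)
        assert sp.std() == pytest.approx(np.sqrt(cov[0, 0]), rel=0.05)

    def test_degenerate_speed_variance(self, rng):
        steps = synthetic_steps(rng, cov=((0.0, 0.0), (0.0, 0.5**2)))
        steps["speed"] = 0.5
        steps["step_length"] = 300.0
        with pytest.warns(UserWarning, match="singular"):
            strata = draw_random_steps(steps, K=3, seed=1)
        rnd = strata.loc[~strata["observed"], "step_length"]
        np.testing.assert_allclose(rnd, 300.0, rtol=1e-3)

    def test_too_few_steps_rejected(self, rng):
        with pytest.raises(ValueError, match="10"):
            draw_random_steps(synthetic_steps(rng, n=5), K=5, seed=0)


def toy_strata():
    """Three strata, one binary covariate; observed prefers covariate=1."""
    rows = []
    pattern = [(1, [1, 0, 0]), (1, [0, 1, 0]), (0, [1, 1, 0])]
    for s, (obs_cov, rand_covs) in enumerate(pattern):
        rows.append({"stratum_id": s, "observed": True, "z": float(obs_cov)})
        for rc in rand_covs:
            rows.append({"stratum_id": s, "observed": False, "z": float(rc)})
    df = pd.DataFrame(rows)
    df["step_length"] = 1.0
    df["turning_angle"] = 0.0
    return df


def brute_force_loglik(df, beta):
    ll = 0.0
    for _, grp in df.groupby("stratum_id"):
        eta = beta * grp["z"].to_numpy()
        ll += eta[grp["observed"].to_numpy()][0] - np.log(np.exp(eta).sum())
    return ll


class TestConditionalLogit:
    def test_toy_matches_grid_search(self):
        df = toy_strata()
        with pytest.warns(UserWarning):
            fit = fit_conditional_logit(df, covariates=("z",))
        grid = np.arange(-10, 10, 1e-3)
        lls = [brute_force_loglik(df, b) for b in grid]
        beta_grid = grid[int(np.argmax(lls))]
        assert fit.betas["z"] == pytest.approx(beta_grid, abs=2e-3)
        assert fit.loglik == pytest.approx(brute_force_loglik(df, fit.betas["z"]), abs=1e-6)

    def test_stratum_constant_covariate_dropped(self):
        df = toy_strata()
        df["const_within"] = df["stratum_id"].astype(float)  # constant per stratum
        with pytest.warns(UserWarning, match="dropped"):
            fit = fit_conditional_logit(df, covariates=("z", "const_within"))
        assert "const_within" in fit.dropped
        assert "const_within" not in fit.betas.index

    def test_likelihood_invariant_to_stratum_constants(self):
        df = toy_strata()
        with pytest.warns(UserWarning):
            f0 = fit_conditional_logit(df, covariates=("z",))
        df2 = df.copy()
        df2["z"] = df2["z"] + df2["stratum_id"] * 7.0
        with pytest.warns(UserWarning):
            f1 = fit_conditional_logit(df2, covariates=("z",))
        assert f0.loglik == pytest.approx(f1.loglik, abs=1e-6)
        assert f0.betas["z"] == pytest.approx(f1.betas["z"], abs=1e-4)


class TestPredictSuitability:
    def test_flat_when_betas_zero(self, world):
        land, _ = world
        fit_zero = make_zero_fit()
        grid = predict_suitability(fit_zero, land)
        assert np.nanstd(grid) == 0.0

    def test_bounds_and_ranking(self, world):
        land, _ = world
        from energyscape.ssf import SsfFit

        fit = SsfFit(
            betas=pd.Series({"prop_urban_240": -2.0, "dist_forest_edge": 0.01}),
            ses=pd.Series({"prop_urban_240": 0.1, "dist_forest_edge": 0.001}),
            loglik=0.0,
            converged=True,
            reference_class="developed_high",
        )
        grid = predict_suitability(fit, land)
        assert np.nanmin(grid) == 0.0 and np.nanmax(grid) == 1.0
        eta = (
            -2.0 * land.layers["prop_urban_240"] + 0.01 * land.layers["dist_forest_edge"]
        )
        order_grid = np.argsort(grid, axis=None)
        order_eta = np.argsort(eta, axis=None)
        np.testing.assert_array_equal(order_grid, order_eta)


def make_zero_fit():
    from energyscape.ssf import SsfFit

    return SsfFit(
        betas=pd.Series({"prop_urban_240": 0.0}),
        ses=pd.Series({"prop_urban_240": 1.0}),
        loglik=0.0,
        converged=True,
        reference_class="developed_high",
    )


class TestValidateSplit:
    def test_habitat_biased_track_beats_random(self, world):
        land, _ = world
        tr = simulate_ssf_track(land, beta_forest=2.0, n_steps=420, seed=8)
        res = validate_split(tr, land, seed=8)
        assert res["observed_mean"] > res["random_mean"]

    def test_degenerate_split_warns(self, world):
        land, _ = world
        tr = simulate_ssf_track(land, beta_forest=0.5, n_steps=100, seed=2)
        with pytest.warns(UserWarning):
            validate_split(tr, land, train_frac=0.95, seed=2)

    def test_bad_fraction_rejected(self, world):
        land, _ = world
        tr = simulate_ssf_track(land, beta_forest=0.5, n_steps=50, seed=2)
        with pytest.raises(ValueError):
            validate_split(tr, land, train_frac=1.5)


def test_wrap_angle_range():
    a = _wrap_angle(np.array([0.0, np.pi, -np.pi, 3 * np.pi, -2.5 * np.pi]))
    assert (a > -np.pi).all() and (a <= np.pi).all()
    assert a[1] == pytest.approx(np.pi)
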