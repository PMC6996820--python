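"""Demographic maps: one-step predictions, simulation, equilibria."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import densdep as dd


class TestPredictNext:
    @pytest.mark.parametrize(
        "form, params, n, expected",
        [
            ("random_walk", {}, 0.05, 0.05),
            ("exponential", {"lambda": 2.0}, 0.01, 0.02),
            # Ricker fixed point N* = ln(lambda)/beta maps to itself
            ("ricker", {"lambda": 3.66, "beta": 19.11}, 0.067894, 0.067894),
        ],
    )
    def test_examples(self, form, params, n, expected):
        assert dd.predict_next(form, params, n) == pytest.approx(expected, abs=1e-4)

    @given(
        lam=st.floats(0.1, 10),
        beta=st.floats(-5, 50),
        n=st.floats(0, 1, exclude_min=False),
    )
    def test_theta_one_reduces_to_ricker(self, lam, beta, n):
        p = {"lambda": lam, "beta": beta}
        assert dd.predict_next("theta_logistic", {**p, "theta": 1.0}, n) == pytest.approx(
            dd.predict_next("ricker", p, n), rel=1e-12, abs=1e-300
        )

    def test_gompertz_zero_density_rejected(self):
        with pytest.raises(ValueError, match="undefined at density 0"):
            dd.predict_next("gompertz", {"lambda": 2.0, "beta": 1.0}, 0.0)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            dd.predict_next("ricker", {"lambda": 2.0, "beta": 1.0}, -0.1)

    def test_ricker_overcompensation_shape(self):
        p = {"lambda": 3.0, "beta": 20.0}
        assert dd.predict_next("ricker", p, 1e-9) < 1e-6
        assert dd.predict_next("ricker", p, 100.0) < 1e-6
        peak = dd.predict_next("ricker", p, 1 / 20.0)
        assert peak > dd.predict_next("ricker", p, 0.3)


class TestSimulateTrajectory:
    def test_noise_free_fixed_point_is_constant(self):
        nstar = math.log(3.66) / 19.11
        traj = dd.simulate_trajectory(
            "ricker", {"lambda": 3.66, "beta": 19.11}, 0.0, nstar, 10, 0
        )
        np.testing.assert_allclose(traj, nstar, rtol=1e-12)

    def test_geometric_growth(self):
        traj = dd.simulate_trajectory("exponential", {"lambda": 2.0}, 0.0, 0.01, 3, 0)
        np.testing.assert_allclose(traj, [0.01, 0.02, 0.04, 0.08], rtol=1e-12)

    @pytest.mark.parametrize("form", dd.FORMS)
    def test_same_seed_same_trajectory(self, form):
        params = {"lambda": 1.5, "beta": 10.0, "theta": 1.2}
        a = dd.simulate_trajectory(form, params, 0.05, 0.05, 30, 42)
        b = dd.simulate_trajectory(form, params, 0.05, 0.05, 30, 42)
        np.testing.assert_array_equal(a, b)
        c = dd.simulate_trajectory(form, params, 0.05, 0.05, 30, 43)
        assert not np.array_equal(a, c)

    def test_noise_free_matches_iterated_prediction(self):
        params = {"lambda": 1.4, "beta": 12.0}
        traj = dd.simulate_trajectory("ricker", params, 0.0, 0.02, 8, 0)
        n = 0.02
        for t in range(8):
            n = dd.predict_next("ricker", params, n)
            assert traj[t + 1] == pytest.approx(n, rel=1e-12)

    def test_densities_clamped_non_negative(self):
        traj = dd.simulate_trajectory("random_walk", {}, 0.5, 0.01, 200, 3)
        assert np.all(traj >= 0)
        assert np.any(traj == 0)  # large noise drives it into the clamp

    def test_trajectory_frame_long_format(self):
        from densdep.forms import trajectory_frame

        t = dd.simulate_trajectory("exponential", {"lambda": 2.0}, 0.0, 0.01, 3, 0)
        f = trajectory_frame(np.vstack([t, t]), start_year=2004)
        assert list(f.columns) == ["replicate", "year", "density"]
        assert len(f) == 8
        assert f["year"].min() == 2004 and f["year"].max() == 2007
        np.testing.assert_allclose(
            f[f["replicate"] == 1]["density"].to_numpy(), t
        )

    def test_noise_calibration(self):
        # mean of the realized increments of a RW stays within 3 sigma/sqrt(n)
        sigma, n = 0.3, 10**5
        traj = dd.simulate_trajectory("random_walk", {}, sigma, 1000.0, n, 7)
        increments = np.diff(traj)
        assert abs(increments.mean()) < 3 * sigma / math.sqrt(n)


class TestEquilibrium:
    def test_reported_protected_equilibrium(self):
        eq = dd.equilibrium_density("ricker", {"lambda": 3.66, "beta": 19.11})
        assert round(eq, 3) == 0.068

    def test_no_growth_means_no_positive_equilibrium(self):
        assert dd.equilibrium_density("ricker", {"lambda": 1.0, "beta": 5.0}) is None

    def test_gompertz_closed_form(self):
        # ln(lambda)/beta = 1 => equilibrium exp(1)
        eq = dd.equilibrium_density("gompertz", {"lambda": math.e**2, "beta": 2.0})
        assert eq == pytest.approx(math.e, rel=1e-12)

    @pytest.mark.parametrize("form", ["random_walk", "exponential"])
    def test_density_independent_forms_have_none(self, form):
        assert dd.equilibrium_density(form, {"lambda": 1.3}) is None

    @given(lam=st.floats(1.01, 20), beta=st.floats(0.1, 100))
    def test_theta_one_matches_ricker_equilibrium(self, lam, beta):
        p = {"lambda": lam, "beta": beta}
        r = dd.equilibrium_density("ricker", p)
        t = dd.equilibrium_density("theta_logistic", {**p, "theta": 1.0})
        assert t == pytest.approx(r, rel=1e-12)

    def test_equilibrium_is_fixed_point(self):
        for form, p in [
            ("ricker", {"lambda": 2.5, "beta": 30.0}),
            ("gompertz", {"lambda": 1.8, "beta": 0.4}),
            ("theta_logistic", {"lambda": 2.5, "beta": 30.0, "theta": 1.7}),
        ]:
            eq = dd.equilibrium_density(form, p)
            assert dd.predict_next(form, p, eq) == pytest.approx(eq, rel=1e-10)
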