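"""Closed forms, first-passage densities and the path simulator."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from ddmexplore import ddm_core as dc
from ddmexplore.ddm_core import (
    DDMCoefficients,
    InvalidParameterError,
    ResolvedDDM,
    UndefinedExtremumError,
)

finite_mu = st.floats(-3, 3)
finite_beta = st.floats(0.3, 3)
finite_alpha = st.floats(-0.95, 0.95)


# ----------------------------------------------------------------------
# parameter maps
# ----------------------------------------------------------------------

class TestResolveParameters:
    def test_linear_maps(self):
        c = DDMCoefficients(c0_mu=0.0, cR_mu=0.2, cI_mu=0.1, c0_beta=1.0, T0=0.3)
        r = dc.resolve_parameters(c, delta_R=5.0, delta_I=1)
        assert r.mu == pytest.approx(1.1)
        assert r.beta == pytest.approx(1.0)
        assert r.alpha == pytest.approx(0.0)  # L(0) = 1/2
        assert r.T0 == 0.3

    def test_degenerate_threshold_rejected(self):
        c = DDMCoefficients(c0_beta=0.0, T0=0.3)
        with pytest.raises(InvalidParameterError):
            dc.resolve_parameters(c, 0.0, 0)

    def test_negative_threshold_rejected(self):
        c = DDMCoefficients(c0_beta=0.5, cR_beta=0.1)
        with pytest.raises(InvalidParameterError):
            dc.resolve_parameters(c, -10.0, 0)

    @pytest.mark.parametrize("bad_dI", [2, -3, 0.5])
    def test_invalid_delta_I(self, bad_dI):
        with pytest.raises(ValueError):
            dc.resolve_parameters(DDMCoefficients(), 0.0, bad_dI)

    def test_alpha_saturates_within_unit_interval(self):
        c = DDMCoefficients(c0_alpha=50.0)
        r = dc.resolve_parameters(c, 0.0, 0)
        assert r.alpha == pytest.approx(1.0)


@given(x=st.floats(-500, 500))
@settings(deadline=None, max_examples=50)
def test_link_symmetry(x):
    assert dc.link_L(x) + dc.link_L(-x) == pytest.approx(1.0, abs=1e-12)


def test_link_values():
    assert dc.link_L(0.0) == 0.5
    assert dc.link_L(1000.0) == pytest.approx(1.0)
    assert dc.link_L(-1000.0) == pytest.approx(0.0)


# ----------------------------------------------------------------------
# choice probability and mean RT
# ----------------------------------------------------------------------

class TestChoiceProbability:
    def test_unbiased_driftless(self):
        assert dc.choice_probability(ResolvedDDM(0.0, 2.3, 0.0, 0.1)) == 0.5

    def test_logistic_point(self):
        # at alpha=0 the closed form is 1/(1+exp(2*beta*mu))
        p = dc.choice_probability(ResolvedDDM(1.0, 1.0, 0.0, 0.0))
        assert p == pytest.approx(1.0 / (1.0 + math.e**2), abs=1e-12)

    def test_driftless_biased(self):
        # mu -> 0 limit is (1 - alpha) / 2
        assert dc.choice_probability(ResolvedDDM(0.0, 1.0, 0.5, 0.0)) == pytest.approx(0.25)

    def test_taylor_branch_continuity(self):
        # points straddle the series/exact switch; difference is bounded by
        # the local slope (1 - alpha^2)/2 times the drift gap
        lo = dc.choice_probability(ResolvedDDM(0.9e-5, 1.0, 0.4, 0.0))
        hi = dc.choice_probability(ResolvedDDM(1.1e-5, 1.0, 0.4, 0.0))
        assert lo == pytest.approx(hi, abs=2e-6)

    def test_extreme_drift_saturates(self):
        assert dc.choice_probability(ResolvedDDM(300.0, 3.0, 0.2, 0.0)) == pytest.approx(0.0)
        assert dc.choice_probability(ResolvedDDM(-300.0, 3.0, 0.2, 0.0)) == pytest.approx(1.0)


@given(mu=finite_mu, beta=finite_beta, alpha=finite_alpha)
@settings(deadline=None, max_examples=60)
def test_mirror_symmetry_choice(mu, beta, alpha):
    """Negating (mu, alpha) swaps the two boundaries' roles exactly."""
    p = dc.choice_probability(ResolvedDDM(mu, beta, alpha, 0.0))
    p_mirror = dc.choice_probability(ResolvedDDM(-mu, beta, -alpha, 0.0))
    assert p + p_mirror == pytest.approx(1.0, abs=1e-10)


class TestMeanRT:
    def test_drift_free_limit(self):
        # T0 + beta^2 at alpha = 0
        assert dc.mean_rt(ResolvedDDM(1e-9, 1.2, 0.0, 0.1)) == pytest.approx(1.54)

    def test_tanh_form(self):
        assert dc.mean_rt(ResolvedDDM(1.0, 1.0, 0.0, 0.2)) == pytest.approx(
            0.2 + math.tanh(1.0), abs=1e-12)

    def test_drift_free_biased_limit(self):
        # mu -> 0 with bias: T0 + beta^2 (1 - alpha^2)
        assert dc.mean_rt(ResolvedDDM(0.0, 1.5, 0.6, 0.0)) == pytest.approx(
            1.5**2 * (1 - 0.36))

    @given(mu=finite_mu, beta=finite_beta, alpha=finite_alpha)
    @settings(deadline=None, max_examples=60)
    def test_mirror_invariance(self, mu, beta, alpha):
        a = dc.mean_rt(ResolvedDDM(mu, beta, alpha, 0.1))
        b = dc.mean_rt(ResolvedDDM(-mu, beta, -alpha, 0.1))
        assert a == pytest.approx(b, rel=1e-9)
        assert a >= 0.1

    def test_taylor_branch_continuity(self):
        lo = dc.mean_rt(ResolvedDDM(0.9e-5, 1.0, 0.4, 0.0))
        hi = dc.mean_rt(ResolvedDDM(1.1e-5, 1.0, 0.4, 0.0))
        assert lo == pytest.approx(hi, rel=1e-6)


class TestRTExtremum:
    def test_symmetric_case(self):
        c = DDMCoefficients(cR_mu=0.25)
        assert dc.rt_extremum_location(c, 0, "threshold_fixed") == 0.0

    def test_arithmetic(self):
        c = DDMCoefficients(c0_mu=0.5, cI_mu=0.1, cR_mu=0.25)
        assert dc.rt_extremum_location(c, 1, "threshold_fixed") == pytest.approx(-2.4)

    def test_zero_slope_undefined(self):
        with pytest.raises(UndefinedExtremumError):
            dc.rt_extremum_location(DDMCoefficients(cR_mu=0.0), 0, "threshold_fixed")
        with pytest.raises(UndefinedExtremumError):
            dc.rt_extremum_location(DDMCoefficients(cR_beta=0.0), 0, "drift_fixed")

    def test_grid_oracle_maximum(self):
        """With threshold fixed, mean RT over a dR grid peaks at the closed form."""
        c = DDMCoefficients(c0_mu=0.3, cR_mu=-0.07, cI_mu=-0.2, c0_beta=0.9, T0=0.2)
        dI = 1
        star = dc.rt_extremum_location(c, dI, "threshold_fixed")
        grid = np.linspace(star - 20, star + 20, 801)
        rts = [dc.mean_rt(dc.resolve_parameters(c, dr, dI)) for dr in grid]
        assert grid[int(np.argmax(rts))] == pytest.approx(star, abs=0.1)

    def test_grid_oracle_minimum(self):
        """With drift fixed, mean RT decreases toward the closed-form location,
        which sits on the edge of the valid domain (the threshold vanishes
        there), so the oracle checks monotone growth away from it."""
        c = DDMCoefficients(c0_mu=0.8, c0_beta=1.2, cR_beta=0.02, T0=0.2)
        star = dc.rt_extremum_location(c, 0, "drift_fixed")
        grid = np.linspace(star + 0.5, star + 15, 100)
        rts = np.array([dc.mean_rt(dc.resolve_parameters(c, dr, 0)) for dr in grid])
        assert np.all(np.diff(rts) > 0)
        with pytest.raises(InvalidParameterError):  # other side is undefined
            dc.resolve_parameters(c, star - 0.5, 0)


# ----------------------------------------------------------------------
# first-passage densities
# ----------------------------------------------------------------------

GRID_SETS = [
    (0.5, 1.0, 0.3, 0.1),
    (-1.5, 0.6, -0.6, 0.2),
    (2.0, 1.8, 0.0, 0.0),
    (0.0, 0.9, 0.8, 0.15),
]


class TestWfptDensity:
    @pytest.mark.parametrize("mu,beta,alpha,T0", GRID_SETS)
    def test_conservation_and_closed_forms(self, mu, beta, alpha, T0):
        res = ResolvedDDM(mu, beta, alpha, T0)
        fl = lambda t: dc.wfpt_density(t, res, "left")
        fr = lambda t: dc.wfpt_density(t, res, "right")
        ml, _ = quad(fl, T0, np.inf, limit=200)
        mr, _ = quad(fr, T0, np.inf, limit=200)
        assert ml + mr == pytest.approx(1.0, abs=1e-4)
        assert ml == pytest.approx(dc.choice_probability(res), abs=1e-4)
        mrt, _ = quad(lambda t: t * (fl(t) + fr(t)), T0, np.inf, limit=200)
        assert mrt == pytest.approx(dc.mean_rt(res), abs=1e-3)

    def test_zero_before_nondecision_time(self):
        res = ResolvedDDM(1.0, 1.0, 0.0, 0.5)
        assert dc.wfpt_density(0.4, res, "left") == 0.0
        assert dc.wfpt_density(0.5, res, "right") == 0.0

    @given(mu=finite_mu, beta=finite_beta, alpha=finite_alpha,
           t=st.floats(0.05, 5.0))
    @settings(deadline=None, max_examples=60)
    def test_mirror_density_identity(self, mu, beta, alpha, t):
        a = dc.wfpt_density(t, ResolvedDDM(mu, beta, alpha, 0.0), "left")
        b = dc.wfpt_density(t, ResolvedDDM(-mu, beta, -alpha, 0.0), "right")
        assert a == pytest.approx(b, rel=1e-9, abs=1e-12)

    def test_density_matches_simulated_rt_distribution(self):
        """Empirical first-passage CDF from paths tracks the integrated density."""
        res = ResolvedDDM(0.6, 1.0, 0.2, 0.1)
        rng = np.random.default_rng(3)
        act, rt, cen = dc.simulate_paths(
            np.full(20000, res.mu), res.beta, res.alpha, res.T0, rng, dt=1e-3)
        assert cen.sum() == 0
        rt_left = np.sort(rt[act == 1])
        grid = np.quantile(rt_left, np.linspace(0.05, 0.95, 19))
        emp = np.searchsorted(rt_left, grid, side="right") / act.size
        theo = [quad(lambda t: dc.wfpt_density(t, res, "left"), res.T0, g,
                     limit=200)[0] for g in grid]
        assert np.max(np.abs(emp - theo)) < 0.02


# ----------------------------------------------------------------------
# simulator
# ----------------------------------------------------------------------

class TestSimulateResponse:
    def test_dominant_drift_picks_disfavored_left_never(self):
        # large positive drift drives p_left -> 0 under this orientation
        rng = np.random.default_rng(0)
        act, rt, cen = dc.simulate_paths(
            np.full(1000, 8.0), 1.0, 0.0, 0.1, rng, dt=1e-3)
        assert (act == -1).mean() > 0.99
        assert not cen.any()

    def test_symmetric_split(self):
        rng = np.random.default_rng(1)
        act, _, _ = dc.simulate_paths(np.zeros(4000), 1.0, 0.0, 0.0, rng, dt=1e-3)
        p = (act == 1).mean()
        assert abs(p - 0.5) < 3 * math.sqrt(0.25 / 4000)

    def test_mean_rt_against_closed_form(self):
        rng = np.random.default_rng(2)
        res = ResolvedDDM(1.0, 1.0, 0.0, 0.0)
        _, rt, _ = dc.simulate_paths(np.full(20000, 1.0), 1.0, 0.0, 0.0, rng, dt=1e-3)
        se = np.nanstd(rt) / math.sqrt(rt.size)
        assert np.nanmean(rt) == pytest.approx(dc.mean_rt(res), abs=3 * se + 2e-3)

    def test_scalar_wrapper_and_censoring(self):
        rng = np.random.default_rng(4)
        a, t, c = dc.simulate_response(ResolvedDDM(0.0, 1.0, 0.0, 0.2), rng, dt=1e-3)
        assert a in (-1, 1) and t > 0.2 and not c
        # an absurdly high threshold with a tiny cap must censor
        a2, t2, c2 = dc.simulate_response(
            ResolvedDDM(0.0, 50.0, 0.0, 0.0), rng, dt=1e-3, max_time=0.05)
        assert c2 and a2 == 0 and math.isnan(t2)


# ----------------------------------------------------------------------
# logistic equivalence
# ----------------------------------------------------------------------

class TestLogisticEquivalentSigma:
    def test_arithmetic(self):
        c = DDMCoefficients(cR_mu=0.25, c0_beta=1.0)
        assert dc.logistic_equivalent_sigma(c) == pytest.approx(math.sqrt(2.0))

    def test_reciprocal_scaling(self):
        c1 = DDMCoefficients(cR_mu=0.25, c0_beta=1.0)
        c2 = DDMCoefficients(cR_mu=0.25, c0_beta=2.0)
        assert dc.logistic_equivalent_sigma(c2) == pytest.approx(
            dc.logistic_equivalent_sigma(c1) / 2.0)

    def test_drift_fixed_case(self):
        c = DDMCoefficients(c0_mu=0.5, cR_beta=0.02, c0_beta=1.0)
        assert dc.logistic_equivalent_sigma(c, "drift_fixed") == pytest.approx(
            1.0 / (2 * math.sqrt(2) * 0.5 * 0.02))

    def test_zero_denominator(self):
        with pytest.raises(UndefinedExtremumError):
            dc.logistic_equivalent_sigma(DDMCoefficients(cR_mu=0.0))

    def test_choice_curve_is_exactly_logistic(self):
        """With bias and threshold slopes zeroed, the diffusion choice curve is
        the logistic choice model with the mapped (A, B, sigma)."""
        from ddmexplore import behavior_models as bm
        c = DDMCoefficients(c0_mu=0.12, cR_mu=-0.06, cI_mu=-0.3, c0_beta=0.9, T0=0.2)
        sigma = dc.logistic_equivalent_sigma(c)
        A = c.cI_mu / c.cR_mu
        B = c.c0_mu / c.cR_mu
        lp = bm.LogisticParams(A=A, B=B, sigma=sigma)
        for dI in (-1, 0, 1):
            for dr in np.linspace(-30, 30, 61):
                p_ddm = dc.choice_probability(dc.resolve_parameters(c, dr, dI))
                p_log = bm.logistic_choice_prob(lp, dr, dI)
                assert p_ddm == pytest.approx(p_log, abs=1e-10)
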