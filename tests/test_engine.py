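"""Stepper contracts: SSA statistics, DA proposals, constraint repairs,
conservation, and the deterministic-limit equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.stats import binom, chisquare

from chanstoch import (
    ChannelPopulation,
    SimulationOverflowError,
    StepContext,
    STEPPERS,
    build_scheme,
    euler_master_step,
    eval_hh_rates,
    project_simplex,
    ref_step,
    run_voltage_clamp,
    ssa_advance,
    ssda_step,
    ssmc_step,
    steady_state,
    tr_step,
    ua_step,
)
from chanstoch.engine import largest_remainder_counts
from chanstoch.kinetics import Edge, KineticScheme, RateForm
from chanstoch.membrane import Trace

from conftest import CountingRng, ZeroNoiseRng, make_two_state

DA_STEPPERS = {"ua": ua_step, "ref": ref_step, "tr": tr_step, "ssda": ssda_step}


def clamped_ctx(rng, v=-40.0, dt=0.005, t=0.0):
    return StepContext(V=v, dt=dt, rng=rng, t=t)


class TestProjectSimplex:
    def test_identity_on_simplex(self):
        x = np.array([0.2, 0.5, 0.3])
        np.testing.assert_array_equal(project_simplex(x), x)

    def test_known_example(self):
        np.testing.assert_allclose(
            project_simplex(np.array([1.2, -0.2, 0.0])), [1.0, 0.0, 0.0], atol=1e-14
        )

    def test_idempotent(self, rng):
        x = rng.normal(size=8)
        once = project_simplex(x)
        np.testing.assert_array_equal(project_simplex(once), once)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_against_quadratic_program(self, seed):
        """Independent oracle: minimize ||y - x||^2 on the simplex (SLSQP)."""
        x = np.random.default_rng(seed).normal(size=5, scale=1.5)
        res = minimize(
            lambda y: np.sum((y - x) ** 2),
            np.full(5, 0.2),
            jac=lambda y: 2 * (y - x),
            bounds=[(0, None)] * 5,
            constraints={"type": "eq", "fun": lambda y: y.sum() - 1.0},
            method="SLSQP",
            tol=1e-12,
        )
        np.testing.assert_allclose(project_simplex(x), res.x, atol=1e-6)

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_output_in_simplex(self, vals):
        y = project_simplex(np.array(vals))
        assert y.min() >= 0.0
        assert y.sum() == pytest.approx(1.0, abs=1e-9)


class TestPopulations:
    def test_largest_remainder_is_deterministic_and_exact(self):
        x = np.array([0.301, 0.299, 0.25, 0.15])
        c = largest_remainder_counts(997, x)
        assert c.sum() == 997
        np.testing.assert_array_equal(c, largest_remainder_counts(997, x))

    def test_steady_state_counts_sum_to_n(self, hh_na):
        pop = ChannelPopulation.from_steady_state(hh_na, 1234, -65.0, "counts")
        assert pop.X.sum() == 1234
        assert np.all(pop.X == np.round(pop.X))

    def test_multinomial_init(self, hh_k, rng):
        pop = ChannelPopulation.from_steady_state(hh_k, 500, -40.0, "counts", rng=rng)
        assert pop.X.sum() == 500


class TestSSA:
    def test_zero_rates_leave_counts_unchanged(self, rng):
        s = make_two_state(alpha=0.0, beta=0.0)
        pop = ChannelPopulation(s, 10, [7.0, 3.0], "counts")
        ssa_advance(pop, clamped_ctx(rng, dt=100.0))
        np.testing.assert_array_equal(pop.X, [7.0, 3.0])

    def test_telegraph_occupancy(self, rng):
        """One 2-state channel: time in the open state -> alpha/(alpha+beta)."""
        alpha, beta = 0.4, 0.6
        pop = ChannelPopulation(make_two_state(alpha, beta), 1, [1.0, 0.0], "counts")
        dt, nsteps = 0.5, 20000
        open_samples = np.empty(nsteps)
        for k in range(nsteps):
            ssa_advance(pop, clamped_ctx(rng, v=0.0, dt=dt, t=k * dt))
            open_samples[k] = pop.X[1]
        p = alpha / (alpha + beta)
        tau = 1.0 / (alpha + beta)
        n_eff = nsteps * dt / (2.0 * tau)
        se = math.sqrt(p * (1 - p) / n_eff)
        assert abs(open_samples.mean() - p) < 3 * se

    def test_three_channel_multinomial_law(self, hh_k, rng):
        """N=3 clamped at -40 mV: pooled occupancy matches binomial(4, n_inf)."""
        pop = ChannelPopulation.from_steady_state(hh_k, 3, -40.0, "counts")
        dt = 25.0  # >> gate relaxation time, samples ~independent
        occupancy = np.zeros(5)
        n_samples = 2000
        for k in range(n_samples + 4):
            ssa_advance(pop, clamped_ctx(rng, dt=dt, t=k * dt))
            if k >= 4:  # burn-in
                occupancy += pop.X
        r = eval_hh_rates(-40.0)
        n_inf = r["alpha_n"] / (r["alpha_n"] + r["beta_n"])
        expected = binom.pmf(np.arange(5), 4, n_inf) * occupancy.sum()
        _, pval = chisquare(occupancy, expected)
        assert pval > 0.01

    def test_counts_conserved(self, hh_na, rng):
        pop = ChannelPopulation.from_steady_state(hh_na, 200, -65.0, "counts")
        for k in range(200):
            ssa_advance(pop, clamped_ctx(rng, v=-40.0, dt=0.01, t=k * 0.01))
        assert pop.X.sum() == 200
        assert pop.X.min() >= 0

    def test_requires_counts_representation(self, hh_k, rng):
        pop = ChannelPopulation.from_steady_state(hh_k, 10, -40.0, "fractions")
        with pytest.raises(ValueError, match="counts"):
            ssa_advance(pop, clamped_ctx(rng))


class TestDASteppers:
    def test_zero_noise_equals_master_equation_euler(self, hh_k):
        x0 = steady_state(hh_k, -65.0)
        ref_pop = ChannelPopulation(hh_k, 1000, x0)
        for _ in range(100):
            euler_master_step(ref_pop, clamped_ctx(ZeroNoiseRng(), v=-30.0))
        for name, step in DA_STEPPERS.items():
            pop = ChannelPopulation(hh_k, 1000, x0)
            for _ in range(100):
                step(pop, clamped_ctx(ZeroNoiseRng(), v=-30.0))
            np.testing.assert_array_equal(pop.X, ref_pop.X, err_msg=name)

    def test_normalization_by_dependent_state(self, hh_na, rng):
        pop = ChannelPopulation.from_steady_state(hh_na, 400, -65.0)
        for k in range(50):
            ua_step(pop, clamped_ctx(rng, v=-50.0, t=k * 0.005))
            # state 0 is defined as 1 - sum(others): exact identity
            assert pop.X[0] == 1.0 - pop.X[1:].sum()
            assert pop.X.sum() == pytest.approx(1.0, abs=1e-12)

    def test_ssda_noise_dimension(self, hh_na, hh_k):
        for scheme, n_expected in ((hh_na, 2), (hh_k, 1)):
            pop = ChannelPopulation.from_steady_state(scheme, 500, -65.0)
            counter = CountingRng(np.random.default_rng(0))
            ssda_step(pop, clamped_ctx(counter))
            assert counter.normal_draws == n_expected

    def test_ua_noise_dimension(self, hh_na, hh_k):
        for scheme, n_expected in ((hh_na, 10), (hh_k, 4)):
            pop = ChannelPopulation.from_steady_state(scheme, 500, -65.0)
            counter = CountingRng(np.random.default_rng(0))
            ua_step(pop, clamped_ctx(counter))
            assert counter.normal_draws == n_expected

    def test_ref_stays_in_simplex(self, hh_k, rng):
        pop = ChannelPopulation.from_steady_state(hh_k, 30, -40.0)
        for k in range(500):
            ref_step(pop, clamped_ctx(rng, t=k * 0.005))
            assert pop.X.min() >= 0.0
            assert pop.X.sum() == pytest.approx(1.0, abs=1e-9)

    def test_tr_residual_carries_truncation_remainder(self):
        # drift pushes state 0 below zero in one large step: the entry is
        # truncated to 0 and the (negative) remainder lands in the residual
        s = make_two_state(alpha=2.0, beta=0.0)
        pop = ChannelPopulation(s, 100, [0.01, 0.99])
        tr_step(pop, clamped_ctx(ZeroNoiseRng(), dt=1.0))
        assert pop.X[0] == 0.0
        assert pop.residual[0] == pytest.approx(-0.01, rel=1e-12)
        assert pop.residual[1] == pytest.approx(0.01, rel=1e-12)
        assert pop.X.sum() == pytest.approx(1.0, abs=1e-12)

    def test_tr_interior_step_keeps_zero_residual(self, hh_k, rng):
        pop = ChannelPopulation.from_steady_state(hh_k, 100000, -40.0)
        tr_step(pop, clamped_ctx(rng))
        np.testing.assert_array_equal(pop.residual, np.zeros(5))

    def test_tr_in_unit_box_and_normalized(self, hh_k, rng):
        pop = ChannelPopulation.from_steady_state(hh_k, 25, -40.0)
        for k in range(500):
            tr_step(pop, clamped_ctx(rng, t=k * 0.005))
            assert pop.X.min() >= 0.0 and pop.X.max() <= 1.0
            assert pop.X.sum() == pytest.approx(1.0, abs=1e-12)

    def test_overflow_raises(self, hh_k):
        for bad in (1e7, np.inf, np.nan):
            pop = ChannelPopulation(hh_k, 50, steady_state(hh_k, -40.0))
            pop.X[2] = bad
            with np.errstate(invalid="ignore"), pytest.raises(SimulationOverflowError):
                ua_step(pop, clamped_ctx(ZeroNoiseRng()))


class TestSSmc:
    def test_reduces_to_ode_when_open_rates_vanish(self):
        """Zero rates on the open-adjacent edge: pure deterministic fluxes."""
        rates = {
            "f": RateForm("constant", a=0.3),
            "b": RateForm("constant", a=0.4),
            "z": RateForm("constant", a=0.0),
        }
        s = KineticScheme(
            "chain3", ("a", "b", "c"),
            (Edge(0, 1, "f", "b"), Edge(1, 2, "z", "z")),
            (2,), rates,
        )
        N = 1024
        pop = ChannelPopulation(s, N, [512.0, 512.0, 0.0], "counts")
        det = ChannelPopulation(s, N, [0.5, 0.5, 0.0])
        rng = np.random.default_rng(0)
        for k in range(200):
            ssmc_step(pop, clamped_ctx(rng, dt=0.01, t=k * 0.01))
            euler_master_step(det, clamped_ctx(rng, dt=0.01, t=k * 0.01))
        np.testing.assert_allclose(pop.X / N, det.X, atol=1e-12)

    def test_counts_conserved_and_bounded(self, hh_k, rng):
        pop = ChannelPopulation.from_steady_state(hh_k, 160, -40.0, "counts")
        for k in range(500):
            ssmc_step(pop, clamped_ctx(rng, t=k * 0.005))
            assert pop.X.sum() == pytest.approx(160.0, abs=1e-9)
            assert pop.X[1:].min() >= 0.0


class TestRegistryAndDeterminism:
    def test_registry_complete(self):
        assert set(STEPPERS) == {"mc", "ua", "ref", "tr", "ssmc", "ssda", "det"}

    @pytest.mark.parametrize("name", ["mc", "ua", "ref", "tr", "ssmc", "ssda"])
    def test_same_seed_same_trajectory(self, hh_k, name):
        step = STEPPERS[name]
        repr_ = "counts" if name in ("mc", "ssmc") else "fractions"
        out = []
        for _ in range(2):
            pop = ChannelPopulation.from_steady_state(hh_k, 200, -40.0, repr_)
            rng = np.random.default_rng(99)
            for k in range(100):
                step(pop, clamped_ctx(rng, t=k * 0.005))
            out.append(pop.X.copy())
        np.testing.assert_array_equal(out[0], out[1])


class TestUpdateCountScaling:
    def test_mc_updates_scale_linearly_with_n(self, hh_k):
        """Expected SSA transitions per timestep grow like N*alpha*dt."""
        vtrace = Trace(t=np.array([0.0, 10.0]), v=np.array([-40.0, -40.0]))
        updates = []
        sizes = [100, 1000, 10000]
        for i, n in enumerate(sizes):
            res = run_voltage_clamp([("k", hh_k, n)], vtrace, 1, "mc", dt=0.005, seed=7 + i)
            updates.append(res.updates["k"])
        slope = np.polyfit(np.log(sizes), np.log(updates), 1)[0]
        assert 0.9 < slope < 1.1
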