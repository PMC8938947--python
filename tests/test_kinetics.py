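"""Delayed-cascade integration, maturation half-times, shutoff and the
simplified concentration model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from fpmat.kinetics import (
    AbundanceParams,
    NumericalError,
    closed_form_onestep,
    dilution_rate_from_distribution,
    maturation_half_time,
    population_average,
    simple_concentration_model,
    simulate_chx_shutoff,
    simulate_single_cell,
    two_step_lower_bound,
    _integrate_cascade,
)
from fpmat.volume import CellCycleDistribution, simulate_volume

LN2 = np.log(2.0)


class TestClosedFormOracle:
    @pytest.mark.parametrize("k_dr,k_m", [(0.1, 0.1), (0.1, 0.05)])
    def test_integrator_matches_closed_form(self, k_dr, k_m, t5min):
        """Method-of-steps solution vs the exact matrix-exponential cascade
        (no divisions, constant volume), including the confluent-rate case."""
        p = AbundanceParams(kind="one_step", k_r=1.0, k_dr=k_dr, k_p=1.0,
                            k_m=k_m)
        num = simple_concentration_model(p, 0.0, t5min, dt=0.05).conc
        exact = closed_form_onestep(p, t5min).Pm
        sel = t5min >= 10.0  # states are identically zero before tau1+tau2
        assert np.max(np.abs(num[sel] - exact[sel]) / exact[sel]) < 1e-6

    def test_states_zero_before_first_delay(self, onestep_params):
        st_ = closed_form_onestep(onestep_params, [0.0, 1.0, 1.9])
        assert np.all(st_.m == 0) and np.all(st_.Pd == 0) and np.all(st_.Pm == 0)

    def test_mrna_solution_and_steady_state(self, onestep_params):
        t = np.array([10.0, 50.0, 400.0])
        st_ = closed_form_onestep(onestep_params, t)
        expect = (1.0 / 0.1) * (1 - np.exp(-0.1 * (t - 2.0)))
        assert np.allclose(st_.m, expect, rtol=1e-12)
        assert st_.m[-1] == pytest.approx(10.0, rel=1e-6)  # k_r/k_dr

    def test_late_time_linear_accumulation(self, onestep_params):
        # dPm/dt -> k_p*k_r/k_dr once m has equilibrated
        st_ = closed_form_onestep(onestep_params, [300.0, 320.0])
        rate = (st_.Pm[1] - st_.Pm[0]) / 20.0
        assert rate == pytest.approx(1.0 * 1.0 / 0.1, rel=1e-4)


class TestSingleCellSimulation:
    def test_zero_transcription_gives_zero_trace(self, vol_degenerate, t5min):
        p = AbundanceParams(kind="one_step", k_r=0.0, k_dr=0.1, k_p=1.0,
                            k_m=0.1)
        tr = simulate_single_cell(p, vol_degenerate, t5min)
        assert np.all(tr.conc == 0.0)

    def test_step_halving_convergence(self, onestep_params, vol_degenerate,
                                      t5min):
        c1 = simulate_single_cell(onestep_params, vol_degenerate, t5min,
                                  dt=0.05).conc[-1]
        c2 = simulate_single_cell(onestep_params, vol_degenerate, t5min,
                                  dt=0.025).conc[-1]
        assert abs(c1 - c2) / c2 < 1e-4

    def test_concentration_continuous_at_divisions(self, realistic_dist,
                                                   onestep_params, t5min):
        for seed in range(5):
            vol = simulate_volume(realistic_dist, 200.0, dt=1.0, rng=seed)
            tr = simulate_single_cell(onestep_params, vol, t5min)
            assert tr.division_times.size >= 1
            jump = np.abs(tr.conc_pre - tr.conc_post) / tr.conc_pre
            assert np.max(jump) < 1e-9

    def test_mass_balance_between_divisions(self, onestep_params):
        """d(Pd+Pm)/dt = k_p * m(t - tau2) between divisions, by quadrature
        on a division-free window."""
        mesh, out, _ = _integrate_cascade(onestep_params, 75.0, 0.05,
                                          np.empty(0), np.empty(0))
        lo, hi = np.searchsorted(mesh, [10.0, 75.0])
        tot = out["Pd"][:, 0] + out["Pm"][:, 0]
        m_delayed = np.interp(mesh - 4.0, mesh, out["m"][:, 0], left=0.0)
        m_delayed[mesh - 4.0 < 2.0] = 0.0
        gain = np.trapezoid(onestep_params.k_p * m_delayed[lo:hi + 1],
                            mesh[lo:hi + 1])
        assert gain == pytest.approx(tot[hi] - tot[lo], rel=1e-5)

    def test_two_step_reduces_to_one_step_for_fast_second_rate(
            self, vol_degenerate, t5min):
        p1 = AbundanceParams(kind="one_step", k_r=1, k_dr=0.1, k_p=1,
                             k_m=0.05)
        p2 = AbundanceParams(kind="two_step", k_r=1, k_dr=0.1, k_p=1,
                             k_m1=0.05, k_m2=500.0)
        a = simulate_single_cell(p1, vol_degenerate, t5min, dt=0.05).conc
        b = simulate_single_cell(p2, vol_degenerate, t5min, dt=0.05).conc
        assert np.max(np.abs(a - b)) / np.max(np.abs(a)) < 1e-3

    def test_grid_outside_trajectory_raises(self, onestep_params,
                                            vol_degenerate):
        with pytest.raises(ValueError, match="covers"):
            simulate_single_cell(onestep_params, vol_degenerate,
                                 np.array([0.0, 250.0]))


class TestPopulationAverage:
    def test_single_cell_consistency_and_determinism(self, realistic_dist,
                                                     onestep_params, t5min):
        tr1, cells = population_average(onestep_params, realistic_dist, 5,
                                        t5min, rng_seed=9, return_cells=True)
        tr2 = population_average(onestep_params, realistic_dist, 5, t5min,
                                 rng_seed=9)
        assert np.array_equal(tr1.conc, tr2.conc)
        assert np.allclose(tr1.conc, cells.mean(axis=0))

    def test_sem_scales_with_cell_count(self, realistic_dist, onestep_params,
                                        t5min):
        _, c8 = population_average(onestep_params, realistic_dist, 32, t5min,
                                   rng_seed=1, dt=0.2, return_cells=True)
        late = c8[:, -1]
        sem8 = late[:8].std(ddof=1) / np.sqrt(8)
        sem32 = late.std(ddof=1) / np.sqrt(32)
        assert sem32 < sem8  # ~1/sqrt(n) shrinkage

    def test_slower_maturation_delays_half_rise(self, realistic_dist, t5min):
        halves = []
        for km in (0.1, 0.05, 0.02):
            p = AbundanceParams(kind="one_step", k_r=1, k_dr=0.1, k_p=1,
                                k_m=km)
            tr = population_average(p, realistic_dist, 10, t5min, rng_seed=4,
                                    dt=0.2)
            half = tr.conc[-1] / 2.0
            halves.append(np.interp(half, tr.conc, t5min))
        assert halves[0] < halves[1] < halves[2]


def _equivalent_half_time_ivp(k1, k2):
    """Independent oracle: integrate the closed two-step system from pure
    first precursor and locate the 50%-mature crossing."""
    def rhs(_, y):
        return [-k1 * y[0], k1 * y[0] - k2 * y[1], k2 * y[1]]

    sol = solve_ivp(rhs, (0.0, 500.0), [1.0, 0.0, 0.0], rtol=1e-10,
                    atol=1e-12, dense_output=True)
    tt = np.linspace(0.0, 500.0, 200_001)
    frac = sol.sol(tt)[2]
    return float(np.interp(0.5, frac, tt))


class TestMaturationHalfTimes:
    def test_one_step_search_bound_is_five_minute_half_time(self):
        assert maturation_half_time("one_step", 0.1386) == pytest.approx(
            5.0, abs=2e-3)

    @pytest.mark.parametrize("t1,t2", [(17.0, 30.0), (22.0, 22.0)])
    def test_two_step_matches_ivp_oracle(self, t1, t2):
        rates = (LN2 / t1, LN2 / t2)
        got = maturation_half_time("two_step", rates)
        assert got == pytest.approx(_equivalent_half_time_ivp(*rates),
                                    abs=5e-3)

    def test_two_step_known_values(self):
        assert maturation_half_time(
            "two_step", (LN2 / 17, LN2 / 30)) == pytest.approx(56.0, abs=0.5)
        assert maturation_half_time(
            "two_step", (LN2 / 22, LN2 / 22)) == pytest.approx(53.3, abs=0.1)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(t1=st.floats(2.0, 120.0), t2=st.floats(2.0, 120.0))
    def test_sum_of_step_half_times_is_lower_bound(self, t1, t2):
        rates = (LN2 / t1, LN2 / t2)
        assert two_step_lower_bound(rates) <= maturation_half_time(
            "two_step", rates) + 1e-9

    def test_lower_bound_values_and_one_step_limit(self):
        assert two_step_lower_bound((LN2 / 22, LN2 / 22)) == pytest.approx(44.0)
        assert two_step_lower_bound((LN2 / 17, LN2 / 30)) == pytest.approx(47.0)
        # k_m2 -> inf: bound and equivalent half-time both -> ln2/k_m1
        rates = (LN2 / 20, 1e6)
        assert two_step_lower_bound(rates) == pytest.approx(20.0, rel=1e-4)
        assert maturation_half_time("two_step", rates) == pytest.approx(
            20.0, rel=1e-3)

    def test_invalid_rates_raise(self):
        with pytest.raises(ValueError):
            maturation_half_time("one_step", -0.1)
        with pytest.raises(ValueError):
            maturation_half_time("two_step", (0.1,))
        with pytest.raises(ValueError):
            two_step_lower_bound((0.1, -0.2))


class TestShutoff:
    def test_one_step_plateau_formula(self):
        lam = LN2 / 80.0
        km = LN2 / 6.9
        p = AbundanceParams(kind="one_step", k_r=1, k_dr=0.1, k_p=1, k_m=km)
        tr = simulate_chx_shutoff(p, lam, np.arange(0.0, 200.0, 1.0))
        assert tr.plateau == pytest.approx(1.0 + lam / km, rel=1e-12)
        assert tr.rel_fluorescence[0] == pytest.approx(1.0)
        assert np.all(np.diff(tr.rel_fluorescence) >= -1e-12)
        assert tr.rel_fluorescence[-1] == pytest.approx(tr.plateau, rel=1e-3)

    def test_instant_maturation_plateau_is_one(self):
        p = AbundanceParams(kind="one_step", k_r=1, k_dr=0.1, k_p=1, k_m=1e4)
        tr = simulate_chx_shutoff(p, LN2 / 80, np.arange(0.0, 10.0, 1.0))
        assert tr.plateau == pytest.approx(1.0, abs=1e-5)

    def test_two_step_plateau_accounts_for_both_pools(self):
        lam, k = LN2 / 80.0, LN2 / 22.0
        p = AbundanceParams(kind="two_step", k_r=1, k_dr=0.1, k_p=1,
                            k_m1=k, k_m2=k)
        tr = simulate_chx_shutoff(p, lam, np.arange(0.0, 400.0, 5.0))
        expect = 1.0 + lam / k + lam * (k + lam) / k**2
        assert tr.plateau == pytest.approx(expect, rel=1e-12)
        assert tr.rel_fluorescence[-1] == pytest.approx(tr.plateau, rel=1e-2)

    def test_zero_maturation_rate_flagged(self):
        p = AbundanceParams(kind="one_step", k_r=1, k_dr=0.1, k_p=1, k_m=0.0)
        with pytest.raises(NumericalError):
            simulate_chx_shutoff(p, LN2 / 80, np.arange(0.0, 10.0, 1.0))


class TestSimpleConcentrationModel:
    def test_coincides_with_single_cell_without_divisions(self, t5min):
        # division-free trajectory: the concentration DDEs with zero dilution
        # equal the abundance cascade, i.e. conc*V(t)
        dist = CellCycleDistribution.degenerate(500.0, 0.2, 12.0, 30.0)
        vol = simulate_volume(dist, 200.0, dt=1.0, rng=0, phase=0.0)
        p = AbundanceParams(kind="one_step", k_r=1, k_dr=0.1, k_p=1, k_m=0.08)
        single = simulate_single_cell(p, vol, t5min, dt=0.05)
        simple = simple_concentration_model(p, 0.0, t5min, dt=0.05)
        abundance = single.conc * vol.value(t5min)
        sel = t5min >= 10.0
        assert np.allclose(simple.conc[sel], abundance[sel], rtol=1e-6)

    def test_mrna_steady_state_includes_dilution(self, onestep_params):
        lam = 0.02
        mesh, out, _ = _integrate_cascade(onestep_params, 600.0, 0.2,
                                          np.empty(0), np.empty(0),
                                          dilution=lam)
        expect = onestep_params.k_r / (onestep_params.k_dr + lam)
        assert out["m"][-1, 0] == pytest.approx(expect, rel=1e-6)

    def test_dilution_rate_modes(self, realistic_dist):
        lam_m = dilution_rate_from_distribution(realistic_dist)
        lam_d = dilution_rate_from_distribution(realistic_dist,
                                                mode="doubling")
        mean_T = np.exp(realistic_dist.log_mean[0]
                        + realistic_dist.log_cov[0, 0] / 2)
        assert lam_d == pytest.approx(LN2 / mean_T)
        # mother cells grow sub-2x per cycle, so dilution is slower
        assert 0 < lam_m < lam_d


class TestDelaySensitivity:
    def test_delay_error_hurts_fast_fp_more(self):
        """A +/-2 min error in the total expression delay shifts the fitted
        half-time of a fast FP more, relatively, than that of a slow FP."""
        from fpmat.inference import FitConfig, fit_ml
        from fpmat.synth import generate_dataset

        cfg = FitConfig(n_grid=12, n_cells=25, dt=1.0, refine=True,
                        refine_iters=1, refine_points=5, seed=777, tau2=6.0)
        shifts = {}
        for t50 in (6.9, 50.0):
            p = AbundanceParams(kind="one_step", k_r=1, k_dr=LN2 / 10,
                                k_p=1, k_m=LN2 / t50)
            ds = generate_dataset(p, n_cells=30, seed=55, dt=0.2,
                                  noise_rule=None)
            fit = fit_ml(ds, cfg, "one_step")
            shifts[t50] = abs(fit.half_time - t50) / t50
        assert shifts[6.9] > shifts[50.0]
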