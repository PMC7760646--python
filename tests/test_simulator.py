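"""Simulator tests: accuracy against the closed-form linear solution,
conservation properties, threshold metrics and the dose sweep."""

import numpy as np
import pytest

from nimopk import (DoseEvent, ModelParameters, SimulationResult, dose_sweep,
                    simulate, successive_increases, time_above_threshold)
from conftest import linear_infusion_conc


@pytest.fixture(scope="module")
def obs_grid():
    return np.arange(0.0, 672.0 + 1e-9, 2.0)


class TestLinearLimit:
    @pytest.mark.parametrize("engine", ["dopri", "lsoda"])
    def test_matches_biexponential_closed_form(self, linear_params, obs_grid,
                                               engine):
        sim = simulate(linear_params, DoseEvent(100.0), times=obs_grid,
                       rtol=1e-10, atol=1e-12, engine=engine)
        exact = linear_infusion_conc(linear_params, 100.0, 0.5, obs_grid)
        mask = exact > 0
        rel = np.abs(sim.free_central_conc[mask] - exact[mask]) / exact[mask]
        assert rel.max() < 1e-6

    def test_superposition(self, linear_params, obs_grid):
        s50 = simulate(linear_params, DoseEvent(50.0), times=obs_grid,
                       rtol=1e-10, atol=1e-12)
        s100 = simulate(linear_params, DoseEvent(100.0), times=obs_grid,
                        rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(2 * s50.free_central_conc,
                                   s100.free_central_conc, rtol=1e-8,
                                   atol=1e-12)

    def test_mass_balance_cl_auc_equals_dose(self, linear_params):
        # extend the horizon until the residual amount is negligible
        p = linear_params
        horizon = 12_000.0
        times = np.arange(0.0, horizon + 1e-9, 1.0)
        sim = simulate(p, DoseEvent(100.0), times=times, rtol=1e-10, atol=1e-12)
        assert sim.free_central_conc[-1] * p.V1 < 1e-4 * 100.0
        auc = np.trapezoid(sim.free_central_conc, sim.times)
        assert p.CL * auc == pytest.approx(100.0, rel=5e-3)

    def test_multiple_dose_events_superpose(self, linear_params, obs_grid):
        # the event engine handles repeated infusions; in the linear limit
        # two identical staggered doses equal the sum of shifted profiles
        doses = [DoseEvent(50.0, start=0.0), DoseEvent(50.0, start=168.0)]
        sim = simulate(linear_params, doses, times=obs_grid, rtol=1e-10,
                       atol=1e-12)
        first = linear_infusion_conc(linear_params, 50.0, 0.5, obs_grid)
        shifted = np.where(obs_grid >= 168.0,
                           linear_infusion_conc(linear_params, 50.0, 0.5,
                                                np.clip(obs_grid - 168.0, 0, None)),
                           0.0)
        np.testing.assert_allclose(sim.free_central_conc, first + shifted,
                                   rtol=1e-6, atol=1e-12)

    def test_one_compartment_bolus_limit(self):
        p = ModelParameters(Rtot=0.0, Rtotp=0.0, Smax=0.0, Q=1e-12)
        times = np.arange(0.0, 400.0, 1.0)
        sim = simulate(p, DoseEvent(100.0, duration=0.01), times=times,
                       rtol=1e-10, atol=1e-12)
        post = times > 0.02
        expected = (100.0 / p.V1) * np.exp(-p.CL / p.V1 * (times[post] - 0.01))
        np.testing.assert_allclose(sim.free_central_conc[post], expected,
                                   rtol=1e-3)


class TestSimulate:
    def test_reference_profile_is_well_behaved(self, typical):
        sim = simulate(typical, DoseEvent(100.0))
        c = sim.total_central_conc
        assert np.all(np.isfinite(c))
        peak = int(np.argmax(c))
        assert np.all(np.diff(c[peak:]) <= 1e-9)   # unimodal decline
        assert c[-1] < 0.02 * c.max()              # washes out by 1000 h
        assert np.all(sim.mediator >= 1.0 - 1e-9)
        assert np.all(sim.mediator <= 1.0 + typical.Smax + 1e-9)

    def test_inert_mediator_stays_at_baseline(self, typical):
        sim = simulate(typical.replace(Smax=0.0), DoseEvent(400.0))
        np.testing.assert_allclose(sim.mediator, 1.0, atol=1e-9)

    def test_engines_agree_on_nonlinear_model(self, typical):
        times = np.arange(0.0, 672.0, 4.0)
        a = simulate(typical, DoseEvent(200.0), times=times, rtol=1e-9,
                     atol=1e-11, engine="dopri")
        b = simulate(typical, DoseEvent(200.0), times=times, rtol=1e-9,
                     atol=1e-11, engine="lsoda")
        np.testing.assert_allclose(a.free_central_conc, b.free_central_conc,
                                   rtol=1e-6)

    def test_tolerance_refinement_stability(self, typical):
        times = np.arange(0.0, 1000.0 + 1e-9, 0.5)
        coarse = simulate(typical, DoseEvent(100.0), times=times,
                          rtol=1e-8, atol=1e-10)
        fine = simulate(typical, DoseEvent(100.0), times=times,
                        rtol=5e-9, atol=5e-11)
        for sim_pair in [(coarse, fine)]:
            m = [time_above_threshold(s, typical.Kss) for s in sim_pair]
            assert abs(m[0] - m[1]) / m[1] < 1e-3
        auc = [np.trapezoid(s.total_central_conc, s.times) for s in (coarse, fine)]
        assert abs(auc[0] - auc[1]) / auc[1] < 1e-3

    def test_input_validation(self, typical):
        with pytest.raises(ValueError):
            DoseEvent(-5.0)
        with pytest.raises(ValueError):
            DoseEvent(100.0, duration=0.0)
        with pytest.raises(ValueError):
            simulate(typical, [], times=np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            simulate(typical, DoseEvent(100.0), times=np.array([2.0, 1.0]))
        with pytest.raises(ValueError):
            simulate(typical, DoseEvent(100.0), rtol=-1.0)


class TestTimeAboveThreshold:
    @staticmethod
    def _series(times, conc):
        c = np.asarray(conc, dtype=float)
        return SimulationResult(times=np.asarray(times, dtype=float),
                                free_central_conc=c, total_central_conc=c,
                                peripheral_conc=np.zeros_like(c),
                                mediator=np.ones_like(c))

    def test_always_below_gives_zero(self):
        sim = self._series([0, 1, 2, 3], [1, 1, 1, 1])
        assert time_above_threshold(sim, 5.0) == 0.0

    def test_piecewise_linear_crossings(self):
        # rises through the threshold at t=1 and falls back at t=3
        sim = self._series([0, 2, 4], [0, 20, 0])
        assert time_above_threshold(sim, 10.0) == pytest.approx(2.0)

    def test_interpolated_partial_interval(self):
        sim = self._series([0, 1], [0, 30.0])
        assert time_above_threshold(sim, 10.0) == pytest.approx(2.0 / 3.0)

    def test_invalid_inputs(self):
        sim = self._series([0, 1], [1, 1])
        with pytest.raises(ValueError):
            time_above_threshold(sim, -1.0)
        with pytest.raises(ValueError):
            time_above_threshold(sim, 1.0, which="bogus")


class TestDoseSweep:
    def test_auc_proportional_to_dose_in_linear_limit(self, linear_params):
        p = linear_params.replace(v1_dose50_change=1e-12)
        sweep = dose_sweep(p, doses=(50.0, 100.0, 200.0), horizon=600.0,
                           grid_step=1.0)
        ref = sweep[50.0].auc_total / 50.0
        for d, m in sweep.items():
            assert m.auc_total / d == pytest.approx(ref, rel=1e-3)

    def test_v1_adjustment_only_on_50mg_arm(self, typical):
        sweep = dose_sweep(typical, doses=(50.0, 100.0), horizon=48.0,
                           grid_step=0.5)
        v1_50 = typical.v1_for_dose(50.0)
        # end-of-infusion free concentration reflects the arm-specific volume
        assert sweep[50.0].cmax_free == pytest.approx(50.0 / v1_50, rel=0.05)
        assert sweep[100.0].cmax_free == pytest.approx(100.0 / typical.V1,
                                                       rel=0.05)

    def test_mediator_peak_nondecreasing_and_saturating(self, typical):
        sweep = dose_sweep(typical, horizon=1000.0, grid_step=1.0)
        peaks = [sweep[d].result.mediator.max() for d in sorted(sweep)]
        assert all(b >= a - 1e-9 for a, b in zip(peaks, peaks[1:]))
        assert peaks[-1] <= 1.0 + typical.Smax + 1e-9
        # the mediator turnover (1/kout ~ 75 h) limits how closely the peak
        # approaches the 1 + Smax ceiling even at the largest dose
        assert peaks[-1] > 1.0 + 0.8 * typical.Smax

    def test_successive_increase_metric(self):
        from nimopk.simulator import DoseMetrics
        sweep = {
            50.0: DoseMetrics(50.0, 0, 0, 0, 10.0),
            100.0: DoseMetrics(100.0, 0, 0, 0, 25.0),
        }
        incr = successive_increases(sweep)
        assert incr[(50.0, 100.0)] == pytest.approx(150.0)
        sweep[50.0].time_above_kss = 0.0
        assert successive_increases(sweep)[(50.0, 100.0)] == float("inf")
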