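"""Estimation-layer tests: likelihood identities, the Laplace marginal against
numerical quadrature, model comparison rules and covariate screening."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from nimopk import (CovariateEffect, FitOptions, ModelParameters, TrialDesign,
                    compare_models, fit, generate_trial, individual_neg2ll,
                    marginal_neg2ll, scm, simulate)
from nimopk.estimation import (FitResult, InvalidComparisonError,
                               _subject_arrays, data_hash)
from nimopk.synthetic_data import SubjectRecord, TrialDataset
from nimopk import _ode


@pytest.fixture(scope="module")
def small_trial(typical):
    design = TrialDesign(n_per_cohort=1)
    return generate_trial(typical, design, seed=2024)


@pytest.fixture(scope="module")
def noise_free_subject(typical):
    p = typical.replace(omega_Rtotp=0.0, omega_kout=0.0, sigma_log=0.0)
    design = TrialDesign(n_per_cohort=1, dose_levels=(100.0,))
    return generate_trial(p, design, seed=1).subjects[0]


class TestIndividualNeg2LL:
    def test_exact_predictions_leave_only_constant(self, typical,
                                                   noise_free_subject):
        # with y == Cpred the quadratic term vanishes: n * log(2 pi sigma^2)
        p = typical.replace(omega_Rtotp=0.0, omega_kout=0.0, sigma_log=0.3)
        n = len(noise_free_subject.times)
        val = individual_neg2ll(noise_free_subject, p)
        assert val == pytest.approx(n * math.log(2 * math.pi * 0.3 ** 2),
                                    rel=1e-6)

    def test_doubling_sigma_quarters_quadratic_term(self, small_trial, typical):
        s = small_trial.subjects[0]
        n = len(s.times)

        def quad_term(sig):
            p = typical.replace(sigma_log=sig)
            return (individual_neg2ll(s, p)
                    - n * math.log(2 * math.pi * sig ** 2)) * sig ** 2

        # residuals are fixed, so SSR = quad_term is sigma-invariant,
        # i.e. the sigma^-2-weighted term scales exactly by 1/4
        assert quad_term(0.4) == pytest.approx(quad_term(0.8), rel=1e-9)

    def test_matches_literal_gaussian_density_sum(self, small_trial, typical):
        # independent oracle: scipy.stats.norm on log residuals with
        # predictions from the LSODA engine
        s = small_trial.subjects[0]
        sim = simulate(typical, s.dose_event, times=s.times, engine="lsoda",
                       rtol=1e-10, atol=1e-12, v1=typical.v1_for_dose(s.dose))
        oracle = -2.0 * norm.logpdf(np.log(s.conc),
                                    loc=np.log(sim.total_central_conc),
                                    scale=typical.sigma_log).sum()
        assert individual_neg2ll(s, typical) == pytest.approx(oracle, rel=1e-6)

    def test_nonpositive_observation_rejected(self, small_trial, typical):
        import dataclasses
        s = dataclasses.replace(small_trial.subjects[0],
                                conc=np.array([0.0, 1.0]),
                                times=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            individual_neg2ll(s, typical)


class TestMarginalNeg2LL:
    def test_zero_omega_reduces_to_individual_sum(self, small_trial, typical):
        p = typical.replace(omega_Rtotp=0.0, omega_kout=0.0)
        m = marginal_neg2ll(small_trial, p)
        s = sum(individual_neg2ll(sub, p) for sub in small_trial.subjects)
        assert m == pytest.approx(s, rel=1e-6)

    def test_uninformative_subject_leaves_ofv_unchanged(self, small_trial,
                                                        typical):
        empty = SubjectRecord(id=999, dose=100.0, infusion_duration=0.5,
                              covariates={}, times=np.array([]),
                              conc=np.array([]))
        bigger = TrialDataset(subjects=small_trial.subjects + [empty])
        assert marginal_neg2ll(bigger, typical) == pytest.approx(
            marginal_neg2ll(small_trial, typical), abs=1e-9)

    def test_laplace_matches_adaptive_quadrature(self, typical):
        # one-subject, one-random-effect toy in a sharp-posterior regime
        # (small sigma keeps the eta posterior near-Gaussian, where the
        # Laplace and Gauss-Newton curvature approximations are accurate)
        p = typical.replace(omega_Rtotp=0.5, omega_kout=1e-8, sigma_log=0.02)
        design = TrialDesign(n_per_cohort=1, dose_levels=(100.0,))
        data = generate_trial(p, design, seed=6)
        s = data.subjects[0]
        bounds, rates, t_obs, log_y = _subject_arrays(s)
        th = p.structural_array(v1=p.v1_for_dose(s.dose))
        s2 = p.sigma_log ** 2
        n = len(t_obs)

        def minus_log_like(eta1):
            f, ok = _ode._eta_log_pred(th, eta1, 0.0, bounds, rates, t_obs,
                                       1e-9, 1e-11)
            assert ok
            r = log_y - f
            return 0.5 * (r @ r) / s2 + 0.5 * n * math.log(2 * math.pi * s2)

        ref = minus_log_like(0.0)

        def integrand(eta1):
            return math.exp(-(minus_log_like(eta1) - ref)) \
                * norm.pdf(eta1, 0.0, p.omega_Rtotp)

        integral, err = quad(integrand, -6 * p.omega_Rtotp,
                             6 * p.omega_Rtotp, limit=200)
        oracle = 2.0 * ref - 2.0 * math.log(integral)
        got = marginal_neg2ll(data, p)
        # agreement to 1e-3 on the -2LL scale (the value has magnitude ~1e2)
        assert got == pytest.approx(oracle, rel=1e-3)


class TestFit:
    def test_perfect_data_recovery(self, typical):
        gen = typical.replace(omega_Rtotp=0.0, omega_kout=0.0, sigma_log=0.0)
        data = generate_trial(gen, TrialDesign(n_per_cohort=2), seed=3)
        init = typical.replace(CL=typical.CL * 1.3, V1=typical.V1 * 0.8,
                               omega_Rtotp=0.0, omega_kout=0.0, sigma_log=0.2)
        fr = fit(data, init, estimate=("CL", "V1"),
                 options=FitOptions(maxfev=400, xtol=1e-4))
        assert fr.estimates.CL == pytest.approx(typical.CL, rel=0.01)
        assert fr.estimates.V1 == pytest.approx(typical.V1, rel=0.01)
        # perfect fit: every individual residual vanishes
        assert fr.eps_shrinkage == pytest.approx(100.0, abs=1.0)

    def test_ofv_never_worse_than_init(self, small_trial, typical):
        fr = fit(small_trial, typical, estimate=("CL",),
                 options=FitOptions(maxfev=60))
        assert fr.ofv <= fr.convergence["ofv_initial"] + 1e-9

    def test_nothing_to_estimate_returns_marginal(self, small_trial, typical):
        fr = fit(small_trial, typical, estimate=())
        # fit refines the inner eta modes with a second warm-started pass, so
        # its OFV can sit slightly below the single cold evaluation
        assert fr.ofv == pytest.approx(marginal_neg2ll(small_trial, typical),
                                       abs=0.01)
        assert fr.ofv <= marginal_neg2ll(small_trial, typical) + 1e-9
        assert fr.convergence["success"]
        assert set(fr.ebe.index) == {s.id for s in small_trial.subjects}

    def test_conflicting_masks_rejected(self, small_trial, typical):
        with pytest.raises(ValueError):
            fit(small_trial, typical, fixed_mask=("CL",), estimate=("CL",))


class TestCompareModels:
    @staticmethod
    def _mk(ofv, n_est, h="abc"):
        return FitResult(
            estimates=ModelParameters(), ofv=ofv,
            ebe=pd.DataFrame(columns=["eta_Rtotp", "eta_kout"]),
            eta_shrinkage={}, eps_shrinkage=0.0,
            convergence={"success": True}, fixed_mask=(),
            estimated=tuple(f"p{i}" for i in range(n_est)), data_hash=h)

    def test_nested_threshold(self):
        small, large = self._mk(1000.0, 3), self._mk(992.1, 4)
        dec = compare_models(small, large, nested=True, df=1)
        assert dec.accept_larger and dec.preferred == "B"
        large_ns = self._mk(1000.0 - 7.0, 4)
        dec = compare_models(small, large_ns, nested=True, df=1)
        assert not dec.accept_larger and dec.preferred == "A"

    def test_zero_improvement_rejected(self):
        dec = compare_models(self._mk(500.0, 3), self._mk(500.0, 4), nested=True)
        assert not dec.accept_larger

    def test_aic_prefers_smaller_on_equal_ofv(self):
        a, b = self._mk(500.0, 3), self._mk(500.0, 5)
        assert compare_models(a, b, nested=False).preferred == "A"

    def test_antisymmetric_and_reflexive(self):
        a, b = self._mk(500.0, 3), self._mk(490.0, 5)
        d1 = compare_models(a, b, nested=False)
        d2 = compare_models(b, a, nested=False)
        assert {d1.preferred, d2.preferred} == {"A", "B"}
        assert d1.delta_ofv == -d2.delta_ofv
        same = compare_models(a, self._mk(500.0, 3), nested=False)
        assert same.preferred == "tie"

    def test_mismatched_data_rejected(self):
        with pytest.raises(InvalidComparisonError):
            compare_models(self._mk(1.0, 1, "x"), self._mk(2.0, 1, "y"),
                           nested=False)


class TestScm:
    def test_shrinkage_gate_skips_screening(self, small_trial, typical):
        base = fit(small_trial, typical, estimate=())
        base.eta_shrinkage = {"Rtotp": 60.0, "kout": 80.0}
        res = scm(small_trial, base, parameters=("Rtotp", "kout"),
                  covariates=("WT",))
        assert res.empty
        assert "shrinkage" in res.reason
        assert set(res.excluded_parameters) == {"Rtotp", "kout"}

    def test_detects_strong_injected_effect(self, typical):
        gen = typical.replace(omega_Rtotp=0.3, omega_kout=0.3, sigma_log=0.15)
        eff = CovariateEffect("CL", "WT", 1.5, reference=65.7)
        data = generate_trial(gen, TrialDesign(n_per_cohort=2), seed=8,
                              covariate_effects=[eff])
        base = fit(data, gen, estimate=())
        res = scm(data, base, parameters=("CL",), covariates=("WT",),
                  options=FitOptions(maxfev=80))
        assert any(t.parameter == "CL" and t.covariate == "WT"
                   for t in res.selected)
        coeff = res.selected[0].coefficient
        assert coeff == pytest.approx(1.5, abs=0.5)

    def test_requires_converged_base(self, small_trial, typical):
        base = fit(small_trial, typical, estimate=())
        base.convergence = {"success": False}
        with pytest.raises(ValueError):
            scm(small_trial, base)


def test_data_hash_distinguishes_datasets(typical):
    a = generate_trial(typical, TrialDesign(n_per_cohort=1), seed=1)
    b = generate_trial(typical, TrialDesign(n_per_cohort=1), seed=2)
    assert data_hash(a) != data_hash(b)
    assert data_hash(a) == data_hash(
        generate_trial(typical, TrialDesign(n_per_cohort=1), seed=1))
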