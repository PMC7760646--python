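"""Population estimation: Laplace-approximated marginal likelihood.

The population model has log-normal random effects on ``Rtotp`` and ``kout``
and additive Gaussian error on log concentration.  The marginal -2
log-likelihood (the objective function value, OFV) is obtained per subject by
locating the posterior mode of the two random effects (damped Gauss-Newton in
the compiled kernel) and applying the Laplace correction with the Gauss-Newton
curvature.  Fixed effects, variances and residual SD are then optimized on the
log scale with a derivative-free simplex search.  Laplace replaces the
original analysis' SAEM/importance-sampling machinery: same model, same error
structure, a different (deterministic) marginalization.

Also here: model comparison by OFV/AIC and the stepwise covariate procedure
(forward inclusion at p<0.05, backward elimination at p<0.01, power/fractional
functional forms, eta-shrinkage gate).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _ode
from .model_core import ModelParameters
from .synthetic_data import (CovariateEffect, SubjectRecord, TrialDataset,
                             SEX_CODE, RACE_CODE)

__all__ = [
    "FitOptions",
    "FitResult",
    "individual_neg2ll",
    "marginal_neg2ll",
    "fit",
    "compare_models",
    "ModelComparison",
    "InvalidComparisonError",
    "scm",
    "ScmResult",
    "DEFAULT_FIXED",
    "DEFAULT_ESTIMABLE",
]

#: parameters that the optimizer may estimate (log scale)
DEFAULT_ESTIMABLE = ("CL", "V1", "Q", "V2", "Kss", "kint", "Rtot", "Rtotp",
                     "kout", "Smax", "S50", "gamma",
                     "omega_Rtotp", "omega_kout", "sigma_log")
#: default identifiability mask for 20-subject trials
DEFAULT_FIXED = ("Kss", "kint", "Rtot", "gamma")

_OMEGA_FLOOR = 1e-8
_NESTED_SELECTION_DELTA = 7.879   # chi2(1), p = 0.005 (model development)
_SCM_FORWARD_DELTA = 3.84         # chi2(1), p = 0.05
_SCM_BACKWARD_DELTA = 6.63        # chi2(1), p = 0.01
_SHRINKAGE_GATE = 35.0            # % — screening gate on eta-shrinkage


@dataclass
class FitOptions:
    """Numerical settings for the marginal-likelihood machinery."""

    rtol: float = 1e-8            # ODE tolerance inside the likelihood
    atol: float = 1e-10
    inner_max_iter: int = 30      # Gauss-Newton iterations for the eta mode
    inner_gtol: float = 1e-3
    method: str = "Nelder-Mead"
    maxfev: int = 1500
    xtol: float = 1e-3            # on log-parameters
    ftol: float = 1e-6
    log_bound: float = 2.0        # search box half-width on log-parameters


@dataclass
class FitResult:
    """Outcome of a population fit."""

    estimates: ModelParameters
    ofv: float
    ebe: pd.DataFrame                   # per-subject eta estimates
    eta_shrinkage: dict                 # % per random effect
    eps_shrinkage: float                # %
    convergence: dict
    fixed_mask: tuple
    estimated: tuple
    covariate_terms: tuple = ()
    data_hash: str = ""

    @property
    def n_estimated(self) -> int:
        return len(self.estimated) + len(self.covariate_terms)

    @property
    def aic(self) -> float:
        return self.ofv + 2.0 * self.n_estimated

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates.to_dict(),
            "ofv": self.ofv,
            "aic": self.aic,
            "eta_shrinkage_pct": self.eta_shrinkage,
            "eps_shrinkage_pct": self.eps_shrinkage,
            "convergence": self.convergence,
            "fixed_mask": list(self.fixed_mask),
            "estimated": list(self.estimated),
            "covariate_terms": [
                {"parameter": t.parameter, "covariate": t.covariate,
                 "coefficient": t.coefficient, "reference": t.reference,
                 "kind": t.kind}
                for t in self.covariate_terms],
            "data_hash": self.data_hash,
            "ebe": {str(i): list(map(float, row))
                    for i, row in zip(self.ebe.index, self.ebe.to_numpy())},
        }


# --------------------------------------------------------------------------
# data plumbing
# --------------------------------------------------------------------------

def _subject_arrays(s: SubjectRecord):
    t_obs = np.asarray(s.times, dtype=float)
    if np.any(s.conc <= 0):
        raise ValueError(f"subject {s.id}: non-positive observed concentration")
    log_y = np.log(np.asarray(s.conc, dtype=float))
    end = max(float(t_obs[-1]) if len(t_obs) else s.infusion_duration,
              s.infusion_duration)
    bounds = np.array([0.0, s.infusion_duration, end])
    rates = np.array([s.dose / s.infusion_duration, 0.0])
    return bounds, rates, t_obs, log_y


def _covariate_value(s: SubjectRecord, name: str) -> float:
    v = s.covariates[name]
    if name == "SEX" and isinstance(v, str):
        return float(SEX_CODE[v])
    if name == "RACE":
        if isinstance(v, str):
            return 1.0 if v == "Caucasian" else 0.0
        return 1.0 if int(v) == RACE_CODE["Caucasian"] else 0.0
    return float(v)


def _subject_theta(p: ModelParameters, s: SubjectRecord,
                   terms: Sequence[CovariateEffect]) -> np.ndarray:
    """Structural parameter vector for one subject's typical values."""
    typ = p
    if terms:
        changes: dict = {}
        for t in terms:
            cur = changes.get(t.parameter, getattr(typ, t.parameter))
            changes[t.parameter] = cur * t.multiplier(_covariate_value(s, t.covariate))
        typ = replace(typ, **changes)
    v1 = typ.v1_for_dose(s.dose)
    return typ.structural_array(v1=v1)


def data_hash(data: TrialDataset) -> str:
    h = hashlib.sha1()
    for s in data.subjects:
        h.update(np.asarray([s.id, s.dose, s.infusion_duration]).tobytes())
        h.update(np.asarray(s.times, dtype=float).tobytes())
        h.update(np.asarray(s.conc, dtype=float).tobytes())
    return h.hexdigest()


# --------------------------------------------------------------------------
# likelihood
# --------------------------------------------------------------------------

def individual_neg2ll(subject: SubjectRecord, p_ind: ModelParameters,
                      options: FitOptions | None = None) -> float:
    """-2 log-likelihood of one subject at fixed individual parameters.

    ``sum_j [ log(2 pi sigma^2) + (log y_j - log Cpred_j)^2 / sigma^2 ]`` with
    the prediction from the ODE solution + total-concentration observable.
    """
    opt = options or FitOptions()
    bounds, rates, t_obs, log_y = _subject_arrays(subject)
    th = p_ind.structural_array(v1=p_ind.v1_for_dose(subject.dose))
    val, ok = _ode.individual_neg2ll_kernel(th, bounds, rates, t_obs, log_y,
                                            p_ind.sigma_log, opt.rtol, opt.atol)
    if not ok:
        raise RuntimeError(f"integration failed for subject {subject.id}")
    return float(val)


def _marginal_components(data: TrialDataset, p: ModelParameters,
                         terms: Sequence[CovariateEffect],
                         eta_out: dict, opt: FitOptions,
                         eta_start: Mapping | None = None):
    """Per-subject Laplace contributions; fills eta_out with the modes.

    The eta mode search starts from ``eta_start`` (default: the prior mode
    (0, 0)).  The start must not depend on the optimizer's evaluation
    history: the inner surface can carry nearby secondary modes, and a
    history-dependent warm start makes the outer objective path-dependent,
    which derails derivative-free outer optimizers.  ``fit`` passes the modes
    found once at the initial parameters, which is deterministic and cuts the
    inner iteration count.
    """
    om1 = max(p.omega_Rtotp, _OMEGA_FLOOR)
    om2 = max(p.omega_kout, _OMEGA_FLOOR)
    zero = np.zeros(2)
    out = np.empty(len(data.subjects))
    for k, s in enumerate(data.subjects):
        bounds, rates, t_obs, log_y = _subject_arrays(s)
        th = _subject_theta(p, s, terms)
        eta0 = zero if eta_start is None else eta_start.get(s.id, zero)
        val, e1, e2, ok = _ode.laplace_subject(
            th, bounds, rates, t_obs, log_y, p.sigma_log, om1, om2,
            eta0, opt.rtol, opt.atol, opt.inner_max_iter, opt.inner_gtol)
        if not ok or not math.isfinite(val):
            raise RuntimeError(
                f"inner optimization failed for subject {s.id}")
        eta_out[s.id] = np.array([e1, e2])
        out[k] = val
    return out


def marginal_neg2ll(data: TrialDataset, p: ModelParameters,
                    covariate_terms: Sequence[CovariateEffect] = (),
                    options: FitOptions | None = None) -> float:
    """Laplace-approximate marginal -2 log-likelihood of the whole dataset."""
    if len(data.subjects) == 0:
        raise ValueError("dataset has no subjects")
    opt = options or FitOptions()
    comps = _marginal_components(data, p, covariate_terms, {}, opt)
    return float(comps.sum())


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def fit(data: TrialDataset,
        init: ModelParameters,
        fixed_mask: Sequence[str] = DEFAULT_FIXED,
        estimate: Sequence[str] | None = None,
        covariate_terms: Sequence[CovariateEffect] = (),
        estimate_covariates: bool = False,
        options: FitOptions | None = None) -> FitResult:
    """Maximize the Laplace marginal likelihood from ``init``.

    Parameters
    ----------
    fixed_mask : names held fixed at their ``init`` values.
    estimate : explicit list of parameters to estimate (overrides the default
        estimable set minus ``fixed_mask``).
    covariate_terms : covariate effects applied during fitting; their
        coefficients are estimated too when ``estimate_covariates`` is True.
    """
    opt = options or FitOptions()
    if estimate is None:
        names = tuple(n for n in DEFAULT_ESTIMABLE if n not in set(fixed_mask))
    else:
        overlap = set(estimate) & set(fixed_mask)
        if overlap:
            raise ValueError(f"parameters both fixed and estimated: {sorted(overlap)}")
        names = tuple(estimate)
    n_cov = len(covariate_terms) if estimate_covariates else 0

    x0 = np.array([math.log(max(getattr(init, n), 1e-12)) for n in names]
                  + [t.coefficient for t in covariate_terms[:n_cov]])

    def build(x):
        changes = {n: math.exp(x[i]) for i, n in enumerate(names)}
        p = init.replace(**changes)
        if n_cov:
            terms = tuple(replace(t, coefficient=float(c))
                          for t, c in zip(covariate_terms, x[len(names):]))
            terms += tuple(covariate_terms[n_cov:])
        else:
            terms = tuple(covariate_terms)
        return p, terms

    # deterministic warm start for the inner mode search: the modes at `init`
    eta_ref: dict = {}
    scratch: dict = {}
    p0, terms0 = build(x0)
    comps0 = _marginal_components(data, p0, terms0, eta_ref, opt)
    ofv0 = float(comps0.sum())

    def objective(x):
        # soft box around the initial point: keeps the derivative-free search
        # out of physiologically absurd regions where the ODE turns stiff and
        # expensive; the gentle slope steers the simplex back inside
        over = np.abs(x[:len(names)] - x0[:len(names)]) - opt.log_bound
        if np.any(over > 0):
            return 1e9 + 1e3 * float(np.sum(np.clip(over, 0.0, None)))
        try:
            p, terms = build(x)
        except ValueError:
            return 1e9
        try:
            comps = _marginal_components(data, p, terms, scratch, opt,
                                         eta_start=eta_ref)
        except RuntimeError:
            return 1e9
        val = float(comps.sum())
        return val if math.isfinite(val) else 1e9

    if len(x0):
        if opt.method == "Nelder-Mead":
            res = minimize(objective, x0, method="Nelder-Mead",
                           options={"maxfev": opt.maxfev, "xatol": opt.xtol,
                                    "fatol": opt.ftol, "adaptive": len(x0) > 4})
        else:
            res = minimize(objective, x0, method=opt.method,
                           options={"maxfev": opt.maxfev, "xtol": opt.xtol,
                                    "ftol": opt.ftol})
        x_best, success, nfev, message = res.x, bool(res.success), res.nfev, str(res.message)
    else:
        x_best, success, nfev, message = x0, True, 1, "nothing to estimate"

    p_hat, terms_hat = build(x_best)
    eta_hat: dict = {}
    ofv = float(_marginal_components(data, p_hat, terms_hat, eta_hat, opt,
                                     eta_start=eta_ref).sum())
    if ofv > ofv0:
        # the search never improved on the initial point; keep the init
        x_best = x0
        p_hat, terms_hat = build(x_best)
        eta_hat = dict(eta_ref)
        ofv = ofv0
        success = success and math.isclose(ofv, ofv0, rel_tol=1e-6)

    # empirical Bayes estimates and shrinkage at the optimum
    ids = [s.id for s in data.subjects]
    ebe = pd.DataFrame(
        [eta_hat.get(i, np.zeros(2)) for i in ids],
        index=ids, columns=["eta_Rtotp", "eta_kout"])
    eta_shr = {}
    for col, om in (("eta_Rtotp", p_hat.omega_Rtotp), ("eta_kout", p_hat.omega_kout)):
        name = col.removeprefix("eta_")
        sd = float(ebe[col].std(ddof=1)) if len(ebe) > 1 else 0.0
        eta_shr[name] = 100.0 * (1.0 - sd / om) if om > 0 else float("nan")

    iwres = _iwres(data, p_hat, terms_hat, ebe, opt)
    eps_shr = 100.0 * (1.0 - float(np.std(iwres, ddof=1))) if len(iwres) > 1 else float("nan")

    return FitResult(
        estimates=p_hat,
        ofv=float(ofv),
        ebe=ebe,
        eta_shrinkage=eta_shr,
        eps_shrinkage=eps_shr,
        convergence={"success": success, "nfev": int(nfev), "message": message,
                     "ofv_initial": float(ofv0)},
        fixed_mask=tuple(fixed_mask) if estimate is None else
                   tuple(n for n in DEFAULT_ESTIMABLE if n not in names),
        estimated=names,
        covariate_terms=terms_hat,
        data_hash=data_hash(data),
    )


def _iwres(data, p, terms, ebe, opt):
    """Individual weighted residuals on the log scale, all subjects pooled."""
    out = []
    for s in data.subjects:
        if len(s.times) == 0:
            continue
        bounds, rates, t_obs, log_y = _subject_arrays(s)
        th = _subject_theta(p, s, terms)
        e = ebe.loc[s.id].to_numpy() if s.id in ebe.index else np.zeros(2)
        f, ok = _ode._eta_log_pred(th, e[0], e[1], bounds, rates, t_obs,
                                   opt.rtol, opt.atol)
        if not ok:
            raise RuntimeError(f"integration failed for subject {s.id}")
        out.append((log_y - f) / p.sigma_log)
    return np.concatenate(out) if out else np.array([])


# --------------------------------------------------------------------------
# model comparison
# --------------------------------------------------------------------------

class InvalidComparisonError(ValueError):
    """Fits being compared were not obtained on identical data."""


@dataclass(frozen=True)
class ModelComparison:
    preferred: str          # "A" | "B" | "tie"
    delta_ofv: float        # ofv_A - ofv_B (positive favours B)
    criterion: str          # "lrt" | "aic"
    threshold: float | None = None
    accept_larger: bool | None = None


def compare_models(fit_a: FitResult, fit_b: FitResult, nested: bool,
                   df: int = 1) -> ModelComparison:
    """Decide between two fits of the same data.

    Nested (A reduced, B full): accept the larger model iff the OFV drops by
    at least 7.879 units per degree of freedom (chi-square, p = 0.005).
    Non-nested: the lower AIC wins; exact AIC ties prefer the model with
    fewer estimated parameters.
    """
    if fit_a.data_hash != fit_b.data_hash:
        raise InvalidComparisonError("fits were obtained on different datasets")
    d = fit_a.ofv - fit_b.ofv
    if nested:
        if df < 1:
            raise ValueError("df must be >= 1")
        small, large = ((fit_a, "A"), (fit_b, "B"))
        if fit_a.n_estimated > fit_b.n_estimated:
            small, large = (fit_b, "B"), (fit_a, "A")
        drop = small[0].ofv - large[0].ofv
        accept = drop >= _NESTED_SELECTION_DELTA * df
        return ModelComparison(
            preferred=large[1] if accept else small[1],
            delta_ofv=d, criterion="lrt",
            threshold=_NESTED_SELECTION_DELTA * df, accept_larger=accept)
    aic_a, aic_b = fit_a.aic, fit_b.aic
    if aic_a == aic_b:
        if fit_a.n_estimated == fit_b.n_estimated:
            pref = "tie"
        else:
            pref = "A" if fit_a.n_estimated < fit_b.n_estimated else "B"
    else:
        pref = "A" if aic_a < aic_b else "B"
    return ModelComparison(preferred=pref, delta_ofv=d, criterion="aic")


# --------------------------------------------------------------------------
# stepwise covariate model building
# --------------------------------------------------------------------------

DEFAULT_SCM_COVARIATES = ("AGE", "WT", "HT", "BSA", "SCR", "CRCL", "TKV",
                          "TCV", "SEX")
_CATEGORICAL = {"SEX", "RACE"}
_IIV_PARAMETERS = {"Rtotp", "kout"}


@dataclass
class ScmResult:
    selected: tuple                 # CovariateEffect terms retained
    trace: list                     # step-by-step record
    base_ofv: float
    final_ofv: float
    screened_parameters: tuple
    excluded_parameters: dict       # name -> reason
    reason: str = ""

    @property
    def empty(self) -> bool:
        return len(self.selected) == 0


def _candidate_term(data: TrialDataset, parameter: str, covariate: str) -> CovariateEffect:
    values = np.array([_covariate_value(s, covariate) for s in data.subjects])
    if covariate in _CATEGORICAL:
        return CovariateEffect(parameter, covariate, 0.0, reference=1.0,
                               kind="fractional")
    ref = float(np.median(values))
    return CovariateEffect(parameter, covariate, 0.0, reference=ref, kind="power")


def _fit_terms(data, base: FitResult, terms, opt) -> FitResult:
    """Refit with the given covariate terms; structural/variance parameters
    are held at the base estimates and only coefficients are estimated
    (univariate screening mode)."""
    return fit(data, base.estimates, estimate=(), covariate_terms=tuple(terms),
               estimate_covariates=True, options=opt)


def scm(data: TrialDataset,
        base: FitResult,
        covariates: Sequence[str] = DEFAULT_SCM_COVARIATES,
        parameters: Sequence[str] = ("CL", "Rtotp", "kout"),
        forward_delta: float = _SCM_FORWARD_DELTA,
        backward_delta: float = _SCM_BACKWARD_DELTA,
        shrinkage_gate: float = _SHRINKAGE_GATE,
        options: FitOptions | None = None) -> ScmResult:
    """Stepwise covariate model building, univariate forward/backward.

    Continuous covariates enter as power functions centered on the median,
    categorical ones as fractional shifts.  Parameters carrying a random
    effect are screened only when their eta-shrinkage is below the gate
    (default 35%); parameters without IIV are screened directly.  Forward
    inclusion requires an OFV drop >= 3.84 (chi-square df 1, p = 0.05),
    backward elimination retains a term only if removing it raises the OFV by
    >= 6.63 (p = 0.01).
    """
    opt = options or FitOptions()
    if not base.convergence.get("success", False):
        raise ValueError("base fit did not converge; SCM requires a converged base")

    excluded: dict = {}
    eligible = []
    for prm in parameters:
        if prm in _IIV_PARAMETERS:
            shr = base.eta_shrinkage.get(prm, float("nan"))
            if not math.isfinite(shr) or shr >= shrinkage_gate:
                excluded[prm] = (f"eta-shrinkage {shr:.1f}% >= gate "
                                 f"{shrinkage_gate:.0f}%")
                continue
        eligible.append(prm)
    trace: list = []
    if not eligible:
        return ScmResult(selected=(), trace=trace, base_ofv=base.ofv,
                         final_ofv=base.ofv, screened_parameters=(),
                         excluded_parameters=excluded,
                         reason="no eligible parameter (shrinkage gate)")

    candidates = [(prm, cov) for prm in eligible for cov in covariates]
    included: list[CovariateEffect] = []
    current_ofv = base.ofv

    # forward inclusion
    while True:
        best = None
        for prm, cov in candidates:
            if any(t.parameter == prm and t.covariate == cov for t in included):
                continue
            cand = _candidate_term(data, prm, cov)
            try:
                f = _fit_terms(data, base, included + [cand], opt)
            except RuntimeError:
                continue
            drop = current_ofv - f.ofv
            trace.append({"step": "forward", "parameter": prm, "covariate": cov,
                          "delta_ofv": drop,
                          "coefficient": f.covariate_terms[-1].coefficient,
                          "significant": drop >= forward_delta})
            if drop >= forward_delta and (best is None or f.ofv < best[1].ofv):
                best = (cand, f)
        if best is None:
            break
        cand, f = best
        included.append(f.covariate_terms[len(included)])
        current_ofv = f.ofv
        trace.append({"step": "forward-include", "parameter": cand.parameter,
                      "covariate": cand.covariate, "ofv": current_ofv})

    # backward elimination
    changed = True
    while changed and included:
        changed = False
        for term in list(included):
            rest = [t for t in included if t is not term]
            if rest:
                f = _fit_terms(data, base, rest, opt)
                ofv_without = f.ofv
            else:
                ofv_without = base.ofv
            rise = ofv_without - current_ofv
            keep = rise >= backward_delta
            trace.append({"step": "backward", "parameter": term.parameter,
                          "covariate": term.covariate, "delta_ofv": rise,
                          "retained": keep})
            if not keep:
                included = rest
                current_ofv = ofv_without
                changed = True
                break

    return ScmResult(selected=tuple(included), trace=trace, base_ofv=base.ofv,
                     final_ofv=current_ofv, screened_parameters=tuple(eligible),
                     excluded_parameters=excluded)
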