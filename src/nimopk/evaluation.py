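"""Model evaluation: pc-VPC, nonparametric bootstrap, goodness-of-fit residuals.

The prediction-corrected visual predictive check (pc-VPC) normalizes each
observation and each simulated observation by the median typical-population
prediction of its time bin (multiplicative on the natural scale, i.e.
additive on the log scale, matching the additive-log residual model), then
compares observed percentiles with the spread of the same percentiles across
simulated replicate trials.  The design is balanced, so the default bins are
the nominal sampling times themselves.

The bootstrap resamples subjects with replacement to the original size and
refits the final model on every replicate; medians and 2.5/97.5 percentiles
of the replicate estimates quantify parameter stability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _ode
from .estimation import (FitOptions, FitResult, _marginal_components,
                         _subject_arrays, _subject_theta, fit)
from .model_core import ModelParameters
from .synthetic_data import TrialDataset

__all__ = [
    "VPCResult",
    "BootstrapResult",
    "pc_vpc",
    "bootstrap",
    "gof_residuals",
]

_PCTL = (2.5, 50.0, 97.5)


@dataclass
class VPCResult:
    """Prediction-corrected VPC summary."""

    bins: np.ndarray                    # bin midpoints (nominal times), h
    observed: pd.DataFrame              # columns p2.5, p50, p97.5 per bin
    simulated_lo: pd.DataFrame          # 2.5th pct of each percentile across reps
    simulated_hi: pd.DataFrame          # 97.5th pct of each percentile across reps
    n_replicates: int

    def __post_init__(self):
        for b in range(len(self.bins)):
            obs = self.observed.iloc[b]
            if not (obs["p2.5"] <= obs["p50"] <= obs["p97.5"]):
                raise ValueError("observed percentiles out of order")
            for col in ("p2.5", "p50", "p97.5"):
                if self.simulated_lo.iloc[b][col] > self.simulated_hi.iloc[b][col]:
                    raise ValueError("simulated band bounds out of order")

    def median_coverage(self) -> float:
        """Fraction of bins whose observed median lies in the simulated
        95% interval of the median."""
        ok = ((self.observed["p50"] >= self.simulated_lo["p50"])
              & (self.observed["p50"] <= self.simulated_hi["p50"]))
        return float(ok.mean())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin_mid_h": self.bins})
        for col in ("p2.5", "p50", "p97.5"):
            tag = col[1:]
            df[f"obs_p{tag}"] = self.observed[col].to_numpy()
            df[f"sim_p{tag}_lo"] = self.simulated_lo[col].to_numpy()
            df[f"sim_p{tag}_hi"] = self.simulated_hi[col].to_numpy()
        return df


def _typical_log_predictions(data: TrialDataset, p: ModelParameters, opt: FitOptions):
    """Typical-population (eta = 0) log prediction for every observation."""
    preds = []
    for s in data.subjects:
        bounds, rates, t_obs, _ = _subject_arrays(s)
        th = _subject_theta(p, s, ())
        f, ok = _ode.predict_log_total(th, bounds, rates, t_obs, opt.rtol, opt.atol)
        if not ok:
            raise RuntimeError(f"integration failed for subject {s.id}")
        preds.append(f)
    return preds


def pc_vpc(
    data: TrialDataset,
    p: ModelParameters,
    n_sim: int = 1000,
    bins: Sequence[float] | None = None,
    seed: int = 0,
    options: FitOptions | None = None,
) -> VPCResult:
    """Prediction-corrected visual predictive check under parameters ``p``.

    Simulates ``n_sim`` replicates of the observed design (same subjects,
    doses and sampling times; fresh random effects and residuals), applies
    the bin-median prediction correction on the log scale to both observed
    and simulated data, and returns observed percentiles together with the
    95% interval of each percentile across replicates.
    """
    if n_sim < 50:
        raise ValueError("n_sim must be >= 50")
    opt = options or FitOptions()
    rng = np.random.default_rng(seed)

    log_pred = _typical_log_predictions(data, p, opt)
    all_times = np.concatenate([s.times for s in data.subjects])
    all_logy = np.concatenate([np.log(s.conc) for s in data.subjects])
    all_pred = np.concatenate(log_pred)

    if bins is None:
        bin_vals = np.unique(all_times)
    else:
        bin_vals = np.asarray(sorted(bins), dtype=float)
    # nearest-bin assignment (identity for the balanced default design)
    idx = np.abs(all_times[:, None] - bin_vals[None, :]).argmin(axis=1)

    # merge empty bins into their left neighbour
    counts = np.bincount(idx, minlength=len(bin_vals))
    if np.any(counts == 0):
        keep = counts > 0
        bin_vals = bin_vals[keep]
        idx = np.abs(all_times[:, None] - bin_vals[None, :]).argmin(axis=1)

    # log-scale prediction correction: log pcY = log y - log pred + log median(pred_bin)
    bin_log_med = np.array([np.median(all_pred[idx == b]) for b in range(len(bin_vals))])
    pc_obs = all_logy - all_pred + bin_log_med[idx]

    obs_pct = np.vstack([
        np.percentile(pc_obs[idx == b], _PCTL) for b in range(len(bin_vals))
    ])

    # simulate replicates of the design under p
    om = np.array([p.omega_Rtotp, p.omega_kout])
    sim_pct = np.empty((n_sim, len(bin_vals), 3))
    for r in range(n_sim):
        sim_logy = np.empty_like(all_pred)
        pos = 0
        for s, base_pred in zip(data.subjects, log_pred):
            eta = rng.normal(0.0, om)
            bounds, rates, t_obs, _ = _subject_arrays(s)
            th = _subject_theta(p, s, ())
            th_i = th.copy()
            th_i[7] *= math.exp(eta[0])   # Rtotp
            th_i[8] *= math.exp(eta[1])   # kout
            f, ok = _ode.predict_log_total(th_i, bounds, rates, t_obs,
                                           opt.rtol, opt.atol)
            if not ok:
                raise RuntimeError(f"integration failed in replicate {r}")
            eps = rng.normal(0.0, p.sigma_log, len(t_obs)) if p.sigma_log > 0 else 0.0
            sim_logy[pos:pos + len(t_obs)] = f + eps
            pos += len(t_obs)
        pc_sim = sim_logy - all_pred + bin_log_med[idx]
        for b in range(len(bin_vals)):
            sim_pct[r, b] = np.percentile(pc_sim[idx == b], _PCTL)

    lo = np.percentile(sim_pct, 2.5, axis=0)
    hi = np.percentile(sim_pct, 97.5, axis=0)

    cols = ["p2.5", "p50", "p97.5"]
    to_conc = np.exp  # percentiles back on the concentration scale
    return VPCResult(
        bins=bin_vals,
        observed=pd.DataFrame(to_conc(obs_pct), columns=cols),
        simulated_lo=pd.DataFrame(to_conc(lo), columns=cols),
        simulated_hi=pd.DataFrame(to_conc(hi), columns=cols),
        n_replicates=n_sim,
    )


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Nonparametric bootstrap of the population fit."""

    replicates: pd.DataFrame       # one row per successful refit
    median: pd.Series
    p2_5: pd.Series
    p97_5: pd.Series
    n_resamples: int
    n_failed: int
    unreliable: bool = False

    def __post_init__(self):
        for k in self.median.index:
            if not (self.p2_5[k] <= self.median[k] <= self.p97_5[k]):
                raise ValueError(f"percentile interval does not contain the "
                                 f"median for {k}")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"median": self.median, "p2.5": self.p2_5,
                             "p97.5": self.p97_5})


def bootstrap(
    data: TrialDataset,
    init: ModelParameters,
    n_resamples: int = 500,
    seed: int = 0,
    fixed_mask: Sequence[str] = None,
    estimate: Sequence[str] | None = None,
    options: FitOptions | None = None,
) -> BootstrapResult:
    """Resample subjects with replacement and refit each replicate.

    ``init`` should be the original fit's estimates so every replicate starts
    close to its optimum.  Failed refits are counted and excluded; if more
    than 20% fail the result is flagged unreliable.
    """
    from .estimation import DEFAULT_FIXED

    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    if fixed_mask is None:
        fixed_mask = DEFAULT_FIXED
    opt = options or FitOptions()
    rng = np.random.default_rng(seed)
    n = len(data.subjects)

    rows = []
    n_failed = 0
    for r in range(n_resamples):
        pick = rng.integers(0, n, size=n)
        subjects = []
        for new_id, k in enumerate(pick, start=1):
            s = data.subjects[k]
            import dataclasses as _dc
            subjects.append(_dc.replace(s, id=new_id))
        boot = TrialDataset(subjects=subjects, design=data.design, seed=None)
        try:
            fr = fit(boot, init, fixed_mask=fixed_mask, estimate=estimate,
                     options=opt)
        except (RuntimeError, ValueError):
            n_failed += 1
            continue
        if not math.isfinite(fr.ofv):
            n_failed += 1
            continue
        rows.append({k: getattr(fr.estimates, k) for k in fr.estimated})
    if not rows:
        raise RuntimeError("all bootstrap refits failed")

    reps = pd.DataFrame(rows)
    return BootstrapResult(
        replicates=reps,
        median=reps.median(),
        p2_5=reps.quantile(0.025),
        p97_5=reps.quantile(0.975),
        n_resamples=n_resamples,
        n_failed=n_failed,
        unreliable=n_failed > 0.2 * n_resamples,
    )


# --------------------------------------------------------------------------
# goodness of fit
# --------------------------------------------------------------------------

def gof_residuals(data: TrialDataset, fitted: FitResult,
                  options: FitOptions | None = None) -> pd.DataFrame:
    """Residual table for goodness-of-fit diagnostics.

    Per observation: population prediction (eta = 0), individual prediction
    (at the empirical Bayes estimates), IWRES (individual weighted residual
    on the log scale) and CWRES (conditional weighted residual from a
    first-order linearization of the log prediction around the EBE).
    """
    opt = options or FitOptions()
    p = fitted.estimates
    if not fitted.convergence.get("success", False):
        raise ValueError("gof_residuals requires a converged fit")
    om = np.array([max(p.omega_Rtotp, 1e-12), max(p.omega_kout, 1e-12)])
    omega = np.diag(om ** 2)
    sig = p.sigma_log

    rows = []
    d = 1e-3
    for s in data.subjects:
        if len(s.times) == 0:
            continue
        if s.id not in fitted.ebe.index:
            raise ValueError(f"missing empirical Bayes estimates for subject {s.id}")
        eta = fitted.ebe.loc[s.id].to_numpy(dtype=float)
        bounds, rates, t_obs, log_y = _subject_arrays(s)
        th = _subject_theta(p, s, fitted.covariate_terms)

        f_pop, ok0 = _ode.predict_log_total(th, bounds, rates, t_obs,
                                            opt.rtol, opt.atol)
        f_ind, ok1 = _ode._eta_log_pred(th, eta[0], eta[1], bounds, rates,
                                        t_obs, opt.rtol, opt.atol)
        f_d1, ok2 = _ode._eta_log_pred(th, eta[0] + d, eta[1], bounds, rates,
                                       t_obs, opt.rtol, opt.atol)
        f_d2, ok3 = _ode._eta_log_pred(th, eta[0], eta[1] + d, bounds, rates,
                                       t_obs, opt.rtol, opt.atol)
        if not (ok0 and ok1 and ok2 and ok3):
            raise RuntimeError(f"integration failed for subject {s.id}")

        J = np.column_stack([(f_d1 - f_ind) / d, (f_d2 - f_ind) / d])
        iwres = (log_y - f_ind) / sig
        # FOCE-style CWRES: mean linearized back to eta = 0
        mean_lin = f_ind - J @ eta
        cov = J @ omega @ J.T + sig ** 2 * np.eye(len(t_obs))
        evals, evecs = np.linalg.eigh(cov)
        inv_sqrt = evecs @ np.diag(evals ** -0.5) @ evecs.T
        cwres = inv_sqrt @ (log_y - mean_lin)

        for j in range(len(t_obs)):
            rows.append({
                "ID": s.id, "TIME": t_obs[j], "DV": s.conc[j],
                "PRED": math.exp(f_pop[j]), "IPRED": math.exp(f_ind[j]),
                "IWRES": iwres[j], "CWRES": cwres[j],
            })
    return pd.DataFrame(rows)
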