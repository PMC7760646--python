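"""Virtual phase-I trial generator.

Emulates the dose-escalation study the analysis assumes: 20 subjects in 4
cohorts of 5 receiving a single 30-min IV infusion of 50/100/200/400 mg, with
serum sampling at 23 nominal post-dose times between 0.5 and 672 h plus a
pre-dose sample.  Inter-individual variability is log-normal on ``Rtotp`` and
``kout`` (exponential model), residual error is additive on the natural-log
concentration, and covariates are drawn to match the observed cohort's summary
table (log-normals for continuous covariates, sex-specific for total kidney
volume; sex and race categorical).

Covariates are generated but, by default, exert no effect on the PK parameters
(the final model retained none) — they provide a true-negative test bed for
covariate screening.  An explicit ``covariate_effects`` argument can inject
known relationships for true-positive tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _ode
from .model_core import ModelParameters
from .simulator import DoseEvent, IntegrationError

__all__ = [
    "TrialDesign",
    "SubjectRecord",
    "TrialDataset",
    "CovariateEffect",
    "sample_individual",
    "sample_covariates",
    "generate_trial",
    "DEFAULT_MASTER_SEED",
]

DEFAULT_MASTER_SEED = 20201147

#: nominal post-dose sampling times, h
DEFAULT_SAMPLING_TIMES = (
    0.5, 1, 2, 6, 12, 24, 36, 48, 72, 96, 120, 144, 168,
    240, 338, 432, 504, 552, 576, 600, 624, 648, 672,
)

#: summary statistics of the observed cohort used to parameterize the
#: covariate distributions: name -> (mean, sd).  TKV is sex-specific.
COVARIATE_SUMMARY = {
    "AGE": (39.0, 11.0),        # years
    "WT": (66.98, 14.69),       # kg
    "HT": (163.60, 8.99),       # cm
    "BSA": (1.72, 0.21),        # m^2
    "SCR": (0.77, 0.14),        # mg/dL
    "CRCL": (103.43, 22.63),    # mL/min/1.73 m^2
    "TCV": (339.93, 201.19),    # mL
}
TKV_SUMMARY = {"male": (822.18, 486.22), "female": (924.14, 404.27)}  # mL
P_FEMALE = 0.70
RACE_LEVELS = ("Caucasian", "AfroAmerican", "Other")
RACE_PROBS = (0.75, 0.05, 0.20)
#: NONMEM-style numeric codes
SEX_CODE = {"male": 0, "female": 1}
RACE_CODE = {lvl: i + 1 for i, lvl in enumerate(RACE_LEVELS)}


@dataclass
class TrialDesign:
    """Design of the virtual dose-escalation trial."""

    n_per_cohort: int = 5
    dose_levels: tuple = (50.0, 100.0, 200.0, 400.0)
    infusion_duration: float = 0.5
    sampling_times: tuple = DEFAULT_SAMPLING_TIMES
    lloq: float = 7.8e-6          # mg/L (7.8 ng/mL)
    covariate_sd_scale: float = 1.0  # 0 collapses covariates to their means

    def __post_init__(self):
        st = np.asarray(self.sampling_times, dtype=float)
        if np.any(np.diff(st) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if any(d <= 0 for d in self.dose_levels):
            raise ValueError("doses must be positive")
        if self.n_per_cohort < 1:
            raise ValueError("n_per_cohort must be >= 1")

    @property
    def n_subjects(self) -> int:
        return self.n_per_cohort * len(self.dose_levels)


@dataclass
class SubjectRecord:
    """One virtual subject: dosing, covariates and observations."""

    id: int
    dose: float                       # mg, single infusion at t=0
    infusion_duration: float
    covariates: dict
    times: np.ndarray                 # h, post-dose observation times
    conc: np.ndarray                  # mg/L, observed total concentration
    below_lloq: np.ndarray = None     # bool per observation
    eta: np.ndarray = None            # generating random effects, if known
    params: ModelParameters = None    # generating individual params, if known

    @property
    def dose_event(self) -> DoseEvent:
        return DoseEvent(amount=self.dose, duration=self.infusion_duration)


@dataclass
class TrialDataset:
    """Collection of subjects forming one analysis dataset."""

    subjects: list
    design: TrialDesign = None
    seed: int = None
    params: ModelParameters = None    # generating population params, if known

    def __len__(self):
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.times) for s in self.subjects)

    def to_frame(self) -> pd.DataFrame:
        """NONMEM-style long format (dosing rows EVID=1, observations EVID=0)."""
        rows = []
        for s in self.subjects:
            cov = s.covariates
            base = {k: cov.get(k, np.nan) for k in
                    ("AGE", "WT", "HT", "BSA", "SCR", "CRCL", "TKV", "TCV")}
            base["SEX"] = SEX_CODE.get(cov.get("SEX"), cov.get("SEX", np.nan))
            base["RACE"] = RACE_CODE.get(cov.get("RACE"), cov.get("RACE", np.nan))
            rate = s.dose / s.infusion_duration
            # pre-dose sample: missing-DV observation record
            rows.append({"ID": s.id, "TIME": 0.0, "AMT": 0.0, "RATE": 0.0,
                         "DV": 0.0, "MDV": 1, "EVID": 0, "DOSE": s.dose, **base})
            rows.append({"ID": s.id, "TIME": 0.0, "AMT": s.dose, "RATE": rate,
                         "DV": 0.0, "MDV": 1, "EVID": 1, "DOSE": s.dose, **base})
            lloq_flags = (s.below_lloq if s.below_lloq is not None
                          else np.zeros(len(s.times), dtype=bool))
            for t, y, bql in zip(s.times, s.conc, lloq_flags):
                rows.append({"ID": s.id, "TIME": t, "AMT": 0.0, "RATE": 0.0,
                             "DV": y, "MDV": int(bool(bql)), "EVID": 0,
                             "DOSE": s.dose, **base})
        cols = ["ID", "TIME", "AMT", "RATE", "DV", "MDV", "EVID", "DOSE",
                "AGE", "WT", "HT", "BSA", "SCR", "CRCL", "TKV", "TCV", "SEX", "RACE"]
        return pd.DataFrame(rows)[cols]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, design: TrialDesign | None = None,
                   seed: int | None = None) -> "TrialDataset":
        required = {"ID", "TIME", "AMT", "RATE", "DV", "MDV", "EVID"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dataset is missing required columns: {sorted(missing)}")
        inv_sex = {v: k for k, v in SEX_CODE.items()}
        inv_race = {v: k for k, v in RACE_CODE.items()}
        subjects = []
        for sid, grp in df.groupby("ID", sort=True):
            times_all = grp["TIME"].to_numpy(dtype=float)
            if np.any(np.diff(times_all) < 0):
                raise ValueError(f"subject {sid}: times are not monotone")
            doserows = grp[grp["EVID"] == 1]
            if len(doserows) != 1:
                raise ValueError(f"subject {sid}: expected exactly one dosing row")
            amt = float(doserows["AMT"].iloc[0])
            rate = float(doserows["RATE"].iloc[0])
            if amt <= 0 or rate <= 0:
                raise ValueError(f"subject {sid}: invalid dose amount/rate")
            obs = grp[(grp["EVID"] == 0) & (grp["MDV"] == 0)]
            dv = obs["DV"].to_numpy(dtype=float)
            if np.any(dv < 0):
                raise ValueError(f"subject {sid}: negative DV")
            cov = {}
            for k in ("AGE", "WT", "HT", "BSA", "SCR", "CRCL", "TKV", "TCV"):
                if k in grp.columns:
                    cov[k] = float(grp[k].iloc[0])
            if "SEX" in grp.columns:
                cov["SEX"] = inv_sex.get(int(grp["SEX"].iloc[0]), grp["SEX"].iloc[0])
            if "RACE" in grp.columns:
                cov["RACE"] = inv_race.get(int(grp["RACE"].iloc[0]), grp["RACE"].iloc[0])
            subjects.append(SubjectRecord(
                id=int(sid), dose=amt, infusion_duration=amt / rate,
                covariates=cov, times=obs["TIME"].to_numpy(dtype=float), conc=dv))
        return cls(subjects=subjects, design=design, seed=seed)

    def covariate_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {"ID": s.id, "DOSE": s.dose, **s.covariates}
            rows.append(row)
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------

def _lognormal_from_moments(rng, mean, sd, size=None):
    """Log-normal draws with the requested arithmetic mean and SD."""
    if sd == 0:
        return np.full(size if size is not None else (), mean, dtype=float)
    s2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - 0.5 * s2
    return rng.lognormal(mu, math.sqrt(s2), size)


def sample_individual(p: ModelParameters, rng) -> ModelParameters:
    """Realize one subject's parameters under the exponential IIV model."""
    ind, _eta = _sample_individual_eta(p, rng)
    return ind


def _sample_individual_eta(p: ModelParameters, rng):
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    eta = np.array([
        rng.normal(0.0, p.omega_Rtotp) if p.omega_Rtotp > 0 else 0.0,
        rng.normal(0.0, p.omega_kout) if p.omega_kout > 0 else 0.0,
    ])
    ind = p.replace(Rtotp=p.Rtotp * math.exp(eta[0]),
                    kout=p.kout * math.exp(eta[1]))
    return ind, eta


def sample_covariates(design: TrialDesign, rng, n: int | None = None) -> pd.DataFrame:
    """Draw a covariate table for ``n`` subjects (defaults to the design size)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if n is None:
        n = design.n_subjects
    sc = design.covariate_sd_scale
    sex = np.where(rng.random(n) < P_FEMALE, "female", "male")
    race = rng.choice(RACE_LEVELS, size=n, p=RACE_PROBS)
    out = {"SEX": sex, "RACE": race}
    for name, (mean, sd) in COVARIATE_SUMMARY.items():
        out[name] = _lognormal_from_moments(rng, mean, sd * sc, n)
    tkv = np.empty(n)
    for i in range(n):
        mean, sd = TKV_SUMMARY[sex[i]]
        tkv[i] = _lognormal_from_moments(rng, mean, sd * sc)
    out["TKV"] = tkv
    return pd.DataFrame(out)


@dataclass(frozen=True)
class CovariateEffect:
    """A known parameter-covariate relationship for data generation.

    ``power``: P_i = P * (cov_i / ref) ** coefficient  (continuous covariates)
    ``fractional``: P_i = P * (1 + coefficient * indicator)  (categorical)
    """

    parameter: str
    covariate: str
    coefficient: float
    reference: float = 1.0
    kind: str = "power"

    def multiplier(self, cov_value) -> float:
        if self.kind == "power":
            return (float(cov_value) / self.reference) ** self.coefficient
        if self.kind == "fractional":
            return 1.0 + self.coefficient * float(cov_value)
        raise ValueError(f"unknown covariate effect kind {self.kind!r}")


def _apply_covariate_effects(p: ModelParameters, cov: Mapping,
                             effects: Sequence[CovariateEffect]) -> ModelParameters:
    changes = {}
    for eff in effects:
        value = cov[eff.covariate]
        if eff.covariate == "SEX" and isinstance(value, str):
            value = SEX_CODE[value]
        current = changes.get(eff.parameter, getattr(p, eff.parameter))
        changes[eff.parameter] = current * eff.multiplier(value)
    return p.replace(**changes) if changes else p


def generate_trial(
    p: ModelParameters,
    design: TrialDesign | None = None,
    seed: int = DEFAULT_MASTER_SEED,
    covariate_effects: Sequence[CovariateEffect] = (),
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> TrialDataset:
    """Generate one virtual trial dataset.

    Per subject: draw covariates and random effects, apply any injected
    covariate effects to the typical values, simulate the individual profile,
    evaluate the total concentration at the nominal sampling times and apply
    the log-scale additive residual: ``y = exp(log(Cpred) + eps)``,
    ``eps ~ N(0, sigma_log^2)``.  The pre-dose sample is recorded as a
    missing-DV row in the exported dataset.
    """
    if design is None:
        design = TrialDesign()
    rng = np.random.default_rng(seed)
    cov_table = sample_covariates(design, rng)
    t_obs = np.asarray(design.sampling_times, dtype=float)

    subjects = []
    sid = 0
    for dose in design.dose_levels:
        for _ in range(design.n_per_cohort):
            cov = cov_table.iloc[sid].to_dict()
            sid += 1
            typ = _apply_covariate_effects(p, cov, covariate_effects)
            ind, eta = _sample_individual_eta(typ, rng)
            v1 = ind.v1_for_dose(dose)
            th = ind.structural_array(v1=v1)
            bounds = np.array([0.0, design.infusion_duration, float(t_obs[-1])])
            rates = np.array([dose / design.infusion_duration, 0.0])
            log_pred, ok = _ode.predict_log_total(th, bounds, rates, t_obs, rtol, atol)
            if not ok:
                raise IntegrationError(
                    f"subject {sid} (dose {dose} mg): integration failed with "
                    f"individual parameters {ind.to_dict()}")
            eps = (rng.normal(0.0, p.sigma_log, len(t_obs))
                   if p.sigma_log > 0 else np.zeros(len(t_obs)))
            y = np.exp(log_pred + eps)
            subjects.append(SubjectRecord(
                id=sid, dose=float(dose),
                infusion_duration=design.infusion_duration,
                covariates=cov, times=t_obs.copy(), conc=y,
                below_lloq=y < design.lloq, eta=eta, params=ind))
    return TrialDataset(subjects=subjects, design=design, seed=seed, params=p)
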