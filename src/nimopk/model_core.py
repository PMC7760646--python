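"""Structural model: two-compartment QSS TMDD with a clearance-stimulating mediator.

Nimotuzumab (an anti-EGFR IgG1, 150 kDa) shows nonlinear disposition driven by
binding to EGFR in both the central and a peripheral (cyst) compartment.  Under
the quasi-steady-state (QSS) approximation with constant total target, binding
kinetics collapse into a single constant ``Kss = (koff + kint) / kon`` and the
free drug amounts obey a three-state ODE system:

* ``A1`` — free drug amount in the central compartment (mg),
* ``A2`` — free drug amount in the peripheral compartment (mg),
* ``A3`` — a dimensionless turnover mediator whose synthesis is stimulated by
  the free central concentration through a sigmoid (``Smax``, ``S50``,
  ``gamma``) and which multiplies the non-specific clearance ``CL``.

Each disposition equation carries the QSS correction factor
``1 + Rtot * Kss / (Kss + C)**2`` (>= 1), the Jacobian of total with respect to
free concentration, which accounts for drug buffered in the drug-target
complex.  The observable is the *total* central concentration: free plus
complex, ``C + Rtot * C / (Kss + C)``.

Units are fixed package-wide: mg, L, h; time zero is the start of infusion.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "ModelParameters",
    "StateVector",
    "BindingKinetics",
    "TYPICAL_PARAMETERS",
    "rhs",
    "total_concentration",
    "steady_state_volume",
    "dissociation_constant",
    "molar_to_mass",
]


# --------------------------------------------------------------------------
# parameterization
# --------------------------------------------------------------------------

# Order of the structural parameters inside the packed float64 vector used by
# the compiled kernels (see _ode.py).  Keep in sync with _ode.py.
STRUCTURAL_ORDER = (
    "CL", "V1", "V2", "Q", "Kss", "kint",
    "Rtot", "Rtotp", "kout", "Smax", "S50", "gamma",
)


@dataclass
class ModelParameters:
    """Population parameters of the QSS TMDD + mediator model.

    Defaults are the final population estimates for nimotuzumab in ADPKD
    (typical values; inter-individual variability on ``Rtotp`` and ``kout``;
    additive residual error on log concentration).

    Parameters
    ----------
    CL : float
        Non-specific (linear) clearance, L/h.  Multiplied by the mediator.
    V1, V2 : float
        Central / peripheral volumes of distribution, L.
    Q : float
        Inter-compartmental clearance, L/h.
    Kss : float
        QSS constant ``(koff + kint)/kon``, mg/L.
    kint : float
        First-order internalization rate of the drug-target complex, 1/h.
    Rtot, Rtotp : float
        Total target concentration in the central / peripheral compartment,
        mg/L (held constant; target turnover is not modelled explicitly).
    kout : float
        First-order degradation rate of the mediator, 1/h.  The zero-order
        synthesis rate is structurally tied to it: ``kin = kout * A3(0)``
        with ``A3(0) = 1``, so the mediator starts at steady state.
    Smax : float
        Maximal fractional stimulation of mediator synthesis (dimensionless).
    S50 : float
        Free central concentration at half-maximal stimulation, mg/L.
    gamma : float
        Hill coefficient of the stimulation sigmoid (dimensionless).
    v1_dose50_change : float
        Signed fractional change of ``V1`` applied to the 50-mg cohort:
        ``V1_50 = V1 * (1 + v1_dose50_change)``.  The reported magnitude is
        53%; the sign is not stated, so both directions are supported.  The
        default is the decrease (−0.53), the direction consistent with the
        faster early elimination observed in the 50-mg arm.
    omega_Rtotp, omega_kout : float
        SDs of the log-normal inter-individual random effects (log scale).
    sigma_log : float
        SD of the additive residual error on natural-log concentration.
    """

    CL: float = 9.64e-3
    V1: float = 2.63
    V2: float = 9.92e-3
    Q: float = 2.88e-2
    Kss: float = 15.5
    kint: float = 4.94e-3
    Rtot: float = 1.05e-2
    Rtotp: float = 956.0
    kout: float = 1.33e-2
    Smax: float = 3.18
    S50: float = 8.57
    gamma: float = 1.0
    v1_dose50_change: float = -0.53
    omega_Rtotp: float = 1.35
    omega_kout: float = 1.97
    sigma_log: float = 0.48

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        positive = ("CL", "V1", "V2", "Q", "Kss", "kint", "kout", "S50", "gamma")
        for name in positive:
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        for name in ("Rtot", "Rtotp", "Smax", "omega_Rtotp", "omega_kout", "sigma_log"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not math.isfinite(self.v1_dose50_change) or self.v1_dose50_change <= -1:
            raise ValueError("v1_dose50_change must be > -1 and finite")

    # -- derived -----------------------------------------------------------
    @property
    def kin(self) -> float:
        """Zero-order mediator synthesis rate; structurally ``kout * A3(0)``."""
        return self.kout

    def v1_for_dose(self, dose_mg: float, apply_change: bool = True) -> float:
        """Central volume for a given dose; the 50-mg arm gets the V1 shift."""
        if apply_change and dose_mg == 50.0:
            return self.V1 * (1.0 + self.v1_dose50_change)
        return self.V1

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def structural_array(self, v1: float | None = None) -> np.ndarray:
        """Pack the structural parameters in STRUCTURAL_ORDER (float64)."""
        vals = [getattr(self, k) for k in STRUCTURAL_ORDER]
        out = np.array(vals, dtype=np.float64)
        if v1 is not None:
            out[1] = v1
        return out

    # -- flat key-value serialization -------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_file(cls, path) -> "ModelParameters":
        """Read a flat YAML/JSON key-value parameter file."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ValueError(f"{path}: expected a flat key-value mapping")
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


#: Final typical parameter estimates (the package-wide reference set).
TYPICAL_PARAMETERS = ModelParameters()


@dataclass(frozen=True)
class StateVector:
    """System state: free central/peripheral amounts (mg) and mediator level."""

    A1: float
    A2: float
    A3: float

    def __post_init__(self):
        if not all(math.isfinite(v) for v in (self.A1, self.A2, self.A3)):
            raise ValueError("state must be finite")
        if self.A1 < 0 or self.A2 < 0:
            raise ValueError("free drug amounts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.A1, self.A2, self.A3], dtype=np.float64)


@dataclass(frozen=True)
class BindingKinetics:
    """In-vitro binding constants (surface plasmon resonance scale).

    Used only for derived-quantity checks (``Kd = koff/kon`` and molar/mass
    unit arithmetic), never inside the ODEs, where binding is collapsed into
    ``Kss``.
    """

    kon: float = 5.2e4     # 1/(s * mol/L)
    koff: float = 1.1e-3   # 1/s
    molecular_weight: float = 150_000.0  # g/mol

    def __post_init__(self):
        for name in ("kon", "koff", "molecular_weight"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")


# --------------------------------------------------------------------------
# model equations
# --------------------------------------------------------------------------

def rhs(t: float, state, p: ModelParameters, infusion_rate: float = 0.0,
        v1: float | None = None) -> np.ndarray:
    """Right-hand side of the QSS TMDD + mediator ODE system.

    Parameters
    ----------
    t : float
        Time, h (the system is autonomous; kept for solver signatures).
    state : StateVector or array-like (A1, A2, A3)
    p : ModelParameters
    infusion_rate : float
        Zero-order drug input into the central compartment, mg/h.
    v1 : float, optional
        Override of the central volume (dose-specific V1); defaults to p.V1.

    Returns
    -------
    ndarray, shape (3,) -- (dA1/dt, dA2/dt, dA3/dt) in (mg/h, mg/h, 1/h).
    """
    if isinstance(state, StateVector):
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
    if y.shape != (3,) or not np.all(np.isfinite(y)):
        raise ValueError("state must be three finite components (A1, A2, A3)")
    if not math.isfinite(infusion_rate) or infusion_rate < 0:
        raise ValueError("infusion_rate must be finite and >= 0")
    p.validate()

    V1 = p.V1 if v1 is None else v1
    A1, A2, A3 = y
    C1 = A1 / V1
    C2 = A2 / p.V2

    # QSS correction factors (Jacobian of total wrt free concentration); >= 1.
    denom1 = 1.0 + p.Rtot * p.Kss / (p.Kss + C1) ** 2
    denom2 = 1.0 + p.Rtotp * p.Kss / (p.Kss + C2) ** 2

    dA1 = (
        infusion_rate
        - (p.CL * A3 / V1 + p.Q / V1) * A1
        + (p.Q / p.V2) * A2
        - p.kint * p.Rtot * A1 / (p.Kss + C1)
    ) / denom1
    dA2 = ((p.Q / V1) * A1 - (p.Q / p.V2) * A2) / denom2

    if p.Smax == 0.0 or C1 == 0.0:
        stim = 0.0
    else:
        cg = C1 ** p.gamma
        stim = p.Smax * cg / (p.S50 ** p.gamma + cg)
    dA3 = p.kin * (1.0 + stim) - p.kout * A3

    return np.array([dA1, dA2, dA3])


def total_concentration(A1, p: ModelParameters, v1: float | None = None):
    """Observable: total (free + target-bound) central concentration, mg/L.

    ``Ctot = C + Rtot * C / (Kss + C)`` with ``C = A1 / V1``.  Scalar or
    array ``A1`` accepted.
    """
    A1 = np.asarray(A1, dtype=float)
    if np.any(A1 < 0) or not np.all(np.isfinite(A1)):
        raise ValueError("A1 must be finite and >= 0")
    V1 = p.V1 if v1 is None else v1
    C = A1 / V1
    out = C + p.Rtot * C / (p.Kss + C)
    return float(out) if out.ndim == 0 else out


def steady_state_volume(p: ModelParameters) -> float:
    """Total distribution volume at steady state, ``Vss = V1 + V2`` (L)."""
    p.validate()
    return p.V1 + p.V2


def dissociation_constant(b: BindingKinetics) -> float:
    """Equilibrium dissociation constant ``Kd = koff / kon`` (mol/L)."""
    return b.koff / b.kon


def molar_to_mass(conc: float, molecular_weight: float) -> float:
    """Convert a molar concentration (mol/L) to mg/L for a given MW (g/mol)."""
    if conc < 0 or not math.isfinite(conc):
        raise ValueError("concentration must be finite and >= 0")
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be > 0")
    return conc * molecular_weight * 1000.0
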