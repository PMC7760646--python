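"""Shared fixtures and independent oracles.

The linear-limit oracle solves the two-compartment infusion system exactly
via the matrix exponential (scipy.linalg.expm) — a route fully independent of
the package's Runge-Kutta/LSODA integration paths.
"""

import numpy as np
import pytest
from scipy.linalg import expm

from nimopk import ModelParameters


@pytest.fixture(scope="session")
def typical():
    """Reference (typical) population parameters."""
    return ModelParameters()


@pytest.fixture(scope="session")
def linear_params():
    """Degenerate configuration: no target binding, inert mediator.

    The system then reduces exactly to a linear two-compartment model with
    clearance CL, volumes V1/V2 and inter-compartmental clearance Q.
    """
    return ModelParameters(Rtot=0.0, Rtotp=0.0, Smax=0.0)


def linear_infusion_conc(p: ModelParameters, dose: float, duration: float,
                         times, v1: float | None = None) -> np.ndarray:
    """Exact free central concentration for the linear two-compartment model.

    Piecewise-constant input handled with the matrix exponential:
    y(t) = e^{Mt} y0 + M^{-1} (e^{Mt} - I) b.
    """
    V1 = p.V1 if v1 is None else v1
    M = np.array([
        [-(p.CL + p.Q) / V1, p.Q / p.V2],
        [p.Q / V1, -p.Q / p.V2],
    ])
    Minv = np.linalg.inv(M)

    def advance(y, b, dt):
        E = expm(M * dt)
        return E @ y + Minv @ (E - np.eye(2)) @ b

    rate = dose / duration
    times = np.asarray(times, dtype=float)
    out = np.empty(len(times))
    for i, t in enumerate(times):
        y = np.zeros(2)
        if t <= duration:
            y = advance(y, np.array([rate, 0.0]), t)
        else:
            y = advance(y, np.array([rate, 0.0]), duration)
            y = advance(y, np.zeros(2), t - duration)
        out[i] = y[0] / V1
    return out
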