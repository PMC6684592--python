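"""Generalized Lotka-Volterra rate models for the EEI and III architectures.

Both vector fields have the canonical GLV form

    dx_i/dt = k * x_i * (A @ x + c)_i

with a scenario-specific interaction matrix ``A`` and drive vector ``c``.
The EEI field couples two excitatory rates (x1, x2) to one inhibitory
rate (y); the III field is a cyclic May-Leonard competition between
three inhibitory rates.  Coordinate axes and planes are invariant, so
non-negative initial conditions yield non-negative trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "GLVParams",
    "RateState",
    "Trajectory",
    "eei_field",
    "iii_field",
    "glv_field",
    "linear_forms",
    "integrate",
]

#: tolerance below which the field norm counts as "settled"
CONVERGENCE_TOL = 1e-8


@dataclass(frozen=True)
class GLVParams:
    """Parameter bundle for one GLV scenario.

    Parameters
    ----------
    scenario:
        ``"EEI"`` or ``"III"``.
    a, b:
        Dimensionless coupling scale factors (the bifurcation parameters).
    g:
        IPSP/EPSP amplitude ratio (EEI only; default 6).
    p:
        Connection-probability multiplier for synapses touching the
        inhibitory population (EEI only; default 3).
    w:
        Relative strength of within-subnetwork excitatory couplings
        (EEI only; default 2).
    I:
        External drive, in model rate units (default 1).
    k:
        Overall time-scale factor (default 1); absorbs neuron and
        network constants that do not appear explicitly in the field.
    """

    scenario: str
    a: float
    b: float
    g: float = 6.0
    p: float = 3.0
    w: float = 2.0
    I: float = 1.0
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.scenario not in ("EEI", "III"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for name in ("a", "b", "g", "p", "w", "I", "k"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {name} must be finite, got {v}")
        if self.a < 0 or self.b < 0:
            raise ValueError("coupling scales a, b must be non-negative")
        if self.I <= 0:
            raise ValueError("external drive I must be positive")
        if self.k <= 0:
            raise ValueError("time-scale factor k must be positive")


# RateState is a plain length-3 float array-like: (x1, x2, y) for EEI,
# (x1, x2, x3) for III.
RateState = np.ndarray


def linear_forms(params: GLVParams) -> tuple[np.ndarray, np.ndarray]:
    """Interaction matrix ``A`` and drive vector ``c`` of the GLV field.

    The field is ``k * x * (A @ x + c)`` componentwise.  The factor 2 on
    the excitatory rows of the EEI matrix reflects the 2:1 size ratio of
    the excitatory to the inhibitory population.
    """
    a, b, g, p, w, I = params.a, params.b, params.g, params.p, params.w, params.I
    if params.scenario == "EEI":
        A = np.array(
            [
                [2 * w, 2.0, -2 * p * g * b],
                [2.0, 2 * w, -2 * p * g * a],
                [b * p, a * p, -p * g],
            ]
        )
        c = np.array([2 * I, 2 * I, I])
    else:
        A = -np.array(
            [
                [1.0, a, b],
                [b, 1.0, a],
                [a, b, 1.0],
            ]
        )
        c = np.array([I, I, I])
    return A, c


def _check_state(state) -> np.ndarray:
    x = np.asarray(state, dtype=float)
    if x.shape != (3,):
        raise ValueError(f"state must have exactly 3 components, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite state components: {x}")
    return x


def eei_field(state: RateState, params: GLVParams) -> np.ndarray:
    """Time derivative (dx1, dx2, dy) of the EEI rate model."""
    if params.scenario != "EEI":
        raise ValueError("eei_field requires an EEI parameter bundle")
    x = _check_state(state)
    A, c = linear_forms(params)
    return params.k * x * (A @ x + c)


def iii_field(state: RateState, params: GLVParams) -> np.ndarray:
    """Time derivative (dx1, dx2, dx3) of the III (May-Leonard) rate model.

    The interaction matrix is circulant, so simultaneously rotating the
    state components (1 -> 2 -> 3 -> 1) rotates the output identically.
    """
    if params.scenario != "III":
        raise ValueError("iii_field requires an III parameter bundle")
    x = _check_state(state)
    A, c = linear_forms(params)
    return params.k * x * (A @ x + c)


def glv_field(state: RateState, params: GLVParams) -> np.ndarray:
    """Dispatch to the field selected by ``params.scenario``."""
    return eei_field(state, params) if params.scenario == "EEI" else iii_field(state, params)


@dataclass
class Trajectory:
    """Solution of a GLV initial-value problem on a uniform output grid."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 3)
    params: GLVParams
    initial_state: np.ndarray
    success: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, 3):
            raise ValueError("states must be (len(times), 3)")

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def converged(self, tol: float = CONVERGENCE_TOL) -> bool:
        """True if the field norm stays below ``tol`` over the final 1%.

        Attractor identity, not settling time, is the quantity of
        interest, so "converged" simply means the trajectory has stopped
        moving at the end of the horizon.
        """
        n_tail = max(2, int(0.01 * self.times.size))
        tail = self.states[-n_tail:]
        return all(np.linalg.norm(glv_field(s, self.params)) < tol for s in tail)

    def to_text(self, path) -> None:
        """Write t, x1, x2, x3/y as whitespace-delimited columns."""
        header = "t x1 x2 " + ("y" if self.params.scenario == "EEI" else "x3")
        np.savetxt(path, np.column_stack([self.times, self.states]), header=header)


def integrate(
    params: GLVParams,
    initial: RateState,
    duration: float,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    n_points: int = 2001,
    floor: float | None = None,
) -> Trajectory:
    """Integrate the GLV field with an adaptive explicit Runge-Kutta scheme.

    Parameters
    ----------
    floor:
        Optional non-negativity floor applied to the state after each
        output step.  Off by default: near a heteroclinic cycle the
        components legitimately approach machine zero, and clamping
        would mimic finite-size noise and alter the period growth.
    """
    x0 = _check_state(initial)
    if np.any(x0 < 0):
        raise ValueError("initial state must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")

    A, c = linear_forms(params)
    k = params.k

    def rhs(t, x):
        return k * x * (A @ x + c)

    t_eval = np.linspace(0.0, duration, n_points)
    sol = solve_ivp(rhs, (0.0, duration), x0, method="RK45", rtol=rtol, atol=atol, t_eval=t_eval)
    states = sol.y.T
    if floor is not None:
        states = np.maximum(states, floor)
    return Trajectory(
        times=sol.t,
        states=states,
        params=params,
        initial_state=x0,
        success=sol.success,
        message=sol.message if not sol.success else "",
    )
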