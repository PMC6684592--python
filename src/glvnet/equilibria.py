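"""On/off equilibria of the GLV fields and their linear stability.

A three-dimensional GLV system has up to 2^3 = 8 equilibrium candidates:
each component is either exactly zero ("off") or solves the linear
system obtained by setting its bracket to zero ("on").  Patterns are
written p_{b1,b2,b3}, e.g. p011 has x1 = 0 and x2, x3 active.  The
active subsystem is linear in the active components, so coordinates are
obtained by a direct linear solve; no root-finding is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .glv_core import GLVParams, linear_forms

__all__ = [
    "PATTERNS",
    "Stability",
    "Equilibrium",
    "equilibrium_at",
    "enumerate_equilibria",
    "jacobian",
    "eigenvalues_at",
    "classify_stability",
]

#: all 8 on/off patterns, ordered as binary triples (p000 ... p111)
PATTERNS: tuple[tuple[int, int, int], ...] = tuple(
    (i >> 2 & 1, i >> 1 & 1, i & 1) for i in range(8)
)

#: hyperbolicity tolerance on eigenvalue real parts; separates genuine
#: bifurcation loci from roundoff
HYPERBOLICITY_TOL = 1e-9

#: relative singularity threshold for the active linear subsystem
_SINGULAR_RCOND = 1e-12


class Stability(str, Enum):
    STABLE = "stable"
    SADDLE_1U = "saddle_1u"
    SADDLE_2U = "saddle_2u"
    UNSTABLE = "unstable"
    NONHYPERBOLIC = "nonhyperbolic"


@dataclass(frozen=True)
class Equilibrium:
    pattern: tuple[int, int, int]
    coords: np.ndarray | None
    eigenvalues: np.ndarray | None
    stability: Stability | None
    positive_octant: bool
    exists: bool

    @property
    def name(self) -> str:
        return "p" + "".join(str(b) for b in self.pattern)


def pattern_name(pattern: tuple[int, int, int]) -> str:
    return "p" + "".join(str(b) for b in pattern)


def equilibrium_coords(pattern, params: GLVParams) -> np.ndarray | None:
    """Coordinates of the equilibrium with the given on/off pattern.

    Off components are exactly zero; active components solve
    ``A[S, S] @ x_S = -c[S]``.  Returns None when that subsystem is
    singular (the fixed point escapes to infinity at such parameters).
    """
    active = [i for i, b in enumerate(pattern) if b]
    x = np.zeros(3)
    if not active:
        return x
    A, c = linear_forms(params)
    sub = A[np.ix_(active, active)]
    # guard against singular/near-singular active subsystems
    if np.linalg.cond(sub) > 1.0 / _SINGULAR_RCOND:
        return None
    x[active] = np.linalg.solve(sub, -c[active])
    return x


def jacobian(state, params: GLVParams) -> np.ndarray:
    """Analytic Jacobian of the GLV field at an arbitrary state.

    With field f_i = k x_i (A x + c)_i the Jacobian is
    ``k * (diag(A x + c) + diag(x) @ A)``.
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (3,) or not np.all(np.isfinite(x)):
        raise ValueError(f"state must be a finite triple, got {state}")
    A, c = linear_forms(params)
    return params.k * (np.diag(A @ x + c) + np.diag(x) @ A)


def classify_stability(eigenvalues, tol: float = HYPERBOLICITY_TOL) -> Stability:
    """Stability label from signs of eigenvalue real parts only."""
    re = np.real(np.asarray(eigenvalues, dtype=complex))
    if re.shape != (3,) or not np.all(np.isfinite(re)):
        raise ValueError("need three finite eigenvalues")
    if np.any(np.abs(re) < tol):
        return Stability.NONHYPERBOLIC
    n_unstable = int(np.sum(re > 0))
    return {
        0: Stability.STABLE,
        1: Stability.SADDLE_1U,
        2: Stability.SADDLE_2U,
        3: Stability.UNSTABLE,
    }[n_unstable]


def equilibrium_at(pattern, params: GLVParams) -> Equilibrium:
    """Full Equilibrium record (coords, eigenvalues, stability) for one pattern."""
    pattern = tuple(int(b) for b in pattern)
    coords = equilibrium_coords(pattern, params)
    if coords is None:
        return Equilibrium(
            pattern=pattern,
            coords=None,
            eigenvalues=None,
            stability=None,
            positive_octant=False,
            exists=False,
        )
    eig = np.linalg.eigvals(jacobian(coords, params))
    # sort by real part for reproducible output
    eig = eig[np.argsort(eig.real)]
    return Equilibrium(
        pattern=pattern,
        coords=coords,
        eigenvalues=eig,
        stability=classify_stability(eig),
        positive_octant=bool(np.all(coords >= 0)),
        exists=True,
    )


def enumerate_equilibria(params: GLVParams) -> list[Equilibrium]:
    """All 8 on/off equilibrium candidates of the chosen scenario."""
    return [equilibrium_at(p, params) for p in PATTERNS]


def eigenvalues_at(pattern, params: GLVParams) -> np.ndarray:
    """Jacobian eigenvalues at the equilibrium with the given pattern."""
    eq = equilibrium_at(pattern, params)
    if not eq.exists:
        raise ValueError(
            f"equilibrium {pattern_name(tuple(pattern))} is singular at these parameters"
        )
    return eq.eigenvalues


def report(equilibria: list[Equilibrium]) -> str:
    """Plain-text table of an equilibrium list."""
    lines = [f"{'pattern':8} {'coords':36} {'stability':14} {'octant':6} eigenvalues"]
    for eq in equilibria:
        if not eq.exists:
            lines.append(f"{eq.name:8} {'<singular>':36} {'-':14} {'-':6} -")
            continue
        coords = " ".join(f"{v: .6f}" for v in eq.coords)
        eigs = " ".join(f"{v.real: .4f}{v.imag:+.4f}j" for v in eq.eigenvalues)
        octant = "+" if eq.positive_octant else "-"
        lines.append(f"{eq.name:8} {coords:36} {eq.stability.value:14} {octant:6} {eigs}")
    return "\n".join(lines)
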