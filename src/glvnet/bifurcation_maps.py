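"""Bifurcation curves and regime maps over the (a, b) coupling plane.

For the EEI scenario the parameter plane splits into six regions,
determined by which of the positive-octant equilibria p001, p011, p101
are stable and by the unstable dimension of p001.  Transcritical lines
follow from zeros of single real eigenvalues; a degenerate Hopf line
follows from the zero crossing of a complex-conjugate pair.  For the
III (May-Leonard) scenario the regime map depends on (a, b) through
closed conditions: coexistence for a+b < 2, winner-take-all for
a, b > 1 with a+b > 2, and oscillations (heteroclinic slowing-down)
otherwise, with a structurally unstable limit cycle exactly on a+b = 2.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from enum import Enum
from functools import lru_cache

import numpy as np
import sympy as sp
from scipy.optimize import brentq

from .equilibria import Stability, equilibrium_at
from .glv_core import GLVParams

__all__ = [
    "RegionLabelEEI",
    "IIIRegime",
    "DiagramGrid",
    "transcritical_curve",
    "axis_bifurcation_values",
    "hopf_locus_p111",
    "eei_region",
    "iii_regime",
    "analytic_diagram",
]

#: the EEI region of interest starts above the degenerate Hopf line
REGION_OF_INTEREST_MIN = 6.0 / 7.0
#: half-width of the "boundary" band around region edges in (a, b)
BOUNDARY_TOL = 1e-3
#: tolerance for analytic regime conditions (III)
ANALYTIC_TOL = 1e-12


class RegionLabelEEI(str, Enum):
    R1 = "R1"
    R2 = "R2"
    R3 = "R3"
    R4 = "R4"
    R5 = "R5"
    R6 = "R6"
    BOUNDARY = "boundary"


class IIIRegime(str, Enum):
    COEXISTENCE = "coexistence"
    WINNER_TAKE_ALL = "winner_take_all"
    OSCILLATORY = "oscillatory"
    BOUNDARY_LIMIT_CYCLE = "boundary_limit_cycle"


def transcritical_curve(a: float, which: str = "p011") -> float:
    """Transcritical bifurcation curve b(a) from the transverse eigenvalue.

    For p011 the single eigenvalue transverse to the x1 = 0 plane
    vanishes on b = (3a^2 - a - 1)/(3a - 2); the p101 branch is its
    a <-> b mirror (the same expression read as a(b)).
    """
    if which not in ("p011", "p101"):
        raise ValueError("which must be 'p011' or 'p101'")
    if abs(3 * a - 2) < 1e-12:
        raise ZeroDivisionError("transcritical curve has a pole at a = 2/3")
    return (3 * a**2 - a - 1) / (3 * a - 2)


@lru_cache(maxsize=8)
def _p011_block_symbols(g: float, p: float, w: float, I: float):
    """Symbolic trace and determinant of the in-plane 2x2 Jacobian block
    at p011, as functions of a (the pair does not involve b)."""
    a = sp.symbols("a", positive=True)
    A = sp.Matrix(
        [
            [2 * w, 2, -2 * p * g * sp.Symbol("b")],
            [2, 2 * w, -2 * p * g * a],
            [sp.Symbol("b") * p, a * p, -p * g],
        ]
    )
    c = sp.Matrix([2 * I, 2 * I, I])
    # active subsystem (x2, y): solve the bracketed linear forms
    sub = A[1:, 1:]
    rhs = -c[1:, :]
    sol = sub.solve(rhs)
    x2s, ys = sol[0], sol[1]
    # Jacobian block on the active components: diag(x) @ A restricted
    block = sp.diag(x2s, ys) * sub
    T = sp.simplify(sp.trace(block))
    D = sp.simplify(block.det())
    return a, T, D


def axis_bifurcation_values(params: GLVParams | None = None) -> dict:
    """Bifurcation values of a on the x1 = 0 axis branch (p011).

    The in-plane eigenvalue pair of the Jacobian at p011 is
    ``(T +- sqrt(T^2 - 4D)) / 2`` with T, D the trace and determinant of
    the active 2x2 block.  An eigenvalue of the pair vanishes exactly
    where D = 0 (transcritical candidates); the pair's common real part
    vanishes where T = 0 with negative discriminant (degenerate Hopf).
    Roots where the p011 coordinates themselves diverge are flagged
    singular rather than asserted to be bifurcations.
    """
    if params is None:
        params = GLVParams("EEI", a=1.0, b=1.0)
    if params.scenario != "EEI":
        raise ValueError("axis bifurcation values are defined for the EEI scenario")
    a, T, D = _p011_block_symbols(params.g, params.p, params.w, params.I)

    # The pair is (T +- sqrt(T^2 - 4D))/2 with T, D rational in a.  Setting
    # it to zero and clearing the square root and the denominators yields
    # the polynomial numer(D * denom(T)^2); its roots include the zeros of
    # the determinant and the poles where the fixed point itself diverges.
    cleared = sp.Poly(sp.numer(sp.together(D * sp.denom(sp.together(T)) ** 2)), a)
    transcritical = sorted(
        float(r) for r in cleared.real_roots() if r.is_real and r > 0
    )

    tr_poly = sp.Poly(sp.numer(sp.together(T)), a)
    hopf = []
    for r in tr_poly.real_roots():
        if not (r.is_real and r > 0):
            continue
        disc = (T**2 - 4 * D).subs(a, r)
        if sp.re(sp.nsimplify(disc, rational=False).evalf()) < 0:
            hopf.append(float(r))
    if len(hopf) != 1:
        raise RuntimeError(f"expected one degenerate Hopf value, found {hopf}")

    singular = [
        r
        for r in transcritical
        if equilibrium_at((0, 1, 1), dataclasses.replace(params, a=r)).exists is False
    ]
    return {
        "transcritical_roots": transcritical,
        "degenerate_hopf": hopf[0],
        "singular_roots": singular,
    }


def _complex_pair_real_part(a: float, b: float, params: GLVParams) -> float:
    """Real part of the complex-conjugate eigenvalue pair of Jac at p111.

    Returns NaN when p111 does not exist, lies outside the positive
    octant (only the physical branch belongs to the diagram), or has an
    all-real spectrum.
    """
    eq = equilibrium_at((1, 1, 1), dataclasses.replace(params, a=a, b=b))
    if not eq.exists or not eq.positive_octant:
        return np.nan
    im = np.abs(eq.eigenvalues.imag)
    pair = eq.eigenvalues[im > 1e-12]
    if pair.size != 2:
        return np.nan
    return float(pair.real.mean())


def hopf_locus_p111(a_grid, b_grid, params: GLVParams) -> np.ndarray:
    """Hopf locus of the interior equilibrium p111, by sign change + bisection.

    Scans each grid column in b for a sign change of the complex pair's
    real part and refines the crossing to |Re| < 1e-8.  Returns an
    (n, 2) array of (a, b) points; empty when no crossing is bracketed.
    """
    if params.scenario != "EEI":
        raise ValueError("the p111 Hopf locus is computed for the EEI scenario")
    points = []
    for a in np.asarray(a_grid, dtype=float):
        re = np.array([_complex_pair_real_part(a, b, params) for b in b_grid])
        for i in range(len(re) - 1):
            if np.isnan(re[i]) or np.isnan(re[i + 1]):
                continue
            if re[i] == 0.0:
                points.append((a, float(b_grid[i])))
            elif re[i] * re[i + 1] < 0:
                b_star = brentq(
                    lambda b: _complex_pair_real_part(a, b, params),
                    float(b_grid[i]),
                    float(b_grid[i + 1]),
                    xtol=1e-12,
                )
                if abs(_complex_pair_real_part(a, b_star, params)) < 1e-8:
                    points.append((a, float(b_star)))
    return np.array(points).reshape(-1, 2)


def eei_region(a: float, b: float, params: GLVParams | None = None) -> RegionLabelEEI:
    """Region label (R1..R6) of an EEI parameter point with a, b > 6/7.

    The label is derived from the stability pattern of the three
    positive-octant candidates: S = set of stable points among
    {p001, p011, p101}, and u = number of positive eigenvalues of p001.
    Region edges (nonhyperbolic eigenvalues, or points within 1e-3 of
    the degenerate Hopf line) are labelled "boundary".
    """
    if params is None:
        params = GLVParams("EEI", a=a, b=b)
    else:
        params = dataclasses.replace(params, a=a, b=b)
    roi = REGION_OF_INTEREST_MIN
    if a < roi - BOUNDARY_TOL or b < roi - BOUNDARY_TOL:
        raise ValueError(
            f"({a}, {b}) lies outside the region of interest a, b > {roi:.4f}; "
            "use enumerate_equilibria for a full stability report"
        )
    if a < roi + BOUNDARY_TOL or b < roi + BOUNDARY_TOL:
        return RegionLabelEEI.BOUNDARY

    eqs = {name: equilibrium_at(pat, params) for name, pat in
           (("p001", (0, 0, 1)), ("p011", (0, 1, 1)), ("p101", (1, 0, 1)))}
    if any(not eq.exists for eq in eqs.values()):
        return RegionLabelEEI.BOUNDARY
    if any(eq.stability == Stability.NONHYPERBOLIC for eq in eqs.values()):
        return RegionLabelEEI.BOUNDARY

    stable = frozenset(n for n, eq in eqs.items() if eq.stability == Stability.STABLE)
    u = int(np.sum(eqs["p001"].eigenvalues.real > 0))

    if stable == {"p001"}:
        return RegionLabelEEI.R1
    if stable == {"p011", "p101"}:
        return RegionLabelEEI.R5
    if stable == {"p011"}:
        return RegionLabelEEI.R2 if u == 1 else RegionLabelEEI.R6
    if stable == {"p101"}:
        return RegionLabelEEI.R3 if u == 1 else RegionLabelEEI.R4
    return RegionLabelEEI.BOUNDARY


def iii_regime(a: float, b: float) -> IIIRegime:
    """May-Leonard regime of the III scenario from (a, b) alone."""
    if a < 0 or b < 0:
        raise ValueError("a, b must be non-negative")
    s = a + b
    if abs(s - 2.0) < ANALYTIC_TOL:
        return IIIRegime.BOUNDARY_LIMIT_CYCLE
    if s < 2.0:
        return IIIRegime.COEXISTENCE
    if a > 1.0 + ANALYTIC_TOL and b > 1.0 + ANALYTIC_TOL:
        return IIIRegime.WINNER_TAKE_ALL
    return IIIRegime.OSCILLATORY


@dataclass
class DiagramGrid:
    """(a, b) lattice with one region/regime/state label per node."""

    a_values: np.ndarray
    b_values: np.ndarray
    labels: np.ndarray  # shape (len(a_values), len(b_values)), dtype str
    provenance: str  # analytic | glv_integration | spiking_simulation
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.a_values = np.asarray(self.a_values, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (self.a_values.size, self.b_values.size):
            raise ValueError("labels shape must be (len(a_values), len(b_values))")
        if np.any(np.diff(self.a_values) <= 0) or np.any(np.diff(self.b_values) <= 0):
            raise ValueError("grids must be strictly increasing")

    def write_csv(self, path) -> None:
        """CSV of (a, b, label) rows plus a JSON metadata sidecar."""
        with open(path, "w") as fh:
            fh.write("a,b,label\n")
            for i, a in enumerate(self.a_values):
                for j, b in enumerate(self.b_values):
                    fh.write(f"{a:.6g},{b:.6g},{self.labels[i, j]}\n")
        sidecar = {"provenance": self.provenance, "metadata": self.metadata}
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(sidecar, fh, indent=2, default=str)


def analytic_diagram(a_values, b_values, params: GLVParams | None = None,
                     scenario: str | None = None) -> DiagramGrid:
    """Label every (a, b) node with its analytic region/regime."""
    if scenario is None:
        scenario = params.scenario if params is not None else "EEI"
    a_values = np.asarray(a_values, dtype=float)
    b_values = np.asarray(b_values, dtype=float)
    labels = np.empty((a_values.size, b_values.size), dtype=object)
    for i, a in enumerate(a_values):
        for j, b in enumerate(b_values):
            if scenario == "EEI":
                try:
                    labels[i, j] = eei_region(a, b, params).value
                except ValueError:
                    labels[i, j] = RegionLabelEEI.BOUNDARY.value
            else:
                labels[i, j] = iii_regime(a, b).value
    meta = {"scenario": scenario}
    if params is not None:
        meta["params"] = dataclasses.asdict(params)
    return DiagramGrid(a_values, b_values, labels, provenance="analytic", metadata=meta)
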