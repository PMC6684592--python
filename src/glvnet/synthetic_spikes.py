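"""Synthetic spike data with known ground truth.

Populations of inhomogeneous-Poisson spike trains whose per-population
rate trajectories follow prescribed rate-model solutions.  Every
downstream stage (binning, steady-state classification, regime
detection) can thus be tested against a known generating regime without
running spiking-network simulations.  Sampling is at the population
level: per bin, the population spike count is Poisson with mean
rate * N * dt, and events are placed uniformly in time and across the
population's neurons — downstream statistics depend only on population
counts, so this keeps fixtures O(number of events).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glv_core import GLVParams, integrate
from .lif_net import SpikeData

__all__ = [
    "RateSchedule",
    "poisson_spikes_from_schedule",
    "regime_fixture",
    "EEI_PRESETS",
    "III_PRESETS",
]

#: (a, b, initial rate state) per EEI region; the initial conditions are
#: the presets under which each region's attractor is reached
EEI_PRESETS = {
    "region1": (1.2, 1.2, (1e-3, 1e-3, 0.01)),
    "region2": (0.9, 1.3, (1e-4, 1e-4, 0.02)),
    "region3": (1.2, 0.9, (1e-4, 1e-4, 0.02)),
    "region4": (0.98, 0.92, (1e-3, 1e-3, 0.01)),
    "region5": (0.9, 0.9, (4e-4, 3e-4, 0.02)),
    "region6": (0.9, 0.97, (2e-4, 2e-4, 0.01)),
}

#: (a, b, initial rate state) per III regime; the WTA initial condition
#: is asymmetric so that the first population wins deterministically
III_PRESETS = {
    "coexistence": (0.75, 0.75, (0.3, 0.25, 0.2)),
    "oscillatory": (1.4, 1.0, (0.3, 0.25, 0.2)),
    "wta": (2.0, 2.0, (0.35, 0.25, 0.2)),
}

#: model-time horizons long enough for each scenario's attractor to be
#: reached while keeping several oscillation cycles in view
_HORIZONS = {"EEI": 80.0, "III": 160.0}

_DEFAULT_SIZES = {"EEI": (600, 600, 300), "III": (400, 400, 400)}


@dataclass
class RateSchedule:
    """Piecewise-constant per-neuron target rates on a uniform bin grid."""

    edges: np.ndarray  # ms, length n_bins + 1
    rates: np.ndarray  # Hz, shape (n_bins, 3)
    pop_sizes: tuple[int, int, int]
    labels: tuple[str, str, str] = ("x1", "x2", "x3")

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (self.edges.size - 1, 3):
            raise ValueError("rates must be (n_bins, 3)")
        if np.any(self.rates < 0) or not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be non-negative and finite")

    @property
    def duration(self) -> float:
        return float(self.edges[-1])


def poisson_spikes_from_schedule(schedule: RateSchedule, seed: int) -> SpikeData:
    """Seeded Poisson realization of a rate schedule."""
    rng = np.random.default_rng(seed)
    widths_s = np.diff(schedule.edges) * 1e-3
    sizes = schedule.pop_sizes
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    all_times, all_ids = [], []
    for k in range(3):
        means = schedule.rates[:, k] * sizes[k] * widths_s
        counts = rng.poisson(means)
        total = int(counts.sum())
        if total == 0:
            continue
        lo = np.repeat(schedule.edges[:-1], counts)
        hi = np.repeat(schedule.edges[1:], counts)
        times = rng.uniform(lo, hi)
        ids = rng.integers(offsets[k], offsets[k + 1], size=total)
        all_times.append(times)
        all_ids.append(ids)
    if all_times:
        times = np.concatenate(all_times)
        ids = np.concatenate(all_ids)
        order = np.argsort(times, kind="stable")
        times, ids = times[order], ids[order]
    else:
        times = np.empty(0)
        ids = np.empty(0, dtype=np.int64)
    slices = tuple((schedule.labels[k], int(offsets[k]), int(offsets[k + 1]))
                   for k in range(3))
    return SpikeData(times=times, ids=ids, pop_slices=slices,
                     duration=schedule.duration, params={"seed": seed})


def regime_fixture(
    scenario: str,
    name: str,
    seed: int,
    duration: float = 2000.0,
    bin_width: float | None = None,
    peak_rate: float = 30.0,
    pop_sizes: tuple[int, int, int] | None = None,
) -> tuple[RateSchedule, SpikeData]:
    """Ground-truth schedule + Poisson spikes for a named dynamical preset.

    The schedule is the rate-model trajectory of the preset, rescaled so
    its peak equals ``peak_rate`` Hz and stretched onto ``duration`` ms.
    """
    presets = EEI_PRESETS if scenario == "EEI" else III_PRESETS
    if name not in presets:
        raise ValueError(f"unknown preset {name!r} for scenario {scenario}; "
                         f"choose from {sorted(presets)}")
    a, b, x0 = presets[name]
    if bin_width is None:
        bin_width = 8.0 if scenario == "EEI" else 3.0
    if pop_sizes is None:
        pop_sizes = _DEFAULT_SIZES[scenario]

    horizon = _HORIZONS[scenario]
    n_bins = int(np.ceil(duration / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    centers_model = (edges[:-1] + bin_width / 2.0) / duration * horizon

    params = GLVParams(scenario, a=a, b=b)
    traj = integrate(params, np.array(x0), duration=horizon,
                     n_points=4 * n_bins + 1)
    states = np.maximum(traj.states, 0.0)
    peak = states.max()
    if peak <= 0:
        raise ValueError("degenerate preset trajectory")
    scale = peak_rate / peak
    rates = np.column_stack([
        np.interp(centers_model, traj.times, states[:, k] * scale) for k in range(3)
    ])
    labels = ("x1", "x2", "y") if scenario == "EEI" else ("x1", "x2", "x3")
    schedule = RateSchedule(edges=edges, rates=rates, pop_sizes=tuple(pop_sizes),
                            labels=labels)
    return schedule, poisson_spikes_from_schedule(schedule, seed)
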