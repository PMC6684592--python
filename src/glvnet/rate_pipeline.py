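"""Spike data to population rates, state classification, and simulated diagrams.

The steady-state classifier mirrors the analysis used to compare the
spiking networks with the rate-model predictions: population rates are
binned, the post-transient mean-rate vector is projected onto the three
unit templates (0,0,1), (0,1,1)/sqrt(2), (1,0,1)/sqrt(2) representing
the attractors p001, p011, p101, and the largest projection wins.  For
the III scenario a regime classifier separates coexistence,
winner-take-all, and the oscillatory (heteroclinic) state from the
binned rate traces alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .bifurcation_maps import DiagramGrid, IIIRegime
from .glv_core import Trajectory
from .lif_net import BlockSpec, LIFNeuronParams, SpikeData, build_network, simulate_lif

__all__ = [
    "RateTrace",
    "StateClassEEI",
    "bin_rates",
    "steady_state_vector",
    "classify_eei",
    "classify_iii",
    "oscillation_metrics",
    "simulated_diagram",
    "compare_diagrams",
]

#: projection templates for the EEI steady states, in classification
#: priority order (ties on degenerate inputs resolve to the earlier one)
EEI_TEMPLATES = {
    "P001": np.array([0.0, 0.0, 1.0]),
    "P011": np.array([0.0, 1.0, 1.0]) / np.sqrt(2.0),
    "P101": np.array([1.0, 0.0, 1.0]) / np.sqrt(2.0),
}

#: analytic-region -> spiking-attractor correspondence; R5 is bistable
REGION_TO_CLASS = {
    "R1": ("P001",),
    "R2": ("P011",),
    "R6": ("P011",),
    "R3": ("P101",),
    "R4": ("P101",),
    "R5": ("P011", "P101"),
}


@dataclass
class RateTrace:
    """Binned per-neuron population rates (Hz) on a uniform time grid."""

    bin_centers: np.ndarray  # ms
    rates: np.ndarray  # shape (n_bins, 3), population order (x1, x2, y/x3)
    bin_width: float  # ms
    pop_sizes: tuple[int, int, int]
    labels: tuple[str, str, str] = ("x1", "x2", "y")


@dataclass(frozen=True)
class StateClassEEI:
    value: str  # P001 | P011 | P101
    projections: tuple[float, float, float]


def bin_rates(spikes: SpikeData, bin_width: float) -> RateTrace:
    """Count spikes per population in half-open bins [t, t + width).

    Rates are per neuron: count / (bin_width * N_pop), in Hz.  The total
    count over all bins equals the number of events in range.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(spikes.duration / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    pops = spikes.population_of(spikes.ids)
    sizes = tuple(stop - start for _, start, stop in spikes.pop_slices)
    rates = np.zeros((n_bins, 3))
    for k in range(3):
        t = spikes.times[pops == k]
        counts, _ = np.histogram(t, bins=edges)
        # np.histogram closes the last bin; [t, t+w) everywhere else
        rates[:, k] = counts / (bin_width * 1e-3 * sizes[k])
    centers = edges[:-1] + bin_width / 2.0
    labels = tuple(lab for lab, _, _ in spikes.pop_slices)
    return RateTrace(bin_centers=centers, rates=rates, bin_width=bin_width,
                     pop_sizes=sizes, labels=labels)


def steady_state_vector(trace: RateTrace, discard: float = 100.0) -> np.ndarray:
    """Mean rate per population over all bins after the transient window."""
    keep = trace.bin_centers >= discard
    if not np.any(keep):
        raise ValueError("discard window leaves no bins")
    return trace.rates[keep].mean(axis=0)


def classify_eei(vector) -> StateClassEEI:
    """Assign a steady-state vector to the nearest attractor template."""
    v = np.asarray(vector, dtype=float)
    if v.shape != (3,) or np.any(v < 0):
        raise ValueError("need a non-negative rate triple")
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("cannot classify the zero vector")
    v = v / norm
    names = list(EEI_TEMPLATES)
    proj = np.array([float(EEI_TEMPLATES[n] @ v) for n in names])
    winner = names[int(np.argmax(proj))]  # first max implements the tie-break order
    return StateClassEEI(value=winner, projections=tuple(proj))


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="same")


@dataclass(frozen=True)
class IIIClassifierConfig:
    """Thresholds of the III regime classifier.

    ``theta_active`` and ``theta_silent`` are fractions of the grand
    mean of the nonzero population mean rates; the oscillation test
    requires at least ``min_alternations`` changes of the dominant
    population with per-population dominance fractions strictly inside
    ``dominance_bounds``.
    """

    theta_active_frac: float = 0.20
    theta_silent_frac: float = 0.05
    min_alternations: int = 3
    dominance_bounds: tuple[float, float] = (0.1, 0.9)
    smooth_bins: int = 5


def classify_iii(trace: RateTrace, discard: float = 100.0,
                 config: IIIClassifierConfig | None = None) -> IIIRegime:
    """Regime of a III rate trace: WTA, oscillatory, or coexistence."""
    if config is None:
        config = IIIClassifierConfig()
    keep = trace.bin_centers >= discard
    if trace.bin_centers[keep].size * trace.bin_width < 1000.0:
        raise ValueError("need at least 1 s of trace after the discard window")
    R = trace.rates[keep]
    means = R.mean(axis=0)
    nonzero = means[means > 0]
    if nonzero.size == 0:
        raise ValueError("all populations silent; no regime defined")
    grand = float(nonzero.mean())
    th_act = config.theta_active_frac * grand
    th_sil = config.theta_silent_frac * grand

    active = means > th_act
    silent = means < th_sil
    if np.sum(active) == 1 and np.sum(silent) == 2:
        return IIIRegime.WINNER_TAKE_ALL

    # oscillation = populations alternating between dominance and
    # near-silence: each swinging population is active (above threshold)
    # for a fraction of the time strictly inside the bounds, and the
    # identity of the dominant population changes repeatedly
    S = np.column_stack([_smooth(R[:, k], config.smooth_bins) for k in range(3)])
    lo, hi = config.dominance_bounds
    active_frac = (S > th_act).mean(axis=0)
    swingers = np.sum((active_frac > lo) & (active_frac < hi))
    dominant = np.argmax(S, axis=1)
    dominant = dominant[S.max(axis=1) > th_act]
    if dominant.size and swingers >= 2:
        runs = dominant[np.r_[True, np.diff(dominant) != 0]]
        if runs.size - 1 >= config.min_alternations:
            return IIIRegime.OSCILLATORY
    return IIIRegime.COEXISTENCE


def oscillation_metrics(times, rates, theta_active: float | None = None,
                        smooth_bins: int = 5, min_separation: int = 3,
                        regular_factor: float = 1.1) -> dict:
    """Peak times, period sequence and relative phases of a 3-population
    oscillation.

    Accepts any uniformly sampled (times, rates) pair — a binned spiking
    trace or a rate-model trajectory.  Peaks are local maxima of the
    smoothed traces above ``theta_active`` (default: 20% of the grand
    mean) separated by at least ``min_separation`` samples.

    A "cycle" is the interval between successive peaks of one
    population; its length is the concurrent period.  Within each
    complete cycle, the gaps between consecutive peaks (of any
    population), divided by that cycle's period and scaled by 2*pi, are
    the relative phases; a perfect three-phase rotation gives 2*pi/3.
    Near a heteroclinic cycle the period grows from cycle to cycle and
    the phase relation degrades with it, so phases are also reported
    restricted to "regular" cycles — those whose period is within
    ``regular_factor`` of the shortest observed period.
    """
    times = np.asarray(times, dtype=float)
    R = np.asarray(rates, dtype=float)
    if R.shape != (times.size, 3):
        raise ValueError("rates must be (len(times), 3)")
    if theta_active is None:
        theta_active = 0.2 * R.mean()
    peak_times = []
    for k in range(3):
        s = _smooth(R[:, k], smooth_bins)
        # prominence filter rejects numerical ripple on dwell plateaus
        idx, _ = find_peaks(s, height=theta_active, distance=min_separation,
                            prominence=0.5 * theta_active)
        # the smoothing kernel is truncated at the ends; drop edge peaks
        idx = idx[(idx >= smooth_bins) & (idx < times.size - smooth_bins)]
        peak_times.append(times[idx])

    # complete cycles over all populations, ordered by start time
    cycles = sorted(
        (pk[i], pk[i + 1] - pk[i], k)
        for k in range(3)
        for i, pk in [(i, peak_times[k]) for i in range(peak_times[k].size - 1)]
    )
    if len(cycles) < 3:
        raise ValueError("need at least 3 full cycles to measure oscillations")
    period_sequence = np.array([c[1] for c in cycles])
    periods = {k: np.diff(peak_times[k]) for k in range(3)}

    all_peaks = sorted((t, k) for k in range(3) for t in peak_times[k])
    order_seq = [k for _, k in all_peaks]
    # cyclic order from the first three distinct populations to peak
    order: list[int] = []
    for k in order_seq:
        if k not in order:
            order.append(k)
        if len(order) == 3:
            break

    phases, phase_periods = [], []
    for start, period, _ in cycles:
        inside = [start] + [t for t, _ in all_peaks if start < t <= start + period]
        for gap in np.diff(inside):
            phases.append(gap / period * 2 * np.pi)
            phase_periods.append(period)
    phases = np.array(phases)
    phase_periods = np.array(phase_periods)
    regular = phases[phase_periods <= regular_factor * period_sequence.min()]
    return {
        "peak_times": peak_times,
        "periods": periods,
        "period_sequence": period_sequence,
        "relative_phases": phases,
        "mean_phase": float(phases.mean()) if phases.size else np.nan,
        "regular_phases": regular,
        "mean_regular_phase": float(regular.mean()) if regular.size else np.nan,
        "dominance_order": order,
    }


def trajectory_metrics(traj: Trajectory, **kwargs) -> dict:
    """oscillation_metrics applied to a rate-model trajectory."""
    return oscillation_metrics(traj.times, traj.states, **kwargs)


def simulated_diagram(
    a_values,
    b_values,
    scenario: str = "EEI",
    seeds=(0,),
    size_factor: float = 0.1,
    duration: float = 1000.0,
    bin_width: float | None = None,
    discard: float = 100.0,
    neuron: LIFNeuronParams | None = None,
    init: str = "near_p000",
) -> DiagramGrid:
    """Classify LIF simulations on an (a, b) grid into a DiagramGrid.

    One network + simulation per seed per node; the stored label is the
    majority over seeds, with the per-seed labels kept in the metadata.
    Failed nodes are labelled "failed" and the diagram is still returned.
    """
    a_values = np.asarray(a_values, dtype=float)
    b_values = np.asarray(b_values, dtype=float)
    if bin_width is None:
        bin_width = 8.0 if scenario == "EEI" else 3.0
    labels = np.empty((a_values.size, b_values.size), dtype=object)
    per_seed: dict[str, list[str]] = {}
    for i, a in enumerate(a_values):
        for j, b in enumerate(b_values):
            node_labels = []
            for seed in seeds:
                try:
                    spec = (BlockSpec.eei(a, b) if scenario == "EEI"
                            else BlockSpec.iii(a, b)).scaled(size_factor)
                    conn = build_network(spec, seed=seed)
                    spikes = simulate_lif(conn, neuron=neuron, duration=duration,
                                          init=init, seed=seed + 1)
                    trace = bin_rates(spikes, bin_width)
                    if scenario == "EEI":
                        lab = classify_eei(steady_state_vector(trace, discard)).value
                    else:
                        lab = classify_iii(trace, discard).value
                except Exception as exc:  # noqa: BLE001 - node-level isolation
                    lab = f"failed:{type(exc).__name__}"
                node_labels.append(lab)
            per_seed[f"{a:.6g},{b:.6g}"] = node_labels
            ok = [l for l in node_labels if not l.startswith("failed")]
            labels[i, j] = max(set(ok), key=ok.count) if ok else "failed"
    meta = {
        "scenario": scenario,
        "seeds": list(seeds),
        "size_factor": size_factor,
        "duration": duration,
        "bin_width": bin_width,
        "discard": discard,
        "per_seed_labels": per_seed,
    }
    return DiagramGrid(a_values, b_values, labels, provenance="spiking_simulation",
                       metadata=meta)


def compare_diagrams(analytic: DiagramGrid, simulated: DiagramGrid) -> dict:
    """Per-node agreement between an analytic and a simulated diagram.

    Analytic regions map to spiking attractors via R1 -> P001,
    R2/R6 -> P011, R3/R4 -> P101; bistable R5 accepts either winner.
    Boundary-labelled analytic nodes are excluded from the denominator.
    """
    if (not np.array_equal(analytic.a_values, simulated.a_values)
            or not np.array_equal(analytic.b_values, simulated.b_values)):
        raise ValueError("diagram grids differ")
    n_match = 0
    n_total = 0
    mismatches = []
    for i, a in enumerate(analytic.a_values):
        for j, b in enumerate(analytic.b_values):
            region = str(analytic.labels[i, j])
            sim = str(simulated.labels[i, j])
            if region not in REGION_TO_CLASS:
                continue
            n_total += 1
            if sim in REGION_TO_CLASS[region]:
                n_match += 1
            else:
                mismatches.append({"a": float(a), "b": float(b),
                                   "analytic": region, "simulated": sim})
    return {
        "agreement": n_match / n_total if n_total else np.nan,
        "n_compared": n_total,
        "mismatches": mismatches,
    }
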