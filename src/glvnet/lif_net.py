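"""Block-structured random networks of leaky integrate-and-fire neurons.

This is the data-generating stage of the pipeline.  A network is a
directed weighted graph over three neuron populations; connectivity is
drawn with exact per-block out-degrees and in-degrees equalized to
within one synapse (configuration model), so that no structural
asymmetry can bias the competition between subnetworks.  Neurons follow

    tau dv_i/dt = -v_i + tau * sum_j J_ij S_j(t) + R_res * I

integrated by forward Euler at step dt, with delta synapses (an
arriving spike after one transmission-delay step jumps the target's
membrane potential by the synaptic weight in mV), threshold-and-reset
spiking, and no refractory period.  The external drive is a DC current
identical for all neurons, so the only randomness is in the
connectivity and the initial membrane potentials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

__all__ = [
    "LIFNeuronParams",
    "BlockSpec",
    "ConnectivityRealization",
    "SpikeData",
    "build_network",
    "simulate_lif",
    "uncoupled_rate",
]


@dataclass(frozen=True)
class LIFNeuronParams:
    """Single-neuron constants (units in the field descriptions).

    ``R_res`` is chosen so that the rheobase current V_th / R_res equals
    250 pA, placing the default 270 pA drive just above threshold drive.
    """

    tau_m: float = 20.0  # membrane time constant, ms
    V_th: float = 20.0  # spike threshold, mV
    V_reset: float = 10.0  # reset potential, mV
    R_res: float = 80.0  # input resistance, MOhm
    I_DC: float = 270.0  # external direct current, pA
    dt: float = 0.1  # integration step, ms
    delay: float = 0.1  # synaptic transmission delay, ms

    def __post_init__(self) -> None:
        if self.V_reset >= self.V_th:
            raise ValueError("V_reset must be below V_th")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.delay < self.dt:
            raise ValueError("delay must be at least one step")

    @property
    def drive_mV(self) -> float:
        """Asymptotic membrane potential R_res * I_DC (MOhm * pA -> 1e-3 mV)."""
        return self.R_res * self.I_DC * 1e-3


def uncoupled_rate(neuron: LIFNeuronParams) -> float:
    """Closed-form firing rate (Hz) of an isolated neuron under DC drive.

    T = tau * ln((R I - V_reset)/(R I - V_th)); zero at or below rheobase.
    """
    ri = neuron.drive_mV
    if ri <= neuron.V_th:
        return 0.0
    period_ms = neuron.tau_m * math.log((ri - neuron.V_reset) / (ri - neuron.V_th))
    return 1000.0 / period_ms


@dataclass(frozen=True)
class BlockSpec:
    """Per-block connectivity specification for one scenario.

    Tables are indexed ``[target_block, source_block]``.  The population
    order is (x1, x2, y) for EEI and (x1, x2, x3) for III.
    """

    scenario: str
    sizes: tuple[int, int, int]
    epsilon: float  # base connection probability (E-E for EEI; uniform for III)
    J: float  # base PSP amplitude, mV (EPSP for EEI; inhibitory base for III)
    a: float
    b: float
    g: float = 6.0
    p: float = 3.0
    w: float = 2.0

    @classmethod
    def eei(cls, a: float, b: float, sizes=(6000, 6000, 3000), epsilon: float = 1.0 / 30.0,
            J: float = 0.09, g: float = 6.0, p: float = 3.0, w: float = 2.0) -> "BlockSpec":
        return cls("EEI", tuple(sizes), epsilon, J, a, b, g, p, w)

    @classmethod
    def iii(cls, a: float, b: float, sizes=(4000, 4000, 4000), prob: float = 0.1,
            J: float = -0.012) -> "BlockSpec":
        return cls("III", tuple(sizes), prob, J, a, b, g=1.0, p=1.0, w=1.0)

    def scaled(self, factor: float) -> "BlockSpec":
        """Shrink populations by ``factor`` while preserving the
        population-level coupling (per-synapse weights scale up by
        1/factor, keeping N_target * prob * weight fixed)."""
        sizes = tuple(int(round(n * factor)) for n in self.sizes)
        return replace(self, sizes=sizes, J=self.J / factor)

    @property
    def labels(self) -> tuple[str, str, str]:
        return ("x1", "x2", "y") if self.scenario == "EEI" else ("x1", "x2", "x3")

    def prob_table(self) -> np.ndarray:
        """Connection probabilities [target, source]."""
        e, p = self.epsilon, self.p
        if self.scenario == "EEI":
            tbl = np.array([[e, e, p * e], [e, e, p * e], [p * e, p * e, p * e]])
        else:
            tbl = np.full((3, 3), e)
        if np.any(tbl <= 0) or np.any(tbl > 1):
            raise ValueError("all connection probabilities must lie in (0, 1]")
        return tbl

    def weight_table(self) -> np.ndarray:
        """Per-synapse PSP amplitudes in mV, [target, source]."""
        a, b, g, w, J = self.a, self.b, self.g, self.w, self.J
        if self.scenario == "EEI":
            return np.array(
                [
                    [w * J, J, -g * b * J],
                    [J, w * J, -g * a * J],
                    [b * J, a * J, -g * J],
                ]
            )
        # III: cyclic May-Leonard magnitudes on a common (negative) base
        return J * np.array([[1.0, a, b], [b, 1.0, a], [a, b, 1.0]])


@dataclass
class ConnectivityRealization:
    """A concrete directed weighted graph drawn from a BlockSpec."""

    weights: sparse.csr_matrix  # [source, target] synaptic weights, mV
    pop_slices: tuple[tuple[str, int, int], ...]  # (label, start, stop) per block
    seed: int
    spec: BlockSpec

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    @property
    def population_map(self) -> np.ndarray:
        """Block index (0, 1, 2) of every neuron."""
        out = np.empty(self.n_neurons, dtype=np.int64)
        for k, (_, start, stop) in enumerate(self.pop_slices):
            out[start:stop] = k
        return out


def _equalized_targets(rng, n_src: int, d: int, tgt_start: int, n_tgt: int,
                       forbid_self: int | None) -> np.ndarray:
    """(n_src, d) matrix of distinct target ids with exact out-degree d,
    in-degrees within 1 of each other, no self-loops.

    Built by shuffling a stub list with equalized multiplicities and
    repairing within-row duplicates / self-loops by random swaps.
    """
    total = n_src * d
    base, extra = divmod(total, n_tgt)
    counts = np.full(n_tgt, base, dtype=np.int64)
    if extra:
        counts[rng.choice(n_tgt, size=extra, replace=False)] += 1
    stubs = np.repeat(np.arange(tgt_start, tgt_start + n_tgt), counts)
    rng.shuffle(stubs)
    M = stubs.reshape(n_src, d)

    if forbid_self is not None:
        self_ids = np.arange(forbid_self, forbid_self + n_src)
    for _ in range(200):
        S = np.sort(M, axis=1)
        bad_rows = set(np.nonzero((S[:, 1:] == S[:, :-1]).any(axis=1))[0])
        if forbid_self is not None:
            bad_rows |= set(np.nonzero((M == self_ids[:, None]).any(axis=1))[0])
        if not bad_rows:
            return M
        for i in bad_rows:
            row = M[i]
            seen: dict[int, int] = {}
            for j in range(d):
                t = row[j]
                dup = t in seen or (forbid_self is not None and t == forbid_self + i)
                if not dup:
                    seen[t] = j
                    continue
                # swap with a random entry in another row
                i2 = int(rng.integers(n_src))
                j2 = int(rng.integers(d))
                M[i, j], M[i2, j2] = M[i2, j2], M[i, j]
    raise RuntimeError("degree-equalized wiring failed to converge")


def build_network(spec: BlockSpec, seed: int) -> ConnectivityRealization:
    """Realize the block connectivity with exact fixed out-degrees.

    Every neuron sends exactly round(prob * N_target) synapses into each
    target block; within each (source-block, target-block) pair the
    in-degrees differ by at most one.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    sizes = spec.sizes
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    probs = spec.prob_table()
    wts = spec.weight_table()

    rows, cols, data = [], [], []
    for m in range(3):  # target block
        for s in range(3):  # source block
            d = int(round(probs[m, s] * sizes[m]))
            cap = sizes[m] - (1 if m == s else 0)
            if d > cap:
                raise ValueError(
                    f"requested out-degree {d} exceeds available targets {cap} "
                    f"in block pair (source {s}, target {m})"
                )
            if d == 0:
                continue
            M = _equalized_targets(
                rng, sizes[s], d, int(offsets[m]), sizes[m],
                forbid_self=int(offsets[s]) if m == s else None,
            )
            src_ids = np.repeat(np.arange(offsets[s], offsets[s + 1]), d)
            rows.append(src_ids)
            cols.append(M.ravel())
            data.append(np.full(src_ids.size, wts[m, s]))

    n = int(offsets[-1])
    W = sparse.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    labels = spec.labels
    slices = tuple((labels[k], int(offsets[k]), int(offsets[k + 1])) for k in range(3))
    return ConnectivityRealization(weights=W, pop_slices=slices, seed=seed, spec=spec)


@dataclass
class SpikeData:
    """Time-stamped spike events with a neuron -> population map."""

    times: np.ndarray  # ms, nondecreasing
    ids: np.ndarray  # neuron ids
    pop_slices: tuple[tuple[str, int, int], ...]
    duration: float  # ms
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.times.shape != self.ids.shape:
            raise ValueError("times and ids must have equal length")
        n = self.pop_slices[-1][2]
        if self.ids.size and (self.ids.min() < 0 or self.ids.max() >= n):
            raise ValueError("spike ids outside the population map")
        if self.times.size and (self.times.min() < 0 or self.times.max() > self.duration):
            raise ValueError("spike times outside [0, duration]")

    @property
    def n_events(self) -> int:
        return self.times.size

    def population_of(self, ids: np.ndarray) -> np.ndarray:
        starts = np.array([s for _, s, _ in self.pop_slices])
        return np.searchsorted(starts, ids, side="right") - 1

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SpikeData)
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.ids, other.ids)
            and self.pop_slices == other.pop_slices
            and self.duration == other.duration
        )


#: initial membrane-potential ranges (mV) per preset; None entries use
#: the per-population EEI ranges
INIT_PRESETS = {
    # all populations start low: the reduced system sits near the origin
    "near_p000": {"EEI": ((0.0, 15.0), (0.0, 15.0), (0.0, 17.0)),
                  "III": ((0.0, 19.0), (0.0, 19.0), (0.0, 19.0))},
    # bias the second excitatory population (and inhibition) upward
    "favor_E2": {"EEI": ((0.0, 15.0), (0.0, 20.0), (0.0, 20.0)),
                 "III": ((0.0, 19.0), (0.0, 19.0), (0.0, 19.0))},
}


def _initial_potentials(conn: ConnectivityRealization, init, rng) -> np.ndarray:
    if isinstance(init, str):
        try:
            ranges = INIT_PRESETS[init][conn.spec.scenario]
        except KeyError:
            raise ValueError(f"unknown initial-condition preset {init!r}") from None
        v0 = np.empty(conn.n_neurons)
        for (lo, hi), (_, start, stop) in zip(ranges, conn.pop_slices):
            v0[start:stop] = rng.uniform(lo, hi, stop - start)
        return v0
    v0 = np.asarray(init, dtype=float)
    if v0.shape != (conn.n_neurons,):
        raise ValueError("explicit initial potentials must have one entry per neuron")
    return v0.copy()


def simulate_lif(
    conn: ConnectivityRealization,
    neuron: LIFNeuronParams | None = None,
    duration: float = 4000.0,
    init: str | np.ndarray = "near_p000",
    seed: int = 0,
) -> SpikeData:
    """Forward-Euler simulation of the spiking network.

    All neurons crossing threshold within a step spike simultaneously;
    their spikes are delivered after the transmission delay.  The
    simulation is deterministic given the connectivity, seed and initial
    condition.
    """
    if neuron is None:
        neuron = LIFNeuronParams()
    dt, tau = neuron.dt, neuron.tau_m
    n_steps = int(round(duration / dt))
    if abs(n_steps * dt - duration) > 1e-9:
        raise ValueError("duration must be a multiple of dt")
    delay_steps = int(round(neuron.delay / dt))

    rng = np.random.default_rng(seed)
    v = _initial_potentials(conn, init, rng)
    n = v.size
    drive = neuron.drive_mV
    leak = dt / tau

    W = conn.weights  # csr by source row
    indptr, indices, wdata = W.indptr, W.indices, W.data

    pending = np.zeros((delay_steps, n))
    spike_times: list[np.ndarray] = []
    spike_ids: list[np.ndarray] = []

    for step in range(n_steps):
        slot = step % delay_steps
        v += leak * (drive - v)
        v += pending[slot]
        pending[slot] = 0.0
        if not np.all(np.isfinite(v)):
            raise RuntimeError(f"non-finite membrane potential at step {step}")
        spiked = np.flatnonzero(v >= neuron.V_th)
        if spiked.size:
            t_spike = (step + 1) * dt
            spike_ids.append(spiked)
            spike_times.append(np.full(spiked.size, t_spike))
            v[spiked] = neuron.V_reset
            # deliver after the delay
            tgt_slot = (step + delay_steps) % delay_steps
            if spiked.size == 1:
                i = spiked[0]
                np.add.at(pending[tgt_slot], indices[indptr[i]:indptr[i + 1]],
                          wdata[indptr[i]:indptr[i + 1]])
            else:
                tgt = np.concatenate([indices[indptr[i]:indptr[i + 1]] for i in spiked])
                wt = np.concatenate([wdata[indptr[i]:indptr[i + 1]] for i in spiked])
                np.add.at(pending[tgt_slot], tgt, wt)

    if spike_times:
        times = np.concatenate(spike_times)
        ids = np.concatenate(spike_ids)
    else:
        times = np.empty(0)
        ids = np.empty(0, dtype=np.int64)
    params = {
        "neuron": neuron.__dict__.copy(),
        "spec": conn.spec.__dict__.copy(),
        "connectivity_seed": conn.seed,
        "init": init if isinstance(init, str) else "explicit",
        "seed": seed,
    }
    return SpikeData(times=times, ids=ids, pop_slices=conn.pop_slices,
                     duration=duration, params=params)
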