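"""Binning, steady-state classification, regime detection, diagrams."""

import numpy as np
import pytest

from glvnet import GLVParams, integrate
from glvnet.bifurcation_maps import DiagramGrid, IIIRegime, analytic_diagram
from glvnet.lif_net import SpikeData
from glvnet.rate_pipeline import (
    RateTrace,
    bin_rates,
    classify_eei,
    classify_iii,
    compare_diagrams,
    oscillation_metrics,
    simulated_diagram,
    steady_state_vector,
)
from glvnet.synthetic_spikes import III_PRESETS, regime_fixture


def make_spikes(times, ids, n_per_pop=10, duration=1000.0):
    slices = (("x1", 0, n_per_pop), ("x2", n_per_pop, 2 * n_per_pop),
              ("x3", 2 * n_per_pop, 3 * n_per_pop))
    return SpikeData(times=np.asarray(times, dtype=float),
                     ids=np.asarray(ids, dtype=np.int64),
                     pop_slices=slices, duration=duration)


def make_trace(rates, bin_width=8.0, n_per_pop=10):
    rates = np.asarray(rates, dtype=float)
    centers = (np.arange(rates.shape[0]) + 0.5) * bin_width
    return RateTrace(bin_centers=centers, rates=rates, bin_width=bin_width,
                     pop_sizes=(n_per_pop,) * 3)


class TestBinRates:
    def test_two_spikes_in_one_bin(self):
        spikes = make_spikes([1.0, 5.0], [0, 3], n_per_pop=10, duration=8.0)
        trace = bin_rates(spikes, 8.0)
        assert trace.rates.shape == (1, 3)
        assert trace.rates[0, 0] == pytest.approx(25.0)  # 2/(0.008 s * 10)

    def test_empty_input_gives_zero_trace(self):
        trace = bin_rates(make_spikes([], [], duration=100.0), 8.0)
        assert np.all(trace.rates == 0.0)

    def test_spike_count_conserved(self, rng):
        n = 500
        spikes = make_spikes(np.sort(rng.uniform(0, 999.9, n)),
                             rng.integers(0, 30, n))
        trace = bin_rates(spikes, 3.0)
        counts = trace.rates * trace.bin_width * 1e-3 * np.array(trace.pop_sizes)
        assert int(round(counts.sum())) == n

    def test_bins_are_half_open(self):
        spikes = make_spikes([8.0], [0], duration=16.0)
        trace = bin_rates(spikes, 8.0)
        assert trace.rates[0, 0] == 0.0 and trace.rates[1, 0] > 0.0


class TestSteadyState:
    def test_constant_trace(self):
        trace = make_trace(np.tile([5.0, 0.0, 5.0], (50, 1)))
        np.testing.assert_allclose(steady_state_vector(trace), [5.0, 0.0, 5.0])

    def test_transient_discarded(self):
        rates = np.tile([2.0, 2.0, 2.0], (50, 1))
        rates[:12] = [50.0, 0.0, 0.0]  # transient confined to first 96 ms
        trace = make_trace(rates)
        np.testing.assert_allclose(steady_state_vector(trace, discard=100.0), 2.0)

    def test_empty_window_rejected(self):
        trace = make_trace(np.ones((5, 3)))
        with pytest.raises(ValueError, match="no bins"):
            steady_state_vector(trace, discard=1000.0)

    def test_fixture_recovers_p011_direction(self):
        """region-2 fixture's steady state is proportional to (0, x2*, y*)."""
        _, spikes = regime_fixture("EEI", "region2", seed=0)
        vec = steady_state_vector(bin_rates(spikes, 8.0))
        x2 = (1 - 0.9) / (3 * 0.9**2 - 2)
        y = (3 * 0.9 - 2) / (18 * (3 * 0.9**2 - 2))
        expected = np.array([0.0, x2, y])
        cos = vec @ expected / np.linalg.norm(vec) / np.linalg.norm(expected)
        assert cos > 0.99


class TestClassifyEEI:
    @pytest.mark.parametrize(
        "vec, expected",
        [((0, 0, 1), "P001"), ((5, 0, 5), "P101"), ((1, 4, 4), "P011")],
    )
    def test_examples(self, vec, expected):
        assert classify_eei(np.array(vec, dtype=float)).value == expected

    def test_projection_values(self):
        res = classify_eei(np.array([1.0, 4.0, 4.0]))
        np.testing.assert_allclose(res.projections, [0.696, 0.984, 0.615], atol=1e-3)

    def test_scale_invariance(self, rng):
        for _ in range(50):
            v = rng.uniform(0, 10, 3) + 1e-6
            c = rng.uniform(0.01, 100)
            assert classify_eei(v).value == classify_eei(c * v).value

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            classify_eei(np.zeros(3))


class TestClassifyIII:
    def test_regime_recovery_on_fixtures(self):
        """Poisson fixtures from the three regimes are recovered >= 9/10."""
        expected = {"coexistence": "coexistence", "wta": "winner_take_all",
                    "oscillatory": "oscillatory"}
        for name, target in expected.items():
            hits = 0
            for seed in range(10):
                _, spikes = regime_fixture("III", name, seed=seed)
                if classify_iii(bin_rates(spikes, 3.0)).value == target:
                    hits += 1
            assert hits >= 9, f"{name}: {hits}/10"

    def test_short_trace_rejected(self):
        trace = make_trace(np.ones((20, 3)), bin_width=3.0)
        with pytest.raises(ValueError, match="1 s"):
            classify_iii(trace, discard=0.0)

    def test_all_silent_rejected(self):
        trace = make_trace(np.zeros((500, 3)), bin_width=3.0)
        with pytest.raises(ValueError, match="silent"):
            classify_iii(trace, discard=0.0)


class TestOscillationMetrics:
    def test_sinusoids_with_third_period_lags(self):
        t = np.linspace(0, 10, 2001)
        R = np.column_stack([np.sin(2 * np.pi * (t / 2 - k / 3)) + 1.5
                             for k in range(3)])
        m = oscillation_metrics(t, R)
        assert m["mean_phase"] == pytest.approx(2 * np.pi / 3, rel=0.02)
        assert m["dominance_order"] == [0, 1, 2]

    def test_glv_heteroclinic_phases_and_period_growth(self):
        xs = 1.0 / 3.4
        traj = integrate(GLVParams("III", a=1.4, b=1.0),
                         np.array([xs + 6e-3, xs - 2e-3, xs - 4e-3]),
                         duration=300.0, n_points=12001)
        m = oscillation_metrics(traj.times, traj.states)
        assert m["mean_regular_phase"] == pytest.approx(2 * np.pi / 3, rel=0.05)
        # dwell near saddles grows: period sequence nondecreasing
        assert np.all(np.diff(m["period_sequence"]) >= -1e-9)

    def test_too_few_cycles_rejected(self):
        t = np.linspace(0, 10, 1001)
        R = np.tile([1.0, 1.0, 1.0], (t.size, 1))
        with pytest.raises(ValueError, match="cycles"):
            oscillation_metrics(t, R)


class TestDiagrams:
    def test_identical_diagrams_agree_fully(self):
        grid = analytic_diagram([0.9, 1.2], [0.9, 1.2], scenario="EEI")
        sim_labels = np.empty_like(grid.labels)
        mapping = {"R1": "P001", "R2": "P011", "R3": "P101", "R4": "P101",
                   "R5": "P011", "R6": "P011"}
        for i in range(2):
            for j in range(2):
                sim_labels[i, j] = mapping[str(grid.labels[i, j])]
        sim = DiagramGrid(grid.a_values, grid.b_values, sim_labels,
                          provenance="spiking_simulation")
        rep = compare_diagrams(grid, sim)
        assert rep["agreement"] == 1.0 and not rep["mismatches"]

    def test_bistable_node_accepts_either_winner(self):
        an = DiagramGrid([0.9], [0.9], np.array([["R5"]], dtype=object), "analytic")
        for winner in ("P011", "P101"):
            sim = DiagramGrid([0.9], [0.9], np.array([[winner]], dtype=object),
                              "spiking_simulation")
            assert compare_diagrams(an, sim)["agreement"] == 1.0

    def test_boundary_nodes_excluded(self):
        an = DiagramGrid([0.9, 1.0], [0.9],
                         np.array([["boundary"], ["R1"]], dtype=object), "analytic")
        sim = DiagramGrid([0.9, 1.0], [0.9],
                          np.array([["P101"], ["P001"]], dtype=object),
                          "spiking_simulation")
        rep = compare_diagrams(an, sim)
        assert rep["n_compared"] == 1 and rep["agreement"] == 1.0

    def test_grid_mismatch_rejected(self):
        a = analytic_diagram([0.9], [0.9], scenario="EEI")
        b = analytic_diagram([1.0], [0.9], scenario="EEI")
        with pytest.raises(ValueError, match="differ"):
            compare_diagrams(a, b)

    def test_single_node_simulated_diagram(self):
        grid = simulated_diagram([1.2], [1.2], scenario="EEI", seeds=(0,),
                                 size_factor=0.1, duration=600.0)
        assert grid.labels.shape == (1, 1)
        assert grid.provenance == "spiking_simulation"
        assert grid.labels[0, 0] == "P001"
        assert grid.metadata["per_seed_labels"]["1.2,1.2"] == ["P001"]
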