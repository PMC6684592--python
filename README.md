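# glvnet

Population dynamics of hierarchically structured spiking networks:
generalized Lotka-Volterra (GLV) bifurcation analysis of three-subnetwork
architectures, validated against leaky integrate-and-fire (LIF) network
simulations.

## The problem

Cortical and subcortical circuits can be viewed as networks of densely
connected subnetworks — cell assemblies or nuclei — whose interactions shape
the collective activity even without external input. `glvnet` studies two
such architectures, each with three interacting populations:

- **EEI** — two excitatory subnetworks (rates x₁, x₂) reciprocally coupled
  to one inhibitory population (rate y);
- **III** — three inhibitory subnetworks in cyclic competition (a neuronal
  May-Leonard system).

Between-subnetwork synaptic strengths are scaled by two bifurcation
parameters a and b. The package answers: which steady states (all-active,
winner-take-all, inhibition-only) or oscillatory regimes occur for which
(a, b), and does a spiking network with the corresponding block-random
connectivity actually do what the rate model predicts?

## The model

The EEI rate model (with g = 6, p = 3, w = 2, I = 1, k = 1 as defaults):

    ẋ₁ = k x₁ (2w x₁ + 2x₂ − 2pgb y + 2I)
    ẋ₂ = k x₂ (2x₁ + 2w x₂ − 2pga y + 2I)
    ẏ  = k y  (bp x₁ + ap x₂ − pg y + I)

and the III (May-Leonard) rate model:

    ẋᵢ = k xᵢ (−xᵢ − a x_{i+1} − b x_{i+2} + I)   (indices cyclic)

Each system has up to 2³ = 8 on/off equilibria p_{b₁b₂b₃} (each component
either zero or solving the active linear subsystem). `glvnet` enumerates
them, computes Jacobians, eigenvalues and stability, locates transcritical
and Hopf loci in the (a, b) plane, and labels the six EEI regions and the
three III regimes (coexistence for a+b < 2, winner-take-all for a, b > 1,
oscillations with growing period otherwise).

The spiking counterpart builds block-structured random graphs with exact
per-block out-degrees and in-degrees equalized to ±1 (configuration model),
simulates LIF neurons (τ = 20 ms, threshold 20 mV, reset 10 mV, DC drive
270 pA, delta synapses of 0.09 mV base amplitude, 0.1 ms delay and step),
bins spikes into population rates, and classifies the steady state by
projecting the rate vector onto (0,0,1), (0,1,1)/√2, (1,0,1)/√2.

## Worked example

```python
import numpy as np
from glvnet import GLVParams, integrate, enumerate_equilibria
from glvnet.bifurcation_maps import eei_region

params = GLVParams("EEI", a=0.9, b=1.3)
print(eei_region(0.9, 1.3))
# RegionLabelEEI.R2

traj = integrate(params, np.array([1e-4, 1e-4, 0.02]), duration=200.0)
print(np.round(traj.final_state, 4))
# [0.     0.2326 0.0904]
```

The point (a, b) = (0.9, 1.3) lies in region 2: the trajectory passes near
the inhibition-only saddle p₀₀₁ and converges to p₀₁₁ = (0, I(1−a)/(3a²−2),
I(3a−2)/(18(3a²−2))) — the second excitatory population wins, at the printed
coordinates (0, 0.2326, 0.0904). The same prediction can be checked against
a (scaled-down) spiking simulation:

```python
from glvnet import BlockSpec, build_network, simulate_lif
from glvnet.rate_pipeline import bin_rates, classify_eei, steady_state_vector

conn = build_network(BlockSpec.eei(0.9, 1.3).scaled(0.1), seed=0)
spikes = simulate_lif(conn, duration=1000.0, seed=1)
print(classify_eei(steady_state_vector(bin_rates(spikes, 8.0))).value)
# P011
```

A command-line interface mirrors the library
(`glvnet glv-integrate | equilibria | analytic-diagram | simulate |
classify | simulated-diagram | compare | synth-spikes`).

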