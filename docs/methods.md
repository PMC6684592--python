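# Methods

## Rate models

Both architectures are generalized Lotka-Volterra (GLV) systems
ẋᵢ = k xᵢ (A x + c)ᵢ with a scenario-specific interaction matrix A and
drive c (`glv_core.linear_forms`). The EEI matrix encodes two excitatory
populations of size N_E reciprocally coupled to an inhibitory population of
size N_I = N_E/2 (the factor 2 on the excitatory rows); g is the IPSP/EPSP
amplitude ratio (default 6), p the probability multiplier for synapses
touching inhibition (default 3), w the within-subnetwork excitatory
strengthening (default 2). The III matrix is the circulant May-Leonard
competition −circ(1, a, b). The drive I and time-scale k default to 1; k
absorbs all network constants that do not appear explicitly, so model time
carries no physical unit and no attempt is made to map it to milliseconds.

Assumptions inherited from the derivation of such rate models: populations
fire asynchronously at low rates, the population transfer function is
approximately exponential (so its logarithmic self-interaction correction
is negligible), and population sizes are large enough that rates behave as
deterministic continuous variables.

## Equilibria and bifurcation structure

A three-dimensional GLV has up to 2³ = 8 on/off equilibrium candidates.
Because the bracketed forms are linear in the active components, each
candidate is obtained by a direct linear solve of A[S,S] x_S = −c_S over
its active set S — exact, no root-finding. Near-singular subsystems
(condition number > 1e12) are flagged `exists=False`: the fixed point
diverges there. Equilibria with negative components are returned but
flagged outside the positive octant; they are unreachable from
non-negative initial conditions and play no dynamical role.

The Jacobian is k (diag(Ax + c) + diag(x) A). Stability labels come from
eigenvalue real-part signs with a hyperbolicity tolerance of 1e−9, which
separates genuine bifurcation loci from roundoff.

At p011 (x₁ = 0) the Jacobian splits into the transverse eigenvalue and an
in-plane 2×2 block with trace T(a) and determinant D(a).
`axis_bifurcation_values` computes T and D symbolically (sympy) from the
package's own linear forms; the eigenvalue pair is (T ± √(T²−4D))/2, and
clearing the square root and denominators of "pair = 0" yields the
polynomial numer(D·denom(T)²), a quartic with positive roots 2/3, √(2/3) ≈
0.816 and 1. The √(2/3) root is where the p011 coordinates themselves
diverge (3a²−2 = 0); it is reported but flagged singular rather than
asserted to be a transcritical point. The degenerate Hopf value is the root
of T = 0 with negative discriminant, a = 6/7 ≈ 0.8571. The transcritical
curve from the transverse eigenvalue is b = (3a²−a−1)/(3a−2) with a pole at
a = 2/3; the p101 branch is its a↔b mirror.

The six-region EEI classifier works on the stability pattern of the three
positive-octant candidates: S = set of stable points among {p001, p011,
p101} and u = unstable dimension of p001. R1: S={p001}; R2/R6: S={p011}
with u=1/2; R3/R4: S={p101} with u=1/2; R5: both stable. This mapping
reproduces all six reference (a, b) assignments and is the only
stability-consistent one. It applies in the region of interest a, b >
6/7 (below it the degenerate Hopf structure takes over); points within
1e−3 of region edges, or with any nonhyperbolic candidate, are labelled
"boundary". Hopf loci are located by sign change of the complex pair's
real part along grid columns plus bisection to |Re λ| < 1e−8, restricted
to the positive-octant branch of p111.

## Numerical integration

Trajectories use an adaptive explicit Runge-Kutta scheme (scipy RK45) with
rtol 1e−9, atol 1e−12. No positivity clamping is applied by default:
near a heteroclinic cycle components legitimately approach machine zero,
and a floor would mimic finite-size noise and alter the period growth; an
optional floor argument exists for experiments. "Converged" means the
field norm stays below 1e−8 over the final 1% of the horizon — attractor
identity, not settling time, is the quantity of interest.

A consequence worth knowing: in the heteroclinic regime the dwell times
near the saddles grow without bound, and once a component underflows double
precision the cycle numerically terminates in the current corner. At
(a, b) = (1.4, 1.0) the corner escape rate is additionally marginal
(1 − b = 0), so only a handful of rotations exist at any numerical
precision; phase measurements therefore use the early, regular rotations
(below).

## Oscillation metrics

Peaks are local maxima of 5-sample moving-average-smoothed traces above
20% of the grand mean rate, with a prominence floor of half that threshold
(rejecting numerical ripple on dwell plateaus) and edge peaks discarded. A
cycle is the interval between successive peaks of one population; within
each cycle the gaps between consecutive peaks of any population, divided
by that cycle's period, give relative phases (×2π). Because the period
grows from cycle to cycle near the heteroclinic, the phase relation is
also reported restricted to "regular" cycles whose period is within 10% of
the shortest observed one; the three-phase rotation value 2π/3 refers to
this regular regime, where the phase concept is well defined.

## Spiking networks

Connectivity: per block pair, every source neuron sends exactly
round(prob × N_target) synapses; in-degrees are equalized to within one
synapse by construction (shuffled stub lists with swap repair), no
self-loops, no multi-edges. Exact out-degrees together with exactly equal
in-degrees is over-constrained in general; the ±1 spread is the
implementation of "identical in-degrees". EEI probabilities are ε = 1/30
within/between excitatory subnetworks and pε = 0.1 for anything touching
inhibition (ε is chosen so pε matches the III probability of 0.1); EEI
per-synapse weights follow the block table wJ, J, ∓g·{a,b}·J, −gJ with
J = 0.09 mV, and III weights are −0.012 mV times the May-Leonard magnitude
pattern circ(1, a, b).

Neurons: τ = 20 ms, threshold 20 mV, reset 10 mV, DC drive 270 pA through
R = 80 MΩ (chosen so the rheobase V_th/R is 250 pA, just below the drive),
no refractory period, delta synapses (instantaneous potential jumps),
transmission delay of one 0.1 ms step, forward-Euler integration at that
step. All neurons crossing threshold in a step spike together and their
spikes act one delay later. The only randomness is connectivity and
initial membrane potentials (uniform: excitatory [0, 15] mV, inhibitory
[0, 17] mV for the default preset; [0, 19] mV for III, a choice made once
since no value is prescribed), both seeded; simulations are bit-exact
reproducible.

Scaled-down simulations use `BlockSpec.scaled(f)`: populations shrink by f
while per-synapse weights grow by 1/f, preserving the population-level
coupling W_mn = τ·prob·N_m·w_syn. Desk-scale validation runs use f = 0.1
(EEI) and f = 0.25 (III) with ~1 s simulated time — large enough for the
steady-state classifier, small enough for a laptop-class budget.

## Classification

Spikes are counted in half-open bins (8 ms EEI, 3 ms III) and normalized
to per-neuron Hz. After discarding the first 100 ms, the EEI steady-state
vector is projected onto (0,0,1), (0,1,1)/√2, (1,0,1)/√2 and the largest
projection wins (ties, which occur only on degenerate inputs, resolve in
that fixed order). The III regime classifier uses thresholds relative to
the grand mean of the nonzero population rates: winner-take-all if exactly
one population exceeds 20% of it while the others sit below 5%;
oscillatory if at least two populations have above-threshold activity
fractions strictly inside (0.1, 0.9) — i.e. they alternate between
dominance and near-silence — and the dominant population changes at least
3 times; coexistence otherwise. Thresholds were set to separate the three
regimes on ground-truth Poisson fixtures and are configurable.

Simulated (a, b) diagrams store a majority label over seeds per node
(1 seed by default) with per-seed labels in the metadata; comparison with
analytic diagrams uses the attractor-identity mapping R1→P001, R2/R6→P011,
R3/R4→P101, R5→either winner, excluding boundary nodes.

## Synthetic spike fixtures

`synthetic_spikes` generates inhomogeneous-Poisson populations whose rate
schedules follow rate-model trajectories of named presets (the six EEI
region presets and the three III regimes), rescaled to a 30 Hz peak —
low-rate, as the exponential-transfer assumption wants — and stretched
onto the requested duration. Sampling is at the population level (per bin,
count ~ Poisson(rate·N·Δ)), which is exact for every downstream statistic
used here and keeps fixtures O(events). These fixtures emulate rate
trajectories with Poisson shot noise only; they do not reproduce LIF
membrane-potential correlations, synchrony, or finite-size rate
fluctuations, so tests passing on them validate the binning/classification
pipeline, not the spiking dynamics themselves.

## Known limitations

- At desk-scale sizes the III spiking network's oscillatory regime does
  not develop: an asymmetric rate kick at (1.4, 1.0) decays within
  ~250 ms at both quarter scale and full 3×4000 size in this simulator.
  Smaller networks have proportionally larger spiking noise, which
  flattens the effective transfer gain; the regime boundary sharpens only
  as N grows. The oscillatory classification is therefore exercised on
  rate-model trajectories and Poisson fixtures, and the spiking validation
  covers the coexistence and winner-take-all regimes (whose finite-size
  onset lies strictly above a = b = 1, moving toward it as N grows).
- Limit-cycle continuation, Floquet multipliers, Lyapunov coefficients and
  homoclinic-connection computations are out of scope; bifurcation loci
  are located by eigenvalue crossings on grids.
- The exponential-transfer constants are absorbed into k; no quantitative
  match of time scales or absolute rates between the rate models and the
  spiking networks is attempted, only attractor/regime identity.
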