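# Methods

## The model

The circuit is a Wilson-Cowan-type population rate model of CA1 with
four populations — pyramidal cells (PYR) and three inhibitory types:
bistratified cells (BiC), PV-expressing basket cells (PV) and
CCK-expressing basket cells (CCK). Each population's mean rate obeys

    α_m⁻¹ dr_m/dt = −r_m + r_{0,m} f(ie_m + Ĩ_m),   f(I) = 1/(1+e^{−βI}),

where the synaptic part Ĩ_m sums w_{n→m}·r_n(t−τ) over the incoming
mask edges plus an external STIM_m. A single lumped delay τ applies to
all rate terms; STIM is instantaneous. Connectivity is fixed at nine
directed edges (three excitatory from PYR, six inhibitory); inhibitory
weights are stored with a negative sign, so the drive is a plain sum
and the weight-search mutation rule "signs never change" is literal.

Default parameters: β = 20 au for all cells, τ = 5 ms,
α = (40, 80, 40, 80) Hz, r0 = (40, 100, 60, 100) Hz,
ie = (0.03, −1.45, 0.8, 0.5) au for (PYR, BiC, CCK, PV). The `beta`
field is per-cell so differential gains can be explored, but all
shipped analyses use the uniform value.

Interpretation of the decoupled milieu: with all weights zero, PYR
fires at ~26 Hz, BiC is silent, CCK and PV fire near their maxima —
the surrounding, unmodeled inputs are absorbed into ie.

## Integration

Explicit Euler with dt = 1 ms, duration 8 s, zero initial conditions
and zero delay history on [−τ, 0); delayed rates are read from a
circular buffer of τ/dt steps (τ must be an integer multiple of dt).
Because α_m·dt ≤ 0.08, the update is a convex step toward a point in
[0, r0], so rates stay in their boxes for all time. STIM protocols are
piecewise-constant and left-closed (a change applies at the first step
with t ≥ t_start). Traces are returned whole; analysis routines drop
the first 1 s transient. The scheme is deliberately plain — no
adaptive or higher-order integrators in the shipped analyses; dt is
varied only in convergence-style checks (see the stability
cross-validation below).

## Spectral quantification

PYR activity is the LFP proxy; theta is 3–12 Hz, gamma 20–100 Hz.
PSDs are Welch periodograms: 2048-sample Hann segments (fs = 1 kHz),
50% overlap, per-segment linear detrend, ~0.49 Hz resolution over the
7 s post-transient record. "Power" always means the PSD value at the
peak grid frequency, not band-integrated power. Theta frequency/power
are read from the PYR periodogram. Because harmonics of the strong PYR
theta can exceed PYR's own gamma peak, the gamma frequency is located
on the PV periodogram and the PYR PSD is read at that grid frequency.
Ties in a band argmax resolve toward the lower frequency.

Two distinct references exist and are never conflated: the GA's primary
constraint compares candidate powers to the reference set's baseline
powers at the 60% level, while the experiment battery judges
"sufficient" theta-gamma coexpression against the mean baseline powers
of the study ensemble at the 25% level (boundary inclusive in both).

## Reference weight set

The shipped reference set is a hand-tuned anchor standing in for a
published parameterization that is not redistributable. It was
constructed in two stages. First, the theta loop (PYR→PYR, PYR→BiC,
BiC→PYR) was solved from the linear stability analysis: prescribing
the PYR+BiC equilibrium (x1*, x2*) and the self-excitation coupling
γ11 determines the three weights in closed form (via f⁻¹), and a grid
over (x1*, x2*, γ11) was screened for a theta-band Hopf root with a
small first bifurcation delay and accurate analysis/simulation
cross-validation. The equilibrium must sit just below PYR saturation:
fully saturated equilibria have vanishing effective gain and no
oscillatory root. Second, the six gamma-side weights were selected by
randomized search so that the CCK+PV and PYR+PV motifs carry gamma-band
roots, the full circuit passes every constraint, and the CCK
perturbation protocols behave as described below. `make_reference_set`
re-validates the anchor from scratch; regeneration is deterministic and
byte-identical.

## Genetic-algorithm search

Mutate-and-filter, no crossover. A parent is drawn uniformly from the
accepted pool; n ~ Poisson(2) weights are mutated (n redrawn until
≥ 1 — a zero-mutation child is a duplicate and wastes an evaluation),
each multiplied by an independent Uniform(0.1, 2) factor. Edges are
selected by sampling ordered integer pairs under the coding 0=PYR,
1=BiC, 2=PV, 3=CCK, rejecting pairs that are not circuit connections
and duplicates within one mutation. Constraints: at baseline, PYR theta
and gamma peak powers ≥ 60% of the reference baseline, max-rate ratio
PV/BiC ≥ 0.67 (a BiC max below 1 µHz marks the ratio undefined and
fails), CCK max rate > 4 Hz; and each of the four critical removals
(PYR→PYR, CCK→PV, PV→PYR, BiC→PYR) must leave PYR theta power < 10% of
the reference baseline. The search stops at the target count (library
default 200; tests and the acceptance script run a scaled-down 20) or
at the evaluation budget, returning a flagged partial pool in the
latter case.

Degeneracy clustering: k-means on the raw 9-dimensional weight vectors,
k chosen by maximum mean silhouette over k ∈ [2, 20] (capped at the
number of distinct vectors and n−1); pools too small for silhouette
selection fall back to one cluster per distinct vector. Clusters are
retained only if some member's PV/BiC ratio reaches 0.70; medoids of
retained clusters (by size, at most 10) are the representatives. For
scaled-down pools that collapse to fewer than five clusters,
`select_study_sets` pads the ensemble with accepted sets chosen by
max-min distance in weight space, so cross-set statistics always run
on ≥ 5 sets without altering the clustering.

## Linear stability analysis

The circuit decomposes into three independent two-cell motifs:
PYR+BiC (drops PV→PYR), PYR+PV (drops BiC→PYR and CCK→PV) and CCK+PV
(drops PYR→PV). For each motif the equilibrium is found by nested
one-dimensional root solving (the second cell's nullcline is unique
because its self-coupling is non-positive); a damped fixed-point
iteration from the decoupled state is also provided. Linearizing with
s_i = x_i*(1 − x_i*/r_i) gives delayed couplings γ_ij = β w_ij s_i;
motifs whose second cell has a self-connection contribute a γ22 on the
diagonal exactly as γ11 does for the first cell. Substituting
λ = iω into the characteristic equation and multiplying by e^{λτ}
yields two linear equations in cos(ωτ), sin(ωτ) with coefficients
κ1…κ6; solving them gives sin(ωτ) = G1(ω), cos(ωτ) = G2(ω), and the
identity G1² + G2² = 1 pins the Hopf frequency. Critical delays are
τ_k = (θ + 2kπ)/ω with θ = atan2(G1, G2) mod 2π — the atan2 branch
satisfies both the sine and cosine conditions simultaneously, where an
arcsin alone can land on the wrong branch. Roots are bracketed on a
geometric scan of ω/2π ∈ (0, 200] Hz (configurable) and polished by
bisection to near machine precision; when several equilibria or roots
exist, the root with the smallest positive τ_0 is reported, with
normalized characteristic residuals ≤ 1e−6.

Frequency at a given delay: G1² + G2² = 1 has discrete roots, so a
frequency-vs-delay curve cannot come from re-solving the root per τ.
Instead the critical-delay relation is read parametrically — sweeping ω
along the continuous phase branch through the Hopf root and plotting
(τ_0(ω), ω) — and inverted at the requested delay. The branch is
restricted to the window where |(G1, G2)| ≥ 0.05; outside it the phase
degenerates to the uncoupled system's and produces spurious crossings.
This curve approximates the frequency the motif expresses at delay τ;
the β sweep re-solves the genuine root per gain, the τ sweep evaluates
this curve. The default τ grid is 3–8 ms around the 5 ms working point.

Analysis/simulation cross-validation runs each motif at τ = 0.5·τ_0
(expect decay: amplitude halves between consecutive 1 s windows or
vanishes) and τ = 1.5·τ_0 (expect sustained oscillation within 20% of
the curve's frequency at that delay). These runs use dt = τ/8: at the
small critical delays of the theta motif a one-step delay buffer
biases Euler's effective delay enough to distort the frequency
comparison, and eight steps per delay removes that bias while keeping
the same scheme.

## Perturbation experiments

STIM sweeps apply a constant input to one cell over an equally spaced
grid on [−2, 2] (121 points at full scale; the shipped acceptance runs
use 81 to keep runtimes in minutes). At each point theta power, gamma
power and theta frequency are extracted; ordinary least-squares slopes
against STIM use only sufficient points and are reported only when at
least five exist. The sufficient-STIM range is (min, max) of the
sufficient grid values. The milieu scan applies the same STIM to all
four cells and reports both the union and the intersection of the
per-set sufficient ranges (the appropriate combination across sets is
ambiguous, so both are kept).

CCK protocols (8 s runs; verdicts on windows that drop 1 s after any
STIM switch): (a) STIM_CCK = −1 from t = 4 s — outcome set-dependent;
(b) STIM_CCK = −1 throughout — expresses no coupling, because from the
quiescent initial state CCK is needed to disinhibit the circuit;
(c) STIM_CCK = −1 from the start, then +0.25 for 250 ms at t = 4 s,
then 0 — the burst initiates coupling, and the first post-burst CCK
peak precedes the first PV peak; (d) STIM_CCK = +20 from t = 4 s —
saturated CCK silences PV and the coupled rhythms collapse. The burst
length (250 ms ≈ one-two theta cycles) is a package choice; it is
configurable.

Regularity: a 10 s run with STIM_CCK = −1 applied at t = 5 s; PYR and
BiC peaks are detected in the CCK-on window [1, 5] s and CCK-off
window [6, 10] s with prominence ≥ 10% of the window's amplitude range
and ≥ 20 ms separation (rejecting gamma ripples riding on theta
peaks), and mean/median/std of peak amplitudes and inter-peak
intervals are reported; windows with < 3 peaks are flagged unreliable.

## Problem sizes in the shipped analyses

Baseline and constraint simulations: 8 s at dt = 1 ms. GA: target 20
accepted sets (library default 200), evaluation budget 100 000. Sweeps
in the acceptance script: 81-point grids across 5 study sets; milieu
scan: 41 points across 2 sets. These sizes are the package's default
study scale; all entry points accept larger grids and pools.

## What the generated data do and do not show

All experiments run on the model's own simulated traces — there is no
external data and no noise source; the integration is deterministic.
Passing tests therefore demonstrate internal consistency of the model,
analysis and search machinery (closed forms, linearization against
finite differences, analysis against simulation, constraint
re-validation), not agreement with any recorded hippocampal signal.
The reference set is a package-constructed parameterization consistent
with the qualitative constraints above, not a published table; emergent
quantities that depend on the specific published weight values — most
visibly the ordering of sufficient-STIM range widths across cell types
and the exact milieu-range endpoints — are reported as measured on the
package's own ensemble.

## Known limitations

- No synaptic time-constant state variables, conductances or spiking;
  the delay lumps synaptic and axonal latencies into one τ.
- The LFP proxy is the PYR rate alone; no cross-frequency-coupling
  metrics are computed on it.
- The stability analysis covers the three 2-D motifs only, not the full
  four-dimensional characteristic equation, and the frequency-at-delay
  curve is a first-order (critical-manifold) approximation that
  degrades far from the bifurcation.
- The theta motif's oscillation is strongly relaxational; its simulated
  frequency runs below the linear prediction as the delay moves past
  the bifurcation, which is why the cross-validation tolerance is 20%.
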