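# Methods

## Neuron model

The model is a single-compartment, modified Morris–Lecar neuron.  Five
currents flow across the membrane: an instantaneously activating sodium
current (gate `m`, always at steady state), a delayed-rectifier
potassium current (gate `w`), a leak current, a low-threshold
non-inactivating Kv1-type potassium current (gate `z`, density
`gbar_Klt`), and an inactivating A-type potassium current (activation
`a` to the fourth power times inactivation `b`, density `gbar_KA`).
The two added potassium densities are the free parameters of every
analysis in the package; everything else is held at the default
constants (`C` = 2 µF/cm², `E_Na` = 50 mV, `E_K` = −100 mV,
`E_leak` = −70 mV, `gbar_Na` = `gbar_Kdr` = 20 mS/cm²,
`gbar_leak` = 2 mS/cm², `φ_w` = `φ_z` = 0.15, `φ_a` = `φ_b` = 1,
`β_m` = −1.2 mV, `β_w` = −10 mV, `β_z` = −21 mV, `γ_m` = 18 mV,
`γ_w` = 10 mV, `γ_z` = 15 mV).

`m`, `w` and `z` use the Morris–Lecar `0.5(1 + tanh((V−β)/γ))` steady
state with `1/cosh((V−β)/2γ)` time constants; the A-type gates use
Boltzmann steady states (`a`: half-activation −60 mV, slope 8.5 mV;
`b`: half-inactivation −78 mV, slope 6 mV) with double-exponential
voltage-dependent time constants.  `τ_b` is the constant 19 ms above
−63 mV; the boundary point V = −63 mV is assigned to the
double-exponential branch (a measure-zero choice that we document
rather than hide — the function is discontinuous there either way).

At the resting potential (≈ −70 mV) the A-type inactivation gate sits
near b ≈ 0.21, so only a fraction of `g_K,A` is available; a
depolarizing subthreshold pre-pulse further inactivates it.  This is
the mechanism by which pre-stimulus membrane potential re-scales the
effective A-conductance axis of the pattern map.

### Integration and protocol

Equations are integrated with forward Euler at dt = 0.1 ms, matching
the numerical scheme under which the spiking-pattern boundaries are
defined.  This matters: the boundary positions in the conductance plane
are properties of the discretized system, and we verified that halving
dt leaves the five canonical pattern classifications unchanged but
shifts boundary positions slightly (see "Known limitations").  The
protocol is a 250 ms settle phase (current `I_pre`, default 0) followed
by a 400 ms stimulus (`I_pre + I_stim`).  The state is initialized at
V = E_leak with gates at steady state; the settle phase makes results
insensitive to this choice.  `I_pre` stays on during the stimulus, and
the pre-stimulus potential is reported as V at the last settle step.

The sweep engine (`sdhspike.sweep`) advances all grid points of a map
in lock-step as NumPy arrays.  Its per-step arithmetic is identical to
the scalar integrator — the test suite asserts spike-level agreement —
and it records only what classification needs: the spike count and the
first three spike times.

## Spike detection and classification

Spikes are upward crossings of a 0 mV threshold within the stimulus
window, with crossing times linearly interpolated between steps.  After
a spike, the trace must fall back below a reset level (default: the
threshold) before the next spike can register; for clean simulated
traces this hysteresis is inert, but it guards recorded traces against
double counting.  The threshold is configurable; model spikes overshoot
+30 mV and subthreshold oscillations stay below −25 mV across the
mapped domain, so the classification is insensitive to thresholds in
the −20…+10 mV range.

The five-way rule, applied in order: no spikes → reluctant; one spike
with first-spike latency > 100 ms → delayed; one spike → single; ≥ 3
spikes with (t₂−t₁) > 1.5(t₃−t₂) → gap; ≥ 2 spikes with
t₁ > 1.5(t₂−t₁) → delayed; otherwise tonic.  Two interpretation
choices were open and are fixed as follows: the gap test precedes the
delayed test for trains satisfying both, and two-spike trains cannot be
gap (the rule needs a second ISI), leaving them delayed or tonic.
Latency is measured from stimulus onset.

## Pattern maps

A map evaluates the model at every node of a regular conductance grid
(default 0–20 mS/cm² on both axes, 0.1 mS/cm² step, 201 × 201 nodes)
and stores one label per node.  Labels are point evaluations, not cell
averages; off-grid queries use nearest-node lookup.  Maps are
deterministic, independent of evaluation order, and serialized as a
CSV label matrix (rows = g_K,A, columns = g_K,lt, codes
reluctant = 1 … tonic = 5) with a JSON header; `load_or_build_map`
caches them keyed by a hash of (grid, protocol, parameters).

At I_stim = 60 µA/cm² the five regions arrange as: tonic in the
low-`g_K,lt`/low-`g_K,A` corner, single at high `g_K,lt`/low `g_K,A`,
delayed at low `g_K,lt`/high `g_K,A`, reluctant at high/high, and gap
between tonic and delayed.  Region centroids are the unweighted means
of node coordinates.

## Single-neuron inference

The set of (g_K,lt, g_K,A) consistent with an observed pattern sequence
is the intersection, across stimulus intensities, of the label regions
matching each observation (default test set 50–80 µA/cm² in 5 µA/cm²
steps).  The result is a point set, not a distribution: the package
offers a bounding box as convenience output but no posterior.  Missing
maps raise rather than interpolate, since labels are categorical and
interpolation across planes is undefined.

## Population forward model

Channel densities across a population follow a bivariate normal with
means (μ_K,lt, μ_K,A), standard deviations (σ_K,lt, σ_K,A) and
correlation ρ.  The expected proportion of pattern *i* is the
distribution's volume over region R_i, computed by 2-D trapezoidal
quadrature on the map grid (optionally a finer sub-grid with
nearest-node labels).  The five volumes sum exactly to the total
integrated mass ("coverage"); proportions are reported unrenormalized
next to the coverage, because treating the volumes as proportions is
only valid when the distribution sits well inside the domain (coverage
≈ 1).  For the reference populations (μ = (3, 4), σ = (1, 1)) the
coverage is 0.9986 — about 0.1% of mass lies at negative conductances
outside the domain.  Refining the quadrature step from 0.1 to
0.05 mS/cm² moves each reference volume by < 0.005.

Finite-sample proportions (`sample_population`) draw n neurons from the
BND with a seeded generator and count nearest-node labels; out-of-domain
samples take the nearest edge node so counts always sum to n (for the
reference populations this affects < 0.1% of draws).

## Population inverse model

The fit alternates two steps from a deliberately uninformative start
(centre of the plane, ρ = 0):

1. **ρ scan.**  MaxError — the largest |V_target,i − V_calc,i| — is
   evaluated for ρ from −0.9 to 0.9 in 0.1 steps.  If the best value is
   below δ = 0.001 the fit ends; if below ε = 0.003 the scan repeats at
   0.01 resolution from −0.99 to 0.99.  Ties are broken toward the
   incumbent ρ, then toward smaller |ρ|, with a 10⁻¹² tie band so that
   numerically indistinguishable candidates (e.g. while the
   distribution still sits wholly inside one region) cannot drag ρ
   around.
2. **Centre update.**  M ← M + Σ_i E_i·(C_i − M)/|C_i − M|, pulling
   the distribution toward under-predicted regions and away from
   over-predicted ones.  Empty regions with nonzero error are skipped
   with a warning.

Iteration stops below δ, when the centre dynamics stop making progress
— displacement below 10⁻⁴ mS/cm², or a 2-cycle in which the centre
returns to within that tolerance of its position two iterations back
(both operationalize "converged on a point"; one final ρ scan is then
run at the settled centre) — or at a 200-iteration guard.
Non-convergence is reported through the result status and per-iteration
history, never as an exception.  Fits are deterministic.

σ is not fitted directly (a σ step makes the iteration far slower and
less stable); instead the whole fit is re-run over a σ grid — default
0.4–1.6 mS/cm² at 0.05 steps on both axes, with a coarser 0.1-step
variant used for the larger recovery experiments — and the pair with
the lowest final MaxError wins, ties resolved by row-major grid order.
The σ search is embarrassingly parallel; the implementation batches all
pairs through one vectorized quadrature kernel (results are identical
to fitting each pair separately, which the tests assert on a collapsed
grid).  Quadrature inside the fit is windowed to ±6σ around the
current centre; the neglected mass (~10⁻⁹) is a million-fold below the
10⁻³ error resolution of the fit.

### Identifiability and known failure modes

Two distinct failure modes of the inverse problem are worth separating,
because the test suite deliberately exposes both:

* **Non-identifiability away from the region junction.**  When the
  distribution's mass straddles only one boundary (e.g. μ_K,A ≳ 7,
  where only the delayed and reluctant regions carry mass), many
  (μ, ρ, σ) combinations reproduce the same proportion vector to
  within 10⁻⁴.  The fit then converges to *a* solution, not *the*
  generating one — recovered μ_K,A and ρ can be arbitrarily wrong while
  MaxError is essentially zero.  No algorithm could do better from
  proportions alone; the information is not in the data.
* **Local attractors of the centroid-vector dynamics.**  The joint
  (centre, ρ) iteration can settle at points where the error-scaled
  vectors cancel with MaxError in the 0.003–0.01 range, especially when
  the assumed σ is wrong; the coarse 0.1-step ρ grid then never refines
  (refinement requires MaxError < ε).  In a σ search, a mismatched σ
  pair that happens to converge below δ with compensating (μ, ρ) can
  therefore beat the true σ pair that stalled in such an attractor.

For populations near the multi-region junction with σ close to 1 —
the regime the method was designed for — the fit is accurate and
stable: the three reference populations are recovered to ±0.003 in μ
and ±0.01 in ρ with MaxError < 0.001.  The parameter-recovery test
draws uniformly from μ_K,lt ∈ [1.5, 6], μ_K,A ∈ [2, 8], ρ ∈ [−0.8, 0.8],
σ ∈ [0.4, 1.6], which includes weakly identified corners; its strict
per-draw bounds (±0.2 on μ and ρ, one σ grid step) therefore fail for
a minority of draws, and the test documents rather than hides this.
That experiment uses the 0.1-step σ grid and a 60-iteration cap as its
scaled-down configuration (convergent fits finish well under 50
iterations; the cap only truncates oscillating non-convergent runs).

## What the synthetic populations do and do not emulate

Targets for the inverse fit are generated by the package's own forward
model (analytic volumes, or seeded finite samples via
`sample_population`).  This emulates the self-consistency experiments
of the study: same map, same quadrature, no model mismatch.  Passing
recovery tests therefore demonstrates properties of the *algorithm*,
not of real recordings: real SDH populations vary in conductances the
map holds fixed (leak, Na⁺, delayed-rectifier densities), express
channels the model omits, and their measured proportions carry
finite-sample noise — all of which blur the region boundaries and
degrade recovery below what these tests show.

## Numerical choices at a glance

| quantity | value | note |
| --- | --- | --- |
| Euler step dt | 0.1 ms | boundaries are defined under this scheme |
| settle / stimulus | 250 / 400 ms | spikes counted only during stimulus |
| spike threshold | 0 mV | insensitive over −20…+10 mV |
| map grid | 0–20 mS/cm², step 0.1 | labels are node evaluations |
| quadrature | trapezoid on map grid | refinement changes volumes < 0.005 |
| δ, ε | 0.001, 0.003 | stop / ρ-refinement thresholds |
| ρ grids | 0.1 coarse, 0.01 fine | fine scan only below ε |
| centre tolerance | 10⁻⁴ mS/cm² | "converged on a point" |
| σ grid | 0.4–1.6, step 0.05 (0.1 for large sweeps) | lowest MaxError wins |
| fit window | ±6σ | truncation error (~10⁻⁹) ≪ δ |
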