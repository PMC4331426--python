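# Methods

## Model

The core model is a one-dimensional, activity-based neural field with
linear adaptation:

    u_t(x,t) = −α u + α H( (w⊗u)(x) + P(x,t) − k ) − α β₀ q
    q_t(x,t) = δ u − δ q
    (w⊗u)(x) = (1/2σ) ∫ e^{−|x−y|/σ} u(y) dy.

u(x,t) is the dimensionless deviation of mean synaptic activity from its
baseline (negative values are a depression of resting activity), q(x,t)
a slow homeostatic adaptation, P an external input, H the Heaviside step.
The activity-based formulation ties the state variable's timescale to
synaptic decay, which is the timescale believed to dominate the LFP.
Internal units are milliseconds and microns throughout; constructors
accept rates in 1/s and divide by 1000 at the boundary. We write
β = α β₀ for the adaptation rate that enters the traveling-frame algebra.

An excitatory–inhibitory extension adds a second population v with its
own rate α_i and threshold k_i, coupled through four exponential kernels
σ_jk gated by binary couplings ḡ_jk; with all cross-couplings off it
reduces *exactly* (same code path, bit-for-bit) to the single-population
model. A model variant moves the adaptation term inside the firing
nonlinearity (as −β₀q in the Heaviside argument); its wake returns to
rest monotonically, with no reverberation — verified as a property test.

### Parameters

| symbol | meaning | units | typical |
|---|---|---|---|
| α | synaptic activity decay rate | 1/ms | 0.0075–0.025 (7.5–25/s) |
| δ | adaptation decay rate | 1/ms | α/10 |
| β₀ | adaptation strength (β = αβ₀) | — | 1.5–5 |
| σ | connectivity decay length | μm | 50–200 |
| k | synaptic input threshold | — | 0.1–0.3 |
| c, w | pulse speed and width (solution features, not model inputs) | μm/ms, μm | — |

## Closed-form traveling pulses

In the frame z = x − ct (c > 0, rightward) a pulse crosses threshold at
exactly two points, taken as z = 0 (trailing) and z = w (leading), with
the Heaviside equal to 1 on (0, w). On each piece the system is linear
with matrix A = [[α, β], [−δ, δ]]/c, whose eigenvalues are

    λ± = [α + δ ± √((α+δ)² − 4δ(α+β))] / (2c),

both with positive real part. Boundedness forces u ≡ 0 ahead of the
pulse; continuity of (u, q) at both edges fixes every coefficient. The
discriminant 4δβ − (α−δ)² splits two families:

- **real regime** (negative): biexponential wake, monotone return to rest
  after a depression;
- **complex regime** (positive): wake ∝ e^{fz}·sin(rz/2c + φ) with
  f = (α+δ)/2c and r = √(4δβ − (α−δ)²); the damped oscillation's first
  positive lobe is the model's reverberation, with temporal period 4π/r.

Both printed-style closed forms (the real-case λ± expression and the
complex-case amplitude/phase form with D, φ₁, φ₂, A₁–A₄ and the raw
sinusoid coefficients c₁–c₄) are implemented and verified to machine
precision against an independent eigenbasis construction, and to 1e-6
against high-order backward integration of the frame ODEs (an
ODE-shooting oracle that never touches the closed forms). The phases use
quadrant-aware arctangents (φ = atan2(A₁, A₂), atan2(A₃, A₄)); the
amplitude factor is D = √(1 − 2e^{−fw}cos(rw/2c) + e^{−2fw}). A
discriminant within 1e-14 /ms² of zero (critical damping) is refused
with an explicit error rather than classified: no closed-form family
applies there.

The reverberation inversion
β_empirical = (δ−α)²/(4δ) + 4π²/(τ²δ) is the exact algebraic inverse of
the damped period (round-trips to 1e-10) and always lands strictly in
the complex regime. With δ = α/10 fixed, β₀ = β_empirical/α converges to
81/40 = 2.025 as α grows.

## Matching conditions and inverse problems

A candidate (c, w) is an actual wave only if the synaptic input
(1/2σ)∫e^{−|x−y|/σ}u(y)dy equals k at **both** x = 0 and x = w. Because
the profile is a piecewise sum of complex exponentials, both threshold
values have exact closed forms; we evaluate them by term-by-term
integration of the profile against the kernel, arranged so that every
exponential that appears is decaying. This is algebraically identical to
the direct textbook expressions but immune to the catastrophic
cancellation those suffer near the regime boundary. The implementation
is pinned to an adaptive-quadrature oracle at 1e-8 relative over
hundreds of random parameter sets (both regimes), and to the compact
closed form for the leading-edge threshold at 1e-12.

Inverse problems, all built on this primitive:

- **Existence diagram** `solve_cw_intersections`: intersections of the
  two level curves k₁(c,w) = k and k₂(c,w) = k, found by damped Newton in
  (log c, log w) seeded from a 40×40 log-spaced grid (default
  c ∈ [1, 3000] μm/ms, w ∈ [10, 10⁴] μm), residual-checked at 1e-8 and
  deduplicated at 0.1% relative distance. Zero, one or two intersections
  arise; with two, one wave is slow and narrow and the other fast and
  wide (asserted as an invariant).
- **Anchoring** `anchor_and_find_second_wave`: when k is unknown but one
  wave on the curve is, k is set to the mean of the two thresholds at
  the anchor; the anchor must lie on the existence curve within 5% or
  the operation refuses (reporting both values). A relaxed mode
  proceeds diagnostically with the mean.
- **(σ, β) solution curve** `solve_sigma_beta_curve`: for fixed
  (c, w, α, δ), Brent root-finding of k₁ = k₂ in β along a σ grid;
  sigmas with no bracketed root are recorded as gaps. On genuine waves
  the curve contains both real- and complex-regime segments and β falls
  as σ grows.
- **Feasibility sweep** `feasibility_sweep`: per observed wave
  (c, w, τ) and per α (with δ = α/ratio), β comes from the reverberation
  inversion and σ from the matching equality; a wave is feasible iff
  some solved σ exceeds 20 μm (a connectivity extent below one cortical
  column is treated as unphysical). Unsolvable waves count as
  infeasible.

### A structural caveat on fast waves

The two thresholds are strongly asymmetric for fast, wide pulses: the
trailing value exceeds the leading one by large factors because the
activity peaks at the trailing edge while the leading edge sees only the
slowly rising front (the leading-edge condition alone reduces, for
fronts, to c = ασ(1−2k)/(2k)). As a consequence the existence locus
k₁ = k₂ is confined to speeds of order ασ — a few μm/ms at
physiological α and σ — and inverse problems posed at much faster target
waves (e.g. c ≳ 100 μm/ms with σ ≲ 200 μm and k ≈ 0.15) have **no
solution**: the σ–β solve returns gaps and the feasibility sweep returns
0%. This is a property of the model itself, triple-checked here
(closed forms ≡ quadrature ≡ direct simulation: emergent simulated waves
satisfy the leading-edge condition to ~3% everywhere, and both
conditions on the locus). The package therefore validates its inverse
machinery on self-consistent on-locus configurations, and the
acceptance script reports what the model actually produces at the
requested parameter values.

## Simulation

RK4 with Δt = 0.005 ms on a regular grid (default 2000 nodes,
Δx = 40 μm). The kernel convolution treats activity as constant within
each cell and uses the exact cell integrals of the kernel as weights;
it is evaluated either via FFT (public array operation) or as two O(n)
recursive exponential passes (inside the fused, numba-compiled
integrator); both match a direct O(n²) summation to 1e-12. σ = 0 is the
delta-kernel limit (identity). Boundaries are zero-padded; measurements
are restricted to the middle half of the domain and a domain-exit
warning fires if suprathreshold drive reaches the far edge. The
integrator is deterministic and raises a divergence alarm (naming node
and time) if |u| leaves [−2, 2] or becomes non-finite.

**Ignition.** Because the firing nonlinearity is a step, input amplitude
does not change the growth rate: during stimulation u rises as
1 − e^{−αt}, so a threshold k needs duration > −ln(1−k)/α. The package's
wave-initiation preset therefore uses a 25–60 ms, 400 μm input (rather
than a 5 ms, one-cell one, which cannot ignite at typical thresholds).
Ignition details do not affect the emergent wave.

**Measurement rules** (`measure_sim_features`): speed is the inverse
slope of the per-node first crossing times of the suprathreshold drive
against position over the middle half of the domain; width is the length
of the contiguous suprathreshold-drive interval at the snapshot whose
support midpoint is nearest the domain center (the quantity the analytic
w is defined by); the reverberation time applies the z-score pipeline's
rule to the activity at the center node with a threshold of 0.1 of the
peak. A front (active region with no trailing closure; behind the
interface u stays near the excited state) is flagged instead of being
assigned a width.

**Stability probing** (`probe_stability`): the simulator is initialized
with the analytic (u, q) pulse of a branch plus a smooth 1% perturbation
and integrated for three transit times (at least 150 ms); "persists"
means measured speed and width stay within 10% of the analytic values,
"collapses" that the activity dies or leaves the branch by more than
50%, anything else "indeterminate". On a two-branch configuration the
fast/wide wave persists and the slow/narrow one collapses; consistently,
simulations ignited from rest converge onto the fast/wide branch, and
refining (Δx, Δt) twice shrinks the sup-norm distance to the closed form
monotonically.

## LFP pipeline

Faithful to the clinical procedure: 2–50 Hz fourth-order Butterworth,
zero-phase (sosfiltfilt), polyphase resampling to 5 kHz, per-channel
z-scores over the full analysis window (making every output invariant to
channel gain). Gradients are central differences between adjacent
electrodes (400 μm pitch); histograms over 36 bins of 10° are weighted
by gradient magnitude. Events are timed by the center signal (mean of
the four central electrodes) crossing z = 2.5 upward, merged within a
50 ms refractory gap; the direction θ₀ is the histogram peak of the
descent direction (−∇V, which points from the approaching crest into the
quiescent tissue, i.e. along propagation for crest-led waves);
(t_initial, t_final) bracket the interval during which the ±20° windows
around θ₀ and θ₀+180° hold at least 25% of the gradient weight. Paths
are the grid-parallel electrode lines (axis or diagonal family, diagonal
step 400√2 μm) nearest θ₀; masked channels split lines, pieces shorter
than 6 electrodes are dropped and shorter than 10 flagged incomplete.
Speed is the median of the 45 pairwise onset-delay estimates per path
(onset: first crossing of z = 1 in the event window; paths with fewer
than 6 onsets are rejected); width is the distance from the last
electrode (the one reached last) to the first electrode below z = 2.5 at
the moment the last electrode first crosses, saturating at the path
extent with a lower-bound flag; the reverberation time follows the
0.5 z down–up–down rule per electrode with a 500 ms horizon. Wave-level
summaries are means across paths with 90% confidence intervals
mean ± t₀.₉₅,ₙ₋₁·s/√n; a single path leaves the interval undefined.

One deliberate robustness addition: all threshold reads are taken on a
5 ms boxcar-smoothed view of the z-scores. At 5 kHz, unsmoothed unit
noise crosses the 0.5 and 1.0 thresholds almost surely within any
window, making the raw rules unusable on realistic noise; 5 ms of
averaging suppresses these sample-level crossings without moving the
crossing times of 2–50 Hz signal content. The smoothing window is a
parameter (`smooth_ms`) on every estimator.

## Synthetic data

`synth_plane_wave_recording` renders, per electrode, a template delayed
by the projection of the electrode position onto the propagation
direction divided by the speed, plus i.i.d. Gaussian noise (default
unit SD; the default crest amplitude of 4 z gives SNR 4). The template
mimics the complex-regime pulse morphology: a flat-top crest whose
extent **above the 2.5 z detection threshold** equals width/speed (this
is the quantity the width rule measures), a trailing depression of 0.3×
the crest, and a positive reverberation lobe of 0.2× the crest timed so
that the 0.5 z rule recovers the requested τ. The template gain is
pre-compensated for the self-inflation of the z-score normalization
(the wave contributes to its own window SD). Ground truth is embedded
in the recording metadata and round-trips through HDF5.

What the generator does *not* model: electrode drift, line noise, spike
waveforms, spatially correlated noise, waveform variability across
electrodes, curvature of the wavefront, or two-dimensional patterns
(spirals, center-out waves). Passing recovery tests therefore
demonstrates correctness of the pipeline's logic under the plane-wave
assumption, not robustness to every artifact of clinical recordings.
Recovery on 20 seeded replicates across speeds 80–400 μm/ms, widths
1.9–5.6 mm and τ 30–150 ms at SNR ≥ 5 is within 10% (speed), 15% or a
correct lower-bound flag (width), 20% (τ) and ±20° (direction).

`synth_from_simulation` bridges the model and the pipeline by sampling a
1-D simulated field onto the array along a chosen direction. For
simulated morphologies with deep wakes the onset gradient peak can point
opposite to travel (the depression flank dominates), so direction
comparisons for such embeddings are made modulo 180°.

## Numerical choices and degenerate inputs

- Discriminant exactly zero → `CriticalDampingError`; regime-specific
  evaluators raise `RegimeMismatchError` on the wrong family.
- Threshold evaluation uses only decaying exponentials; near-degenerate
  exponent s → 0 in the interior integrals switches to the s·w → 0
  limit below 1e-9.
- Newton seeds are ranked by coarse residual and capped (250) for
  speed; roots outside twice the search box are discarded.
- The Brent solves use brackets from sign changes on log-spaced scans
  (240 points in β, 120 in σ); multiple roots per σ are all kept.
- Problem sizes in tests and the acceptance script (320–1500 nodes,
  2.3–3.9 s of model time) are chosen so every measured wave crosses
  the middle half of its domain with at least 10 pulse widths of room;
  the reference Δt = 0.005 ms and Δx = 40 μm are kept for all headline
  runs, with coarser grids only in refinement studies and long
  stability probes.

## Known limitations

- The two-crossing pulse ansatz assumes the suprathreshold set is a
  single interval. In the complex regime the reverberation lobe can
  re-cross threshold and re-ignite activity behind the wave; emergent
  waves then satisfy the leading-edge condition but not the trailing
  one, and the measured "width" of the leading interval breathes over
  time. The real regime is free of this effect.
- Thresholds below the active-state equilibrium 1/(1+β₀) produce
  fronts, not pulses (flagged, never assigned a width).
- Stability is probed by direct perturbation, not by spectral analysis
  of the linearized operator; "indeterminate" outcomes are possible
  near branch folds.
- The pipeline handles one dominant plane wave per event window;
  overlapping waves from different directions are reported as separate
  events only if separated by the refractory gap.
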