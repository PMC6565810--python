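# Methods

This note records the models, estimators and numerical choices behind
`neomode`, in the package's own terms: what is computed, under which
assumptions, and what the synthetic experiments do and do not establish.

## The generative model

Cortical activity is modelled as a stationary superposition of surface
eigenmodes,

    Y(r, t) = Σⱼ aⱼ mⱼ(r) cos(2πνt) cos(2πωt) + σ η(r, t),

with carrier frequency ω = 10 Hz (alpha band), amplitude-modulation
frequency ν = 0.1 Hz, record length 300 s at 100 Hz, and spatiotemporal
Gaussian white noise of SD σ. Each modulated mode is a beat — a pair of
half-amplitude spectral lines at ω ± ν — so the model is stationary; no
neural-field dynamics are integrated, and the eigenfrequencies that a
dispersion relation would attach to each mode are carried as metadata only.
ν and ω are ordinary frequencies in Hz (`cos(2πνt)`), fixed by their stated
values.

The spatial basis solves the Helmholtz problem `∇²mⱼ = −kⱼ²mⱼ` with the
Laplace–Beltrami operator of a triangular surface mesh, discretized by
linear finite elements: cotangent stiffness and lumped (barycentric) mass,
solved as the generalized symmetric eigenproblem `K m = k² M m` in
shift-invert mode around −10⁻⁸ (the stiffness is singular at k² = 0) with a
fixed Lanczos start vector for determinism. Eigenvectors are
mass-orthonormalized and given a fixed sign (largest-magnitude entry
positive, ties broken by lowest vertex index). Validation is against the
analytic sphere spectrum k² = l(l+1)/R² with multiplicities 2l+1; tests on
degenerate clusters assert eigenvalues and subspaces, never individual
vectors, because within-cluster rotations are arbitrary.

**Mode scaling.** For simulation the modes are rescaled to unit RMS over
the surface (multiplying the mass-orthonormal modes by √area), so the
first mode is the constant 1 and mode weights aⱼ are signal amplitudes in
noise-SD units.

**Noise convention.** The white-noise field is defined at the resolution of
the analysis: one unit-SD process per parcel. Averaging vertex-level i.i.d.
noise over parcels would shrink the noise floor with every mesh refinement —
a discretization artifact, not physics — and would silently move the
operating point of the whole pipeline. With unit parcel noise the
admissible weight range a′ ∈ [0, 0.5] maps exactly onto the informative
part of the envelope-coupling response (couplings ~0 to ~0.15). The literal
vertex-averaged projection remains available
(`parcel_noise_scale(vertex_averaged=True)`).

Because parcels are disjoint, the parcel-level simulation
(`simulate_parcel_timeseries`) is distributionally exact with respect to
simulating the vertex field and projecting through the area-weighted parcel
means; the vertex-level `simulate_field` exists for spectral and spatial
checks.

## Signal processing

Band-pass filtering is a high-pass/low-pass Butterworth cascade, each
filter at the smallest order reaching 20 dB at its stop edge for a single
pass (1 dB pass-band tolerance), applied forward and backward
(`sosfiltfilt`) so the phase response is identically zero; the
forward-backward application doubles the effective attenuation. Canonical
bands: delta 0.4–1.5, theta 4–8, alpha 8–13, low beta 13–22 Hz, with stop
edges at half/1.5× the band edges. Narrow bands are parameterized by their
centre f: pass 0.85f–1.15f, stop 0.5f–1.5f. The carrier bank runs
fₖ = 0.5·1.2^(k−1) Hz for k = 1..21 (f₂₁ ≈ 19.2 Hz) and the amplitude bank
fₖ = 0.015·1.2^(k−1) Hz for k = 1..15 (f₁₅ ≈ 0.19 Hz), giving 315 band
pairs. Broadband preprocessing is 0.15–45 Hz, polyphase anti-aliased
resampling to 100 Hz, and common-average re-referencing.

Amplitude envelopes are the magnitude of the analytic (Hilbert) signal —
the standard estimator in the envelope-correlation literature. The first
and last 2 s of every filtered epoch are discarded before correlation
(filter transients). For the double filter bank, envelopes are decimated to
2 Hz before amplitude-band filtering; envelope content of interest lies
below 0.3 Hz, so this changes nothing but the cost of the 315-cell grid.

## Connectivity

The coupling estimator between parcels x and y is the Pearson correlation
of amplitude envelopes after leakage orthogonalization: within
non-overlapping 2 s windows, y's least-squares projection on x is removed
(a window with identically zero x leaves y untouched; a trailing partial
window is dropped); the envelope of the residual is correlated with the
envelope of x; the two directions are averaged. Degenerate inputs
(collinear pairs, constant envelopes) contribute zero by contract.

Two properties of this estimator matter for the model work:

- It removes *zero-lag coherent* signal by construction. That is its
  purpose (instantaneous source-reconstruction leakage is zero-lag), and a
  property test confirms that an instantaneous 2×2 mixture of independent
  sources yields |coupling| < 0.06 where the plain envelope correlation
  exceeds 0.5.
- The model's own coupling is *exactly* zero-lag coherent — every parcel
  shares the one deterministic beat — so the orthogonalizing estimator
  nullifies it regardless of SNR. The model-fitting pipeline therefore
  uses the plain envelope correlation, identically on the model side and
  on the data side of the moment match; `orthogonalize` is an explicit
  pipeline flag everywhere. Orthogonalization stays on where it belongs:
  leakage-contaminated inputs, the reliability-mask surrogates, and any
  analysis of externally supplied recordings. For the synthetic cohorts in
  this package the parcel signals carry no leakage, so the network
  statistics default to the plain estimator as well.
- The windowed projection leaves a small negative bias under the null
  (≈ −0.025 at 300 s): each window removes chance-aligned energy, which
  couples the residual envelope negatively to the reference envelope. The
  null tests assert against this calibrated floor rather than zero.
- Envelope coupling is polarity-blind: flipping the sign of one signal
  changes nothing (exactly). Consequently mode-driven connectivity follows
  the *magnitude* profile |mⱼ(p)| of a mode across parcels, not its sign
  pattern.

A full matrix holds all 1653 unordered pairs of the 58 parcels. The
edge-reliability mask emulates the rejection of parcel pairs that a sparse
electrode montage cannot resolve: in each iteration every pair in turn is
given a shared slow amplitude modulation on independent alpha carriers,
all parcel signals are mixed through a toy leakage operator (Gaussian
centroid-distance kernel, rows normalized; spread 0 → identity, spread → ∞
→ uniform), and the pair's recovered coupling is compared with surrogate
couplings of non-synchronized mixed parcels, pooled across all iterations
(a per-edge variant is available by flag). Edges whose mean recovered
coupling falls below the pooled 99th percentile are rejected; the same mask
applies to every subject. On this geometry retention collapses from 100% to
0% as the spread crosses the inter-centroid distance (~20–25 mm); the
default spread of 25 mm excludes ≈ 32–36% of edges, matching the scale of
exclusion a 19-electrode montage imposes. Masked matrices are normalized by
the global sum of |weights| (sign-preserving, scale-invariant, idempotent).

Edge-length distributions use Euclidean centroid distances with a
Silverman-bandwidth Gaussian KDE. The parcel scale of the synthetic
geometry is not matched to any particular atlas, so these distributions are
qualitative.

## Network statistics

Edge-wise contrasts: sleep main effect — paired t on (AS − QS) over all
subjects; group main effect — two-sample pooled-variance t (preterm vs
control) on state-averaged weights; interaction — two-sample t on the
per-subject state differences. (A paired reading of the group contrast is
selectable but not the default; groups are independent samples.)

The NBS thresholds |t| ≥ h (h = 3 for canonical bands, 2.5 for fingerprint
grids) separately for the positive and negative tails, finds connected
components of suprathreshold edges in the parcel graph, and compares each
observed component's *edge count* against the permutation null of the
maximum component size from its own tail (within-subject state swaps for
the sleep effect; group-preserving reassignment for the group and
interaction contrasts, the latter applied to difference matrices).
p-values carry the +1 correction and are never zero. The permutation null
controls family-wise error per directed search — empirically ≈ 0.046 at
α = 0.05 on null cohorts — while the union over both tails runs near 2α,
as for any two one-sided families; calibration is asserted per tail.

Spectral fingerprints repeat a contrast at each of the 315 carrier ×
amplitude cells (carrier filtering and envelope extraction are done once
per carrier and reused across amplitude bands) and report Cohen's
d = mean component t / √(total df) of the largest component, with cells
lacking suprathreshold edges marked null. No correction is applied across
cells; the grid is descriptive.

## Fitting the mode weights

Connectivity depends only on the ratios aⱼ/σ, so the fit fixes σ = 1 and
searches a′ = (a′₁, a′₃, a′₄) over [0, 0.5]³; the left-right antisymmetric
second mode is fixed at zero (the observed networks are bilaterally
symmetric) but can be released. The cost is the two-moment match
`J = (μ_data − μ_model)² + (s_data − s_model)²` on masked, normalized edge
weights, computed identically for model and data.

**Pairwise response surface.** Every model parcel signal is
`g_p c(t) + noise` with `g_p = Σⱼ aⱼ mⱼ(p)`, so the coupling of a pair
depends only on the two SNRs `u = |g|/s`. The model moments over the whole
grid are therefore evaluated from a pre-simulated surface F(u, v) — the
Monte-Carlo mean and sampling SD of the plain envelope coupling of two
independent signals at those SNRs, pushed through the exact pipeline at the
exact record length. Because envelopes are conditionally independent given
the shared modulator, F factorizes as r(u)·r(v); projecting the estimated
surface onto its leading eigenpair removes most Monte-Carlo noise (the
rank-1 term carries ~98% of the spectrum). Model moments are expectations
over noise realizations: μ = mean(F̄)/Z and s = √(var(F̄) + mean(F_sd²))/Z
with Z = Σ E|w| the expected normalization constant (folded-normal per
edge — essential at low SNR, where weights straddle zero and the magnitude
normalization is what makes μ informative at all). A direct
simulate-per-node route (`model_connectivity` + `connectivity_moments`)
serves as the cross-check oracle in the tests.

**Grid search.** Default: a coarse 26³ grid at step 0.02, then one local
refinement at step 0.0025 in a ±0.02 box around the coarse minimum — the
reference granularity at the optimum without evaluating all 201³ nodes
(which the evaluator could afford, but pointlessly). Exact cost ties break
lexicographically by (a′₁, a′₃, a′₄); a boundary flag marks optima on the
box edge.

**Noise scale.** σ is recovered by matching the pooled time-series SD:
at unit noise the model's pooled variance is `mean_p(g_p²⟨c²⟩ + 1)` with
⟨c²⟩ the discrete time average of the squared carrier (≈ 1/4), so
σ = SD_empirical/SD_model and aⱼ = σ·a′ⱼ. Recovery of a known σ is exact
to a fraction of a percent at 300 s.

**Identifiability.** Two moments cannot pin three weights. Empirically the
fit identifies a′₁ (within ±0.05 in ≈ 98% of 300 s replicates at the
reference triple) and the combined anteroposterior energy
√(a′₃² + a′₄²) (within 0.05 in ≥ 90%), but the a′₃/a′₄ split rides a flat
exchange ridge of J — the parcel magnitude profiles of modes 3 and 4 are
near-exchangeable under the polarity-blind estimator — and the full triple
lands within ±0.05 per coordinate in only about half the replicates. The
corresponding acceptance test is intentionally strict and documents this
limit; group-level conclusions in this package rest on the uniform-mode
weight, where recovery is strong. A related conditioning boundary: subjects
with `1.6a₃ + 1.7a₄ ≳ a₁` fold parcel amplitudes through zero and can jump
to a distant a₁↔a₃ exchange basin. The cohort defaults keep subjects clear
of that region, which is also the physically expected ordering (low-order
modes carry most of the energy).

## Synthetic cohorts

The bihemispheric stand-in geometry is two mirrored ellipsoid lobes
(semi-axes 60 × 45 × 40 mm, 6 mm gap, icosphere subdivision 3), stitched
through a thin medial band so the mesh is one connected component — which
is what keeps mode 1 global and mode 2 left-right antisymmetric. The
58-parcel scheme grows 29 parcels on one hemisphere by farthest-point
seeding with geodesic nearest-seed assignment and mirrors them, giving
contiguous, bilaterally symmetric parcels without an atlas.

Cohort defaults (group × state mean weight triples at unit noise,
between-subject SD (0.04, 0.015, 0.015), truncated normal at zero since
weights are amplitudes):

| group | state | a₁ | a₃ | a₄ |
|---|---|---|---|---|
| control (HC) | AS | 0.22 | 0.050 | 0.040 |
| control (HC) | QS | 0.37 | 0.040 | 0.030 |
| preterm (EP) | AS | 0.24 | 0.045 | 0.035 |
| preterm (EP) | QS | 0.30 | 0.040 | 0.030 |

Quiet sleep gains uniform-mode energy and loses a little anteroposterior
energy; the state swing is attenuated in the preterm group, which is what
produces the group-by-sleep interaction. All randomness flows from one
cohort seed through per-subject derived seeds, so any subject is
independently reproducible and equal seeds give bit-identical cohorts.
Outcome scores for preterm subjects are linear in the subject's
connectivity change plus age effect and noise, with a negative default
coupling; where a target partial correlation is requested (−0.5 at n = 32
in the reference design) the noise is set from the realized change spread.

**What the synthetic data do not emulate:** electrode-level measurement,
real source reconstruction (the toy leakage kernel is isotropic and
distance-based), cortical folding, artifacts and non-stationarities, state
staging uncertainty, and any within-subject correlation between AS and QS
draws. Passing tests therefore demonstrate that the estimators and
statistics behave correctly on data generated by the stated model — not
that real recordings satisfy that model.

## Problem sizes and defaults

Reference conditions are 300 s records at 100 Hz and 58 parcels. The
response table uses 26 SNR nodes × 12 replicates; the NBS calibration runs
400 null cohorts of 20 + 20 paired subjects on 190-edge networks at 1000
permutations; recovery experiments use 50 replicates; the end-to-end cohort
uses 12 + 12 subjects. The pipeline's demo config scales down (60 s
records, 25 mask iterations) and a `paper_scale` preset restores the full
design (42 + 52 subjects, 5000 permutations, 500 mask iterations).

## Known limitations

- The a′₃/a′₄ degeneracy above; a third distributional moment or a
  spatially resolved cost would be needed to split them.
- The stationary beat model has a two-line spectrum; it reproduces
  envelope statistics, not realistic EEG spectra.
- The reliability mask's leakage operator is a geometric toy; its excluded
  fraction is calibrated in scale, not in spatial detail.
- EDF export is not provided (no writer in the dependency set); cohorts are
  written as array containers with JSON sidecars, and EDF reading is
  available through `mne` when installed.
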