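# Methods

## Problem and model

A digested food sample is filtered onto a silicon membrane with a
restricted filtration area of about 14 mm²; a µRaman instrument scans
part of that surface point by point on a regular lattice (5 µm pitch by
default), recording one Raman spectrum per lattice position over roughly
550–2000 cm⁻¹. The task is to decide, per pixel, which polymer (if any)
produced the spectrum, group same-polymer pixels into particles, and
report particle counts per class normalized to the sample volume.

The pipeline treats pixels as independent spectra for classification and
re-introduces spatial structure only at the particle-detection stage.
That separation is what makes every stage testable in isolation.

## Preprocessing

Order is fixed: grid refit → baseline correction → smoothing → SD
scaling.

- **Grid refit.** Cubic-spline interpolation onto 559–1990 cm⁻¹ every
  3 cm⁻¹ (478 points). Extrapolation is refused: a spectrum that does
  not cover the target range is an error, not a guess. Interpolation at
  existing knots reproduces the input to numerical precision.
- **Baseline.** Asymmetric least squares (Whittaker-style second-
  difference penalty, asymmetric weights): minimize
  `Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)²` with `wᵢ = p` above the current baseline
  and `1−p` below, iterated ≤ 10 times. One fixed "universal" parameter
  set is the default: `λ = 1e5`, `p = 0.01`. With these values a
  Gaussian band of width ~10 cm⁻¹ on a quadratic background is recovered
  to within ~1% of its height, and adding a constant offset to a
  spectrum changes the corrected result by well under 1% of that offset.
  The solve uses a symmetric banded factorization (pentadiagonal
  system), ~0.3 ms per 478-point spectrum. The estimated baseline is
  kept in `meta["baseline"]` for audit.
- **Smoothing.** A smoothing spline over all points with a small
  roughness penalty (`λ = 5` on the second-derivative integral). The
  default is chosen signal-preserving: a noiseless smooth signal passes
  through within 0.01% while white-noise variance is roughly halved.
- **Scaling.** Division by the spectrum's own (population, ÷n) standard
  deviation; at n = 478 the n vs n−1 distinction is immaterial but the
  convention is fixed here. Scaling makes classification invariant to
  laser power and collection efficiency.

**Degenerate spectra.** A constant trace carries no spectral
information; it is what a desynchronized acquisition frame looks like.
Constancy is detected after the refit with a relative tolerance
(peak-to-peak ≤ 1e-9 of the signal level) because spline refitting of an
exactly constant vector leaves ~1e-13 numerical ripple which SD-scaling
would otherwise amplify into a unit-variance noise spectrum and feed to
the classifier. Degenerate pixels bypass the forest and are assigned
NMP, confidence 0, review flag set.

## Classification

A scikit-learn RandomForestClassifier, 1500 trees by default, bootstrap
sampling, library defaults for feature subsampling (√p features per
split) and no class weighting; features are the 478 scaled intensities
directly — no derived descriptors. The out-of-bag error is the headline
diagnostic; the OOB confusion matrix (rows = true class, columns = OOB
prediction) has row sums equal to the per-class training counts. A
sample that happened to be in-bag for every tree — possible only for
tiny forests, never at 1500 trees — is counted as correct to preserve
that row-sum invariant.

Confidence is the fraction of trees voting for the winning class; since
the trees are grown to pure leaves, the forest's averaged class
probabilities equal the vote fraction. Pixels with confidence below the
review threshold (default 0.5) are flagged for operator review; flagged
pixels still count unless `drop_review` is set, because the automated
pipeline cannot stand in for the operator's judgment.

The class set is closed: 9 polymers, stearate, NMP. Stearate is kept as
a separate decoy class (its spectrum closely resembles PE, and keeping
it separate makes PE↔stearate misclassification visible in the
confusion matrix); `merge_stearate_nmp` folds its predictions into NMP
for reporting. Silicon-filter background spectra belong to NMP.

## Particle detection

Per class independently: build a graph on that class's pixels, connect
two pixels iff their lattice distance is ≤ `max_gap` (default 2), take
connected components. The distance is Chebyshev — diagonal neighbors are
at distance 1 — which is the natural 8-connectivity generalization and
makes the "jump over one missed pixel" rule symmetric in all directions;
Euclidean-in-lattice-units is available as an option (it excludes the
(2,2) diagonal at gap 2). Particle purity is by construction: edges
never cross classes. NMP pixels form no particles.

Metrics: area = n_pixels × step² (µm²); size = √area (side of the
equal-area square, so the < 50 µm² small class is size < ~7.07 µm); a
circular-equivalent diameter √(4A/π) is emitted as well for
comparability with studies that size by diameter. The representative
spectrum of a particle is its highest-confidence member pixel (ties go
to the earlier pixel in scan order).

## Quantification and QC

Counting chain per class: observed → ÷ analyzed fraction, rounded half
away from zero (counts are integers) → blank subtraction, clamped at 0
(a blank can exceed a sample count by chance; negative counts are
meaningless) → × 100 / sample volume (default 25 mL). The reported total
is the sum of the per-class per-100 mL figures, so the table is
internally consistent after rounding.

QC thresholds follow the filter-loading criteria: a blank passes with
*fewer than* 300 particles/mm² and *at most* 5% surface covered; a
sample passes with *at most* 600/mm² and at most 30%. The strict/
inclusive boundary semantics are deliberate. In the laboratory these
numbers come from an optical-microscope pre-check before the Raman scan;
the pipeline's report derives proxies from the detected particles over
the analyzed area and labels them as such.

The mass estimate treats all counted microplastics as spheres of 10 µm
diameter and density 1 g/cm³ in a 100 mL ≈ 100 g serving:
m = n·(π/6)d³ρ, so 1000 particles per 100 mL ≈ 5.2 µg/kg. Milk is
closer to 1.03 g/mL; the estimate deliberately uses 1 because it is an
order-of-magnitude figure, not a measurement.

`scan_point_factor(a, b) = (a/b)²` is the lattice-point (and therefore
scan-time) cost of changing the pitch: 5 µm → 1 µm costs ×25.

**Extrapolation factor.** `simulate_extrapolation_factor` places N
particles uniformly at random on the disc-shaped filter (polar sampling,
radius ∝ √u), counts them on the full disc and on a half-disc of random
orientation, and averages the full/half ratio over replicates. For a
uniform spatial distribution the mean ratio is ~2 (slightly above, by
Jensen's inequality on 1/K with K ~ Binomial(N, ½)); the simulation at
N = 200 and 100 replicates lands in [1.9, 2.1] and justifies the ×2
extrapolation for half-filter scans. Real filters can violate
uniformity — particles stuck to fibers create hot spots — which is a
limitation of the ×2 rule, not of the simulation.

## Synthetic data: what it emulates and what it does not

Spectra are sums of Gaussian (optionally Lorentzian) bands from
per-class peak tables, plus a random polynomial fluorescence baseline,
plus shot-like noise whose standard deviation scales with the square
root of local intensity and equals amplitude/SNR at the brightest point.
Libraries draw each spectrum's SNR uniformly from (3, 30) by default —
deliberately including very noisy traces, as a curated instrument
library does. The peak tables use canonical polymer band positions (PE
1062/1129/1295/1440 cm⁻¹, the PS ring mode at 1001 cm⁻¹, PTFE 732 cm⁻¹,
…); the stearate table is a PE-like pattern with extra weak bands, so
the PE↔stearate confusion structure of real libraries is reproduced.
NMP is broad humps (fluorescent residue, silicon background). All tables
are caller-overridable.

Scenes rasterize particle discs onto the lattice (a pixel belongs to a
disc iff its center lies strictly inside — the simplest unambiguous,
oracle-checkable rule; a particle that would rasterize to zero pixels
occupies its nearest pixel instead), add elongated NMP fiber polylines,
fill the background with NMP spectra, and turn dropout pixels into
constant traces. Overlapping particles of different classes are a scene
error because they would make the ground truth ambiguous. With
`preserve_connectivity` (default), dropout that would split or erase a
ground-truth particle under the gap-2 rule is undone for that particle,
so planted-vs-recovered particle counts compare exactly.

What the generator does **not** emulate: mixed or layered particles,
pigmented/fluorescence-saturated spectra (dark particles are often
invisible to Raman), cosmic-ray spikes, instrument drift within a run,
spatially correlated noise, or particle aggregation on fibers. Passing
the end-to-end recovery test therefore shows the pipeline's logic is
correct under its stated assumptions, not that real-world recovery is
100%.

## Scale choices

Default synthetic study conditions: 11 classes × 50 library spectra,
1500 trees, a 400 × 400 µm scene window (81 × 81 = 6561 pixels) with 20
planted particles of 10–20 µm at SNR 15–30 and 10% dropout, analyzed
fraction 0.5. These desk-scale sizes keep a full pipeline run around a
minute while leaving every mechanism (dropout bridging, extrapolation,
blank subtraction, OOB control) exercised at realistic per-particle
pixel counts. The examples shrink further (fewer trees and particles)
purely for brisk demonstration.

## Known limitations

- The forest is retrained per run in the `run-all` path; model reuse is
  supported via the CLI's joblib save/load but no versioned model format
  is defined.
- The review loop only flags and exports low-confidence pixels; there is
  no automated acceptance rule for them, by design.
- Polymers outside the 11-class closed world are reported as their
  nearest class with low confidence plus a review flag — the pipeline
  detects *that* something needs review, not *what* the unknown is.
- QC density/coverage from Raman-detected particles underestimate the
  optical pre-check values (they miss non-Raman-active residue).
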