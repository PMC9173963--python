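# Methods

## The model

Every algorithm in this package works on the multiplicative
illumination–reflectance decomposition of an observed intensity image,

    I(x, y) = S(x, y) · R(x, y),

where `S` is a smooth, strictly positive illumination (in MRI practice, the
coil-sensitivity *bias field*) and `R` is the reflectance that carries the
tissue contrast of interest. Taking logarithms turns the product into a sum,
`log I = log S + log R`, so estimating and subtracting a smooth version of
`log I` removes the bias. The package implements two estimator families and
everything needed to evaluate them against known ground truth.

All processing is floating point; natural logarithms are used throughout
(only log *differences* reach any output, so the base cancels once the
result is display-stretched). Zero pixels are guarded by an additive epsilon
inside `safe_log` (default `1e-6` in display units); the epsilon makes
nominally exact identities (scale invariance, telescoping ratio chains) hold
only to about `epsilon / min(I)`, which is why several tests compare at
`1e-5` rather than machine precision.

## Path-based estimators

**Random path.** The lightness of a pixel E relative to a reference S is the
thresholded sum of log brightness ratios along a path through pixels
`p_1 … p_n`:

    log(E/S) = Σ_i T'(log p_i − log p_{i−1}).

The threshold function has two modes. The default (`as-printed`) *keeps* a
ratio `x` when `1−T ≤ x ≤ 1+T` and resets it to 1 otherwise — it trusts
gradual variation and discards jumps. The `classic` mode inverts the
branches (resets the near-unity ratios, keeps the jumps), which is the
behaviour classic lightness-retinex descriptions use; both are exposed
because the two conventions coexist in the literature and they answer
different questions about what counts as illumination.

Design choices that the formulation leaves open, fixed here once:

* the reference is the globally brightest pixel (white-patch assumption);
* per pixel, `n_paths` independent paths are drawn and their log-ratio
  chains arithmetically averaged;
* a path is a uniformly random *monotone* (staircase) lattice walk from the
  reference to the target. A monotone walk is the simplest random path that
  is guaranteed to terminate at the target; when the Manhattan distance
  exceeds `path_length`, the walk is subsampled to `path_length` waypoints
  (the chain telescopes through the retained waypoints, so only the
  thresholding, not the endpoint lightness, is affected);
* determinism: one `numpy` generator seeded from `PathConfig.seed` drives
  all draws.

**Frankle–McCann spiral.** The estimate is initialized to the log image and
refined by comparisons against a copy of itself shifted by an offset that
starts at magnitude `D = 2^(⌊log2 min(rows, cols)⌋ − 1)` (the floor keeps
the offset an integer for non-power-of-two sizes), rotates 90° clockwise and
halves after every comparison, stopping below one pixel. Each comparison is
the classic four-step cycle, executed in the log domain:

* proportion/product: `candidate = r_shifted + (l − l_shifted)` — the
  shifted pixel's lightness estimate propagated through the brightness
  ratio of the compared pair;
* reset: `candidate = min(candidate, log max)` — no estimate may exceed the
  white reference (by default the log of the image maximum; the initial
  estimate is clamped there too, so the bound holds inductively);
* average: `r ← (r + candidate)/2`.

Shifts are toroidal (`np.roll`); with offsets that halve from `D` the
wrap-around contributions are the standard behaviour of this algorithm
family and vanish on constant images.

**McCann99 pyramid.** A fine-to-coarse pyramid is built by 2×2 block
averaging of intensities (odd trailing rows/columns are trimmed before each
halving; levels are added while both dimensions are ≥ 4). From the coarsest
level — initialized at the white reference — the same
product/reset/average cycle runs against all 8 neighbours of the 3×3
neighbourhood, `iterations_per_level` times (default 4), then the estimate
is duplicated 2× (nearest neighbour, edge-padded to the exact finer shape)
and the cycle repeats at the next level. Nearest-neighbour duplication is
used because it preserves the reset clamp exactly — interpolation could
create values above the ceiling.

A note on fidelity: the one-line per-level update sometimes quoted for this
algorithm, `r ← r + s − r_shifted`, ignores the neighbour's accumulated
estimate and is divergent under iteration (the update operator has spectral
radius above 1 at high spatial frequencies). The product/reset/average
cycle used here is the consistent realization of the named four steps and
preserves every invariant the algorithm is supposed to have
(constant → constant, scale invariance, the reset contract).

**Output convention.** Both deterministic path variants return
log-reflectance *relative to the white reference* (`r − log max`). This
makes all path outputs exactly invariant under global rescaling of the
input — multiplying `I` by `k > 0` shifts every log by `log k`, and the
shift cancels — and gives all variants a common interpretation: 0 at the
white patch, negative below it.

## Center-surround estimators

**SSR.** `log R = log I − log(F ∗ I)` with the Gaussian surround
`F(x, y) = K·exp(−(x² + y²)/σ²)`. The exponent carries `σ²`, not `2σ²`,
i.e. the spread in conventional Gaussian-sigma terms is `σ/√2`; the kernel
is implemented exactly in this parameterization. `K` normalizes the
truncated discrete window to sum 1 (truncation radius `⌈3σ⌉`,
renormalized after truncation, so the unit-sum property holds discretely to
machine precision). Because the kernel factorizes, the convolution runs as
two separable 1-D passes — the normalized separable form is *identical* to
the normalized 2-D kernel on its square support, which is what the
brute-force oracle test verifies. Borders are reflect-padded: in log space,
zero padding would darken the surround estimate near edges and produce
bright rims. Default `σ = 100`, the midpoint of the commonly used [80, 120]
working range.

**MSR.** Weighted average of SSR over several scales; defaults
`σ = (25, 75, 150)` with equal weights 1/3 — one scale under 50, one
between 50 and 100, one above 100.

**MSRCR.** Per channel `i`, MSR output multiplied by the color-restoration
factor `C_i = β · log(a · I_i / Σ_j I_j)` (defaults `a = 125`, `β = 46`,
the classic working constants; both exposed). The channel proportion is
scale-free, so `C` depends only on chromaticity; a small epsilon on
numerator and denominator guards zero-sum pixels while keeping achromatic
pixels exactly symmetric. The result is display-stretched per channel.

**Display stretch.** `R' = 255 · (R − Rmin)/(Rmax − Rmin)` maps the signed
log-reflectance onto 8-bit display with the endpoints attained exactly. A
constant input has no range and raises a degenerate-range error rather than
silently emitting zeros.

## Quality metrics

MSE and `PSNR = 10·log10((2ⁿ − 1)²/MSE)` with the peak set by the declared
bit depth (`n = 8` unless an image says otherwise); identical images report
an infinite PSNR and larger PSNR means *less* distortion (the universal
convention, and the one consistent with how enhanced-vs-original scores are
actually compared).

SSIM is computed from *global* population moments (mean, variance,
covariance over the whole image), matching a formulation written with
single image-level moments; the familiar sliding-window variant
(11×11 uniform window, mean-pooled) is available behind `windowed=True`.
Components: luminance `(2μμ'+C1)/(μ²+μ'²+C1)`, contrast
`(2σσ'+C2)/(σ²+σ'²+C2)`, structure `(σ_MN+C3)/(σσ'+C3)`, with
`C1=(0.01·255)²`, `C2=(0.03·255)²`, `C3=C2/2`. The `σσ'+C3` structure
denominator is what makes `SSIM(M, M) = 1` and bounds the index by 1; a
`μμ'+C3` denominator variant is kept behind `as_printed=True` for
comparison experiments, with neither property. Note that the often-quoted
range [0, 1] holds for *positively related* nonnegative images (e.g.
degraded versions of one scene); anticorrelated images legitimately produce
a negative structure term, so the package does not clamp.

## The phantom generator

The generator manufactures the decomposition explicitly so every algorithm
can be scored against known truth:

* **Reflectance:** `n_structures` (default 6) random ellipses with distinct
  levels evenly spaced in [0.1, 1.0] on a 0.05 background. Radii are drawn
  from 2–5% of the smaller image dimension (floor of 2 px), centers from
  the central 70%.
* **Illumination:** Gaussian-filtered white noise rescaled to
  `[1 − strength, 1 + strength]` and renormalized to mean 1. Defaults:
  `strength = 0.5`, `smoothness_sigma = size/2`.
* **Observation:** `clip(S·R + noise, 0, 1)` scaled to `2ⁿ − 1`; additive
  Gaussian noise (default sd 0.005 on the unit scale) keeps the
  multiplicative algebra exact at zero noise; Rician magnitude noise (the
  physically correct MRI model) is available as an option. The clipped
  fraction is recorded so tests can demand clip-free phantoms.

The scale choices are deliberate and load-bearing. The decomposition
`I = S·R` is only identifiable when the two factors live at separated
spatial scales, and a surround estimator can only exploit that separation
when its own scale sits between them:

    structure scale (≲ 13 px)  <  surround σ (25–150 px)  <  bias scale (≈ size/2).

A bias field as wiggly as the tissue (or tissue as large as the bias) makes
the problem ill-posed for *any* homomorphic method — early drafts of the
generator with quarter-image ellipses sat in exactly that regime. The
defaults emulate the clinically realistic situation: focal lesions of a few
millimetres under a near-global coil-sensitivity gradient.

What the phantom does *not* emulate: MRI sequence contrast, k-space
acquisition, partial-volume edges (tissue boundaries here are hard),
spatially correlated noise, and anatomy more structured than ellipses.
Passing the recovery tests therefore demonstrates that the estimators
remove smooth multiplicative bias under the model's own assumptions — not
that they improve any particular clinical sequence.

**Evaluation protocol.** Recovery is scored in the *log display domain*,
the domain the estimators operate in: the observed image and the true
reflectance pass through `linear_stretch(safe_log(·))`, the enhancement's
log-reflectance output through `linear_stretch` alone, and each is compared
to the stretched log-reflectance truth with global SSIM/PSNR
(`recovery_scores`). Comparing in linear intensity would conflate the
estimator's bias removal with the monotone log remapping of tissue levels,
which a radiologist's window/level adjustment undoes anyway. At the default
study conditions (256², bias 0.5, noise 0.005) SSR at σ = 100 and MSR at
its default scales improve SSIM against truth in ≥ 95% of seeded
replicates; absolute SSIM values in this protocol are small (the log
display exaggerates background bias), and it is the ordering that carries
meaning.

## Clinical statistics

* Sensitivity/specificity/accuracy from a confusion matrix, reported in
  percent to two decimals, rounded half away from zero (the convention
  under which 31/35 prints as 88.57).
* Pearson χ² homogeneity on r×c count tables without continuity correction
  (none is conventional for r×c; the small-count 2×2 case is served by the
  exact test instead), expected counts from the margins, `df = (r−1)(c−1)`.
* Two-sided Fisher exact test for 2×2 tables, summing hypergeometric
  probabilities not exceeding the observed table's.
* `counts_from_percentages` inverts two-decimal printed percentages back to
  the unique integer composition of the group size, by exhaustive search
  with a uniqueness check — printed rates are often all that a report
  provides, and the inversion makes them testable. Ambiguity (no match or
  multiple matches) is an error, not a guess.
* Welch's t for (mean ± sd) measurement data is included as a routine
  wrapper for workflow completeness.

## Problem sizes used in the test suite

Unit and property tests run on 16×16 to 64×64 images, where the brute-force
oracles (direct spatial convolution, hand-computed moments, hypergeometric
enumeration) are exact and fast. The recovery checks use 128² phantoms
(10 replicates) in the module suite and 256² phantoms (20 replicates, the
full study conditions) in the end-to-end suite and the acceptance script.

## Known limitations

* The random-path variant is `O(pixels · n_paths · path_length)` in Python
  and is intended for small images and methodological study, not production
  enhancement.
* Toroidal shifts in the spiral variant mix opposite image borders; on
  images whose borders differ strongly this shows up as faint ghosting at
  the largest offsets.
* Global-moment SSIM is insensitive to where in the image a discrepancy
  sits; the windowed variant should be preferred when local structure
  matters.
* The `as-printed` threshold mode discards large ratios, so the random-path
  estimate is not guaranteed to telescope exactly; residuals slightly above
  the white reference are possible and expected.
* DICOM and NIfTI support is read-only and extracts a single (middle)
  slice; no geometry or metadata handling.
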