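# Methods

This note documents the models, conventions and design choices behind
`adcstab`, and what its synthetic experiments do and do not demonstrate.

## Signal model and phantoms

Each phantom is a single 2D slice (default 64×64 pixels at 1 mm spacing —
finer than a clinical breast-DWI matrix, chosen so that mask perturbations
are well resolved at desk scale) holding one circular lesion. The
diffusion-weighted signal is mono-exponential,

    S(b) = S0(x) · exp(−b · ADC(x) · 10⁻³),

with b in s/mm² (default 50, 750, 1500) and ADC in μm²/ms. The ADC field
is composed of:

- a background at 2.2 μm²/ms (fibroglandular tissue);
- a lesion disk whose interior is exactly the lesion mean ADC. Solid
  lesions draw their mean uniformly from (0.6, 1.4) μm²/ms (depressed vs
  background, DWI-bright); a configurable fraction (default 0.25) is
  cyst-like with ADC uniform in (2.5, 3.0) μm²/ms and an elevated
  proton-density/T2 factor (default 6×) applied to S0, modelling the T2
  shine-through that keeps fluid lesions visible on high-b images;
- a partial-volume-like rim: outside the disk the lesion contrast (in both
  ADC and S0) decays as a Gaussian of the boundary distance with scale
  `edge_width` (default 1 mm). Two phantom properties forced this rim and
  are worth recording. With an infinitely sharp edge, (i) threshold
  resizing selects pixels by their ADC value (the b1500 signal is a
  monotone function of ADC), truncating the interior intensity
  distribution instead of moving the boundary, and (ii) a one-pixel shift
  swaps in full-contrast background. Neither happens on measured data,
  where scanner point-spread and peritumoral tissue always produce a
  transition zone;
- spatially correlated texture over the *whole* slice: white Gaussian
  noise convolved with a Gaussian kernel (correlation length 2 mm),
  rescaled to standard deviation 0.08 μm²/ms. Texture is deliberately not
  restricted to the lesion: a strictly constant background collapses the
  delineated region's histogram to a single bin, so Otsu's between-class
  variance becomes flat across the entire class gap and the deterministic
  lowest-maximizer tie-break degenerates to "just above background". Real
  histograms have spread on both sides of the gap.

Noise is additive Gaussian per b-value image (σ = 2 % of S0 by default),
magnitude-rectified as the simplest Rician-like surrogate. The rough
delineation is the true disk dilated by two pixels. Cohort lesion radii
are uniform over (2.05, 20.5) mm, the extremes of maximum lesion diameters
reported for clinical breast-lesion cohorts of this kind.

Limitations of the phantom: no EPI distortion, no fat-suppression failure,
no multi-slice/3D structure, circular lesions only, and a single texture
field for both lesion and background. Stability results on phantoms
therefore show that the *pipeline* behaves correctly and reproduces the
expected stability ordering; they are not a substitute for patient data.

## ADC fitting

The two-point fit uses the two lowest b-values (50, 750); the b1500 image
is only used for segmentation. Pixels with non-positive signal are flagged
invalid (NaN) rather than clipped, and the outlier filter marks pixels
outside [0, 3.5] μm²/ms invalid with inclusive bounds ("outside the
range" excludes endpoints from removal). Invalid pixels are removed from
every mask before feature extraction, so shape features are measured on
the same pixel set as intensity features.

## Segmentation and variants

Otsu's threshold is computed from the delineated region only: candidates
are the interior edges of a 256-bin histogram spanning the region's
intensity range, the objective w0·w1·(μ0−μ1)² is evaluated on the actual
values split at each edge, and the lowest maximizing edge wins (exact
ties broken deterministically). Segmentation keeps pixels *strictly above*
the threshold, with no connected-component filtering. Resizing re-segments
at 80/90/110/120 % of the threshold, which guarantees monotone nesting of
the masks; shifting translates the original mask one pixel along ±x/±y
without re-intersecting with the delineation. A lesion whose th = 120 %
mask is empty (possible for small, low-contrast lesions) is excluded from
the cohort and logged — the pipeline never aborts on per-lesion failures.

## Feature definitions

The 102 features follow IBSI-style 2D definitions with the conventions of
the widely used extraction tools: population (1/n) moments, non-excess
kurtosis, histogram entropy in bits, symmetric GLCM with per-angle feature
averaging over the four in-plane angles (also for GLRLM), 8-connected
GLSZM zones, GLDM dependence at Chebyshev distance 1 with tolerance α = 0
and the center pixel counted as its own dependency (sizes 1–9, so the
1/j² emphases are defined for isolated pixels), and NGTDM over the 8
neighborhood with no-neighbor pixels contributing zero deviation. A fully
uniform region has infinite NGTDM coarseness; the conventional cap 10⁶ is
returned. Degenerate statistics (e.g. GLCM correlation of a single-level
region, skewness of a constant region) are NaN and flagged, never silently
zeroed, and the stability stage drops incomplete lesions pairwise with a
logged count.

Discretization uses a fixed bin width of 0.025 μm²/ms anchored at ADC = 0
(level = floor(v/width) + 1), giving ≈ 40–140 levels on breast ADC values.
Anchoring at zero ties bin boundaries to absolute ADC, so the same tissue
value falls in the same bin for every segmentation variant. Bin width,
anchor, GLCM distance and the GLDM tolerance are configurable.

Mesh surface, perimeter and maximum diameter come from the marching-squares
boundary (0.5 iso-level of the padded mask) with signed areas so holes
subtract; axis lengths are 4·√(eigenvalues) of the foreground-coordinate
covariance (sample covariance, matching common tooling).

## Stability statistics

OCCC uses population (1/n) variance/covariance estimators. The convention
matters: sample estimators rescale the covariance and variance terms but
not the mean-difference term, so mixing them changes the value. For J = 2
the implementation reduces exactly to Lin's CCC, and a common affine map
applied to all columns leaves it unchanged (both properties are tested).
Per category J = 5 (the original plus four variants; the original is
shared between categories).

DR uses absolute differences and the original-segmentation Max/Min over
all lesions. A feature with zero between-lesion range has no
discriminative value; its DR is flagged degenerate and scores 0 points.
DR below 0 (differences exceeding the natural range) is reported with a
warning rather than clamped.

Confidence intervals for both OCCC and DR come from one coherent
machinery: percentile bootstrap over lesions (B = 1000, level 95 %,
seeded). Resamples on which a statistic is undefined are skipped with a
logged count. Percentile intervals are first-order accurate: in simulation
their coverage of a known OCCC is ≈ 92–95 % at n = 100 lesions but drops
toward ~88 % at n = 30, a known small-sample property of percentile
bootstrap for variance-ratio statistics that users should keep in mind
when reading CIs from small cohorts.

## Scoring, ranking, significance tests

Points: < 0.75 → 0, [0.75, 0.85) → 1, [0.85, 0.90) → 2, [0.90, 0.95) → 3,
≥ 0.95 → 4; identical for OCCC and DR; degenerate → 0. The per-category
score is their sum (max 8). Ranking uses the Euclidean distance of
(shifting, resizing) scores to (8, 8) — the natural reading of a 2D score
scatter; Manhattan and Chebyshev are selectable and can reorder the
mid-table but not the top group. Ties share a dense rank. Shape features
carry only the resizing category and are ranked separately on that axis.

Threshold-pair testing treats the five resizing thresholds as repeated
measurements: per pair, Shapiro–Wilk on the paired differences (the
quantity whose normality the paired t-test actually assumes) selects the
paired t-test or the Wilcoxon signed-rank test ("paired Wilcoxon rank sum"
is read as the signed-rank test, the paired member of that family);
two-sided p-values are compared against 0.05/10. Zero-variance difference
vectors are flagged and skipped.

## Problem sizes and determinism

The default study conditions are a 30-lesion cohort, B = 1000 bootstrap
resamples, and 64×64 slices; a full run takes seconds on one CPU. All
randomness flows from explicit integer seeds (cohort seed, per-case seeds
spawned from it, bootstrap seed), making every table byte-reproducible.
The test suite's simulation studies use 1000 replicates for the
family-wise error check and 200 cohorts for bootstrap coverage.
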