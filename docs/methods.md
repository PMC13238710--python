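# Methods

## Scope and data model

The package quantifies 2D skin-section immunofluorescence: it consumes
multi-channel images with isotropic pixel size (default 0.61 µm/px, a
typical widefield acquisition resolution) together with binary structure
masks for epidermis, dermis, nerve fibers and blood vessels. Segmentation
itself is out of scope — masks are inputs, produced upstream by whatever
tool the study uses; `threshold_segment` exists only as a high-contrast
stand-in for end-to-end demonstrations on synthetic data. Sections are
treated as 2D projections; no 3D morphology is attempted.

## Geometry in physical units

All distances are Euclidean between pixel centers: pixel (r, c) has center
(r + 0.5, c + 0.5) in pixel units. Mask expansion by a physical distance d
selects pixels whose center lies within the *closed* ball of radius d
around any foreground center, computed with an exact Euclidean distance
transform; this definition is reproducible to the bit against a brute-force
all-pairs oracle, which the test suite and the acceptance script both
verify. Expansion clips at image borders without compensation — sections
are assumed framed so the analysis ROI is fully contained.

The sub-epidermal band is the dermis within 50 µm of the epidermis
(`expand(epidermis, 50 µm) ∩ dermis`). The 50 µm expansion distance and
the 5 µm vessel-proximity radius are the protocol constants and the
defaults of `RunConfig`. Overlapping epidermis/dermis inputs are rejected
with the overlap pixel count rather than silently resolved;
`resolve_overlap` provides the documented pre-step (overlap → epidermis)
for segmentations that emit overlapping classes.

### Basement membrane

The membrane is the epidermis–dermis *interface* only; the free epidermal
surface contributes neither length nor crossings. Two representations are
derived:

* the **crossing band**: dermis pixels 8-adjacent to the epidermis. With
  8-adjacency, any 8-connected path from epidermis into dermis must touch
  the band, so diagonal fiber trajectories cannot tunnel through uncounted;
* the **polyline**: the band is skeletonized and each connected component
  ordered by a deterministic greedy nearest-neighbor walk starting from an
  endpoint (ties resolve lexicographically). Skeletonization matters for
  length: where the boundary steps diagonally the raw band is two pixels
  thick and a naive trace would charge 2 px instead of √2.

Length per segment is the polyline arc length plus one pixel (two
half-pixel end caps), so a straight full-width interface measures exactly
`width × pixel size`. On undulating boundaries (slope < 1 px/px) the
measured length tracks the analytic arc length of the rasterized boundary
closely; the generator closed-loop test bounds the discrepancy at 5 % and
straight interfaces are exact.

## Fiber counting

One 8-connected component of `nerve ∩ band` = one crossing. No minimum
component size is applied, mirroring the manual convention of counting
every immunoreactive fiber that crosses the basement membrane. Two known
biases of 2D mask-based counting are accepted and documented rather than
patched: a fiber touching the band at two separated loci counts twice (the
mask carries no fiber identity), and thin-section automated counts
generally run below thick-section manual counts — `manual_vs_automated`
reports the rank (default) or Pearson correlation with a Fisher-z 95 % CI
(se = 1/√(n−3)) plus a direction flag for exactly this comparison.

## Fluorescence quantification

MFI is the arithmetic mean of channel intensities over `nerve ∩ ROI`
pixels. No background subtraction or flat-field correction is applied: the
inputs are vendor-processed projections, and the PGP9.5-normalized ratio —
invariant to any global intensity scale — is the control for staining and
imaging variability. An empty `nerve ∩ ROI` yields a *missing* value,
never zero (absence of fibers is not absence of signal); missing values
propagate through ratios and are excluded pairwise by the statistics
layer. One shared nerve mask (PGP9.5-based) is used for all markers by
default; per-marker masks can be passed explicitly. Per-subject
aggregation of the two images per subject is the arithmetic mean with
missing values dropped.

## Neurovascular interaction

Vessel metrics are restricted to the dermis (epidermal vessel pixels are
treated as segmentation noise). The interaction area is
`area(vessels ∩ dermis ∩ expand(nerve, 5 µm))`, reported as absolute µm²
per image. Interaction is monotone in the proximity radius and in the
vessel mask, and positive exactly when the nearest vessel rim comes within
the radius of a fiber (±1 px discretization, verified by a planted
distance sweep).

## Clinical scores

The 11 QST parameters follow the DFNS analysis conventions: CDT, WDT, TSL,
PPT, MPT, MPS, WUR, MDT and VDT are log₁₀-transformed before scoring; CPT
and HPT stay linear. z = sign · (domain(x) − µ)/σ against a reference
stratum, with the sign multiplier orienting positive z as gain of
function. Abnormality is membership outside the stratum's 95 % reference
interval in the analysis domain; the interval is closed (boundary values
are normal — a recorded convention, since boundary handling is otherwise
unspecified) and both tails are abnormal. Published normative tables are
licensed data and are **not** bundled; `ReferenceNorms` is a user-supplied
YAML table with free-form stratum keys (falling back to `"all"`), and
`synthetic_norms()` ships a synthetic, schema-complete stand-in whose
values are plausible in magnitude only. Non-positive raw values of
log-domain parameters become missing (instrument floor readings), and
missing values never enter denominators. Pain ratings band as 0 none,
1–3 mild, 4–6 moderate, ≥ 7 severe; a medication-relief-adjusted rating,
when supplied, takes precedence (the adjustment itself is an upstream,
flag-only concern).

## Relative expression

Standard Livak 2^(−ΔΔCt): replicate Cts are averaged arithmetically
(replicate SD > 0.5 cycles flags the well set for QC — a common laboratory
threshold), ΔCt = Ct_target − Ct_reference per sample, and the ΔΔCt
baseline is the arithmetic mean of calibrator-group ΔCts, which makes the
calibrator geometric-mean fold exactly 1 (asserted to 1e-12). Samples
missing the reference gene are excluded and logged. Efficiency-corrected
quantification is out of scope.

## Statistics layer

Two-group comparisons are routed by Shapiro–Wilk at α = 0.05 on each
group: both normal → independent t-test with mean (SD) descriptives,
otherwise Mann–Whitney U with median (IQR = Q3 − Q1, type-7 quantiles).
Groups under n = 3 get descriptives only. The Mann–Whitney p is the exact
permutation value when the combined n ≤ 20 without ties, else the midrank
normal approximation with tie and continuity corrections; constant samples
are treated as non-normal (Shapiro–Wilk is undefined there). The routed
procedure's type-I error on 10,000 null pairs sits within 5 % ± 1 %
(recomputed by the acceptance script).

2×2 tables use the Yates-corrected χ²,
χ² = n(|ad − bc| − n/2)² / ((a+b)(c+d)(a+c)(b+d)) floored at zero, with
Fisher's exact test when any expected count is below 5. Odds ratios are
ad/bc with Woolf log-normal 95 % CIs; a zero cell triggers the
Haldane–Anscombe +0.5 correction, flagged. Note that a Woolf interval on
the bundled worked-example table (16/3 vs 15/15) is 1.28–22.19; published
intervals for such tables are sometimes computed by other (often
unidentifiable) methods, so the CI method here is fixed and documented
rather than matched. All tests are two-tailed at α = 0.05 with no
multiple-testing correction by default — mirroring common clinical
reporting practice — with `holm` available for families of p-values.

## Synthetic data: what it emulates, and what it does not

`generate_section` builds: a sinusoidally undulating epidermal boundary
(slope capped at 0.9 px/px), crossing fibers as jittered random walks that
run strictly vertically through the undulation zone — guaranteeing exactly
one interface contact per planted fiber, the property that makes planted
count = countable count — plus purely dermal fibers kept clear of the
band; elliptical dermal vessels either placed at an exact
center-to-nearest-fiber distance (±0.5 px, via the fiber distance
transform) or clear of the proximity analysis; and per-channel intensities
as additive Gaussian noise (truncated at 0, quantized to 16-bit) around
background (mean 200) and fiber (PGP9.5 2000, CGRP 1800 on the peptidergic
subset, TrkA 1500, GAP43 1200) levels, SD 50. Everything is deterministic
given the spec seed; infeasible specs (fibers that cannot fit at the
minimum spacing, vessels planted inside fibers, boundaries leaving the
frame) raise errors rather than degrade.

`CohortSpec` plants the qualitative clinical pattern: patients (both pain
phenotypes) get fiber-density ×0.5, TrkA intensity ×5, vessel-area ×1.4
and NGF expression fold 0.75; only the painless subgroup gets the
vessel-interaction multiplier ×3 (implemented as near-planted vessel
count). Defaults: 20 subjects/group, 2 images/subject, 16 crossing fibers
per 1024×1024 px image (≈0.62 mm of interface). That density is higher
than distal-leg patient biopsies; it is chosen, together with a subject
lognormal CV of 0.1, so that counting statistics rather than sampling
noise dominate recovery at the 20/group scale — the closed loop is a test
of pipeline bias, not a power simulation. Consequences for interpretation:
passing recovery shows the measurement chain is unbiased on clean,
well-separated structures; it says nothing about segmentation quality,
optical artifacts, fiber fragmentation, or realistic biological
variability, none of which the generator models. The near-vessel plant
also adds vessel area in the painless group beyond the vessel-area
multiplier; vessel-area contrasts between patient subgroups therefore
reflect both plants.

QST cohorts draw raw values from the norms' own distributions (optionally
shifted in SD units), so the unshifted abnormality rate calibrates to
≈5 % by construction. Ct tables plant reference Ct ≈ 18, target ΔCt 8
(TrkA) and 7 (NGF), subject ΔCt SD 0.25 and replicate SD 0.12 cycles;
group folds enter as −log₂(fold) ΔCt shifts. With 25 patients the
median-fold estimator scatters by roughly ±9 % across master seeds —
Monte-Carlo noise, not bias.

## Numerical choices

* Exact EDT (not chamfer) for all physical-distance operations; closed
  thresholds (≤).
* Type-7 (linear interpolation) quantiles everywhere.
* Deterministic tie-breaking in polyline tracing (lexicographic).
* Degenerate inputs prefer explicit errors (empty dermis, non-positive
  section length, out-of-range NRS/Ct) or explicit missingness (empty MFI
  selection, zero-variance correlation input) over silent zeros.
* Cohort randomness flows from one master seed through `SeedSequence`
  spawning; per-image seeds stay below 2³¹.

## Known limitations

* 2D counting without fiber identity: multi-contact fibers double-count.
* Membrane length on strongly stepped boundaries is a skeleton-trace
  approximation (exact on straight interfaces, ≤ ~5 % otherwise).
* MFI assumes vendor-normalized projections; no shading or background
  model.
* The statistics layer implements the routing it documents; it does not
  attempt to reproduce any particular software's tie-handling or CI
  conventions beyond what is stated above.
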