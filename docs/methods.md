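# Methods

This note documents the models, defaults and numerical choices behind
`evuptake`, and what the synthetic data do and do not establish about real
images.

## Synthetic myocyte fields

Live cardiomyocytes are drawn as rotated rectangles with semicircular end caps
("stadium" shapes): length 90–130 µm, width 20–28 µm by default, giving areas
of ≈1700–3500 µm² and axis ratios ≥ 3.2 — inside the default QC window by
construction. Hypercontracted dead cells are near-circular ellipses
(diameter 45–60 µm, eccentricity jitter ≤ 10 %), so their area falls inside
the same window while their axis ratio ≈ 1 fails the rod criterion; this makes
"rejected for shape, not size" the expected verdict, as for real dead cells.
Nuclei are elongated ellipses along the cell axis (major 10–18 µm, minor
3–4.5 µm), a range that deliberately straddles the >30 µm² / ratio>3 criteria
so both qualifying and non-qualifying nuclei occur.

Cells are placed by rejection sampling against an occupancy grid (2-px
clearance, 200 attempts per cell; failures are counted in the ground truth).
Centres are sampled with a half-length margin so cells lie fully inside the
field; border-crossing cells are opt-in (`n_border_cells`) and flagged.

Channel 1 (405 nm) = background (10) + autofluorescence over cell bodies (30)
+ Hoechst on nuclei (200). Channel 2 (488 nm) = background + per-cell
NeonGreen2 level × a multiplicative texture field. The texture is a Gaussian
random field (white noise smoothed at a 5-µm correlation length, unit
variance, scaled by the heterogeneity amplitude, floored at 0, mean 1), so the
within-cell mean is unbiased and GLCM homogeneity decreases monotonically with
the amplitude. Noise is Poisson-scaled shot noise plus additive Gaussian read
noise; both are zero-able, which makes exact-value tests possible (uniform
cell ⇒ homogeneity exactly 1). Pixel size defaults to 0.5 µm/px and the field
to 512×512 px; acquisition parameters like magnification and bit depth are
declared in the config, not inferred.

What the generator does **not** emulate: point-spread-function blur, channel
bleed-through, depth (3-D) structure, contraction motion, and clumped or
overlapping cells. Passing tests therefore demonstrate the correctness of the
measurement and inference chain under known truth, not robustness to optical
artefacts; on real images the Otsu defaults may need overriding with fixed
thresholds, which every operation accepts.

## Segmentation

The cell-outline threshold is parameter-free by default: Otsu's method first
separates the bright nuclear population, then a second Otsu pass on the
sub-nuclear intensity range separates autofluorescent cell bodies from
background. Binary masks are hole-filled and despeckled (components < 50 µm²
removed — well below nuclear scale). The nuclear threshold is Otsu over
within-cell 405-nm intensities. Both thresholds accept fixed overrides.

Shape metrics come from the second-central-moment equivalent ellipse
(`skimage.regionprops`); axes are floored at one pixel so the ratio is defined
for degenerate masks. Cell criteria (area ∈ [1500, 6000] µm², ratio ≥ 2.5) are
inclusive; nuclear criteria (>30 µm², ratio > 3) are strict, so a nucleus of
exactly 30 µm² is excluded. Rejection reasons are assigned in the order
border → area → ratio. Touching cells are not split (no watershed): the
simulator places non-overlapping cells, and real clumps fail the shape QC.
Multiple qualifying nuclei per cell are pooled into one nuclear mask for the
nuclear mean (the per-nucleus count is reported).

## GLCM homogeneity

The co-occurrence matrix uses 32 grey levels, the four unit displacements
(right, down, down-right, down-left) accumulated into one matrix, and
symmetric counting — standard texture-analysis practice; all three are
configurable and recorded in output metadata. Quantization is linear min–max
**per region**, not global, which makes homogeneity invariant to multiplying
all intensities by a positive constant: it measures spatial texture, not
brightness (brightness is the separate mean readout). A constant region maps
to the first level and yields homogeneity exactly 1. Pairs with either pixel
outside the mask are dropped entirely (no padding); a mask admitting no valid
pair raises a degenerate-geometry error rather than returning a value.
Homogeneity is computed on the cytoplasmic mask (cell minus pooled nuclei).

## Positivity threshold

The threshold is the maximum sham value retained after iterative outlier
removal: Grubbs' two-sided test at α = 0.05 by default, repeated until no
value is flagged (a mean ± 3 SD rule is selectable); removed indices, rule and
parameters are reported as an audit trail. The procedure is idempotent.
Positivity uses strict ">", so sham positivity is exactly 0. At least three
sham values are required.

## Hierarchical inference

The reference procedure is deliberately two-stage rather than a mixed model:
average cells within each heart, then treat heart means as the observations.
With 3–4 hearts per group a random-effects fit is fragile (variance components
on the boundary), while the two-stage procedure is transparent, exact under
balanced designs, and invariant to duplicating cells within a heart — the
operational definition of removing pseudo-replication. The omnibus test is a
Welch one-way ANOVA (unequal variances); pairwise comparisons versus control
use Dunnett's T3: each Welch t statistic is referred to the studentized
maximum modulus (SMM) distribution with k = number of comparisons and that
comparison's Welch degrees of freedom. The SMM CDF is evaluated by adaptive
quadrature over the chi distribution (absolute tolerance 1e-9, stricter than
the 1e-6 target); at k = 1 it reduces exactly to the two-sided Welch t test,
which is verified in the tests alongside a Monte-Carlo check of the CDF.
Degenerate inputs are handled by convention: zero-variance ties report p = 1
(logged); groups with a single heart are excluded from testing with a warning.

A cell-level mode (`aggregation="none"`) exists solely to demonstrate the
pseudo-replication error: under a null with heart-level SD equal to the
cell-level SD, its type-I error is an order of magnitude above nominal while
the heart-mean analysis stays at ≈0.05 (`analysis/07`, 400 replicates; the
test suite uses 1000).

## Sections, FRAP, biodistribution

Sections: compartment masks are DAPI-above-threshold (nuclear),
actinin-above-threshold minus nuclear (cytoplasmic), and the remainder; they
partition the field for any input. Histograms share bin edges (64 bins over
the red channel's global range). The simulator hits requested area fractions
by quantile thresholds on smoothed random fields, accurate to well under 2 %.

FRAP: the fit is a three-parameter least squares (floor F₀, amplitude A, τ)
on post-bleach samples, baseline fixed at the pre-bleach mean; initial guesses
from curve geometry (τ₀ = time to half recovery / ln 2, fallback: one third of
the window). τ is bounded positive; a negative fitted amplitude clamps the
mobile fraction to 0 with a warning. The fit is invariant to intensity
rescaling. At noise amounting to 5 % of baseline (25 % of the default recovery
amplitude) the estimator's relative bias over 100 replicates is ≈3 %;
individual fits scatter more, as least squares must on this sampling grid
(0.5-s intervals, 60-s window). Only a single-exponential model is offered —
no diffusion-equation or multi-component recovery — and uncertainty is
reported via residual RMS.

Biodistribution: normalized = raw / (dose × tissue mass); fold = group mean
normalized over control mean normalized, per organ, so control folds are 1 by
definition and mass variation cancels exactly in the noise-free case.
Normalization is by tissue mass (protein-content normalization would be an
alternative; the column semantics are identical).

## Problem sizes and determinism

Default test and analysis runs use 512×512-px fields with 4–7 cells, 2–4
hearts per group and 16–40 cells per heart, 400–1000 replicate experiments
for error-rate estimates, and 100 replicates for FRAP bias — sizes chosen so
every statistical check has adequate Monte-Carlo resolution. All randomness
flows from one master seed through named sub-streams per (group, heart,
field), so adding fields never perturbs earlier ones and identical configs
give bit-identical outputs; pipeline outputs carry the config hash, seed and
package version.
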