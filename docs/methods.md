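# Methods

This note documents the models, parameter choices and numerical details of
pattquant, and what its synthetic-data tests do and do not establish about
real photographs.

## Binarization model

A region photograph is reduced to a binary melanistic/background map by
global robust-background (Niblack) thresholding with the window equal to
the whole region: T = mu − k·sigma on the green channel, clamped below by
60 and, for the trunk, above by 108 (0–255 scale). The green channel is
used because melanistic spots and shadows of similar brightness separate
best there; k is body-part specific (0.85 limbs/trunk/tail, 0.50 head —
the head carries a larger melanistic fraction, which depresses mu and
would otherwise push T below the lighter spots). The floor exists because
pixels below 60 are essentially always melanistic; the trunk cap guards
sparsely patterned trunks whose high mean would otherwise drag T into the
background.

**Artifact handling.** Shadows and glare are flagged by fixed rules
(limbs: green outside mu ± 0.3 sigma; trunk: blue below mu_B − 0.85
sigma_B; head and tail: none). Any brightness-based shadow rule on the
spot-detection channel inevitably also flags the spots themselves, so
flagged pixels cannot simply be barred from the dark set — that would
delete the pattern. The package therefore (a) removes a least-squares
illumination plane from the green channel of shadow-prone parts (limbs,
trunk) before thresholding, which is the concrete "lighting adjustment"
the flags call for, and (b) uses the flags only to exclude pixels from the
recomputed (mu, sigma). The plane is fitted over all mask pixels; when
spots are distributed roughly uniformly their contribution is nearly
constant and does not bias the gradient estimate. A numerically flat plane
(< 1e-6 peak-to-peak) is treated as exactly zero so noiseless inputs pass
through unchanged. If the flags swallow all but one pixel, the statistics
fall back to the full mask.

Dark classification is strict (G < T), so a uniform region at G = T
produces an empty pattern. Coordinates are 0-based row/column; masks are
same-shape booleans.

## Spot model

Spots are maximal 8-connected components (background connectivity for hole
filling is 4-connected — the standard complementary convention). The
pipeline is: label → drop components < 350 px (inclusive minimum; at the
intended photographic scale 350 px ≈ 0.5 mm², below every real spot but
above most artifacts) → fill enclosed holes (4-connected background flood
from the border and out-of-mask pixels) → smooth contours by morphological
closing then opening, 2 iterations of a 3×3 square element → relabel,
re-filter, classify. The closing/opening pair removes granular edge
effects without moving boundaries by more than the 2-px element radius;
the pipeline is idempotent on its own output. A spot is *interior* when no
pixel is 8-adjacent to out-of-mask territory or the image border;
boundary spots are excluded from the size/shape indices because their
geometry is truncated by the mask cut. Qualifying minima (4 interior spots
for limbs, 6 for trunk/tail, none for the head) separate genuinely
patterned regions from faint or absent patterns.

## Indices

Fourteen indices describe one region (sample, n−1, standard deviations
throughout; indices whose defining spot class is empty are NaN — never a
silent zero):

- **FM** — melanistic fraction: total spot area / mask area.
- **SS, SSD** (cm) — full major-axis length of the ellipse with the same
  normalized second moments as the spot, from the pixel coordinates'
  central moments with the +1/12 per-pixel correction (axes 4·sqrt of the
  eigenvalues). Degenerate single-line spots have the minor axis floored
  at the one-pixel equivalent 4·sqrt(1/12). Interior spots only.
- **EE, EED** — major:minor axis ratio (≥ 1). An eccentricity convention
  (sqrt(1 − (b/a)²)) is available via `ee_convention="eccentricity"`; the
  ratio is the default because it is the verbal definition of spot
  ellipticity used with this data. Interior spots only.
- **PL** (cm) — characteristic wavelength: the binary field is cropped to
  the mask bounding box, out-of-mask pixels set to the in-mask mean, the
  mean removed, zero-padded to the next power-of-two square N; the 2-D FFT
  power spectrum is averaged over integer-radius annuli and the peak
  radius r* gives PL = N/r* · cm_per_pixel. Annulus width 1 and the
  argmax over r ≥ 1 are the simplest concretization; all four choices
  (padding, mean fill, annulus width, peak rule) live in one function.
  PL is quantized to N/r values — adjacent patterns can share a PL.
- **MD, MDD** (cm) — per spot, the mean centroid distance to the
  min(3, n−1) nearest other spots, then mean/sd over all spots (boundary
  spots included: their centroids are still informative for spacing).
- **SA, SAD** (cm²) — interior spot areas.
- **SI, SID** — green values pooled over all spot pixels of the original
  photograph (pixel-level pooling, not per-spot means).
- **EL, ELD** — elongation area/(2d²) where d is the number of erosions
  with the 4-connected cross element until the spot vanishes. The cross
  element makes d track the inscribed radius, so a disk gives
  EL ≈ π/2 — a square element would give d ≈ r/√2 and break that
  normalization.

Replicate averaging is the per-index arithmetic mean; an index missing in
a subset of replicates is averaged over the non-missing ones with a
warning, so one bad photograph does not void a body part.

## Distances on pattern space

Mahalanobis: d²(x,y) = (x−y)ᵀS⁻¹(x−y) with S the sample covariance of all
qualifying, complete patterns pooled over body parts. S is inverted
directly; only if its condition number exceeds 1e12 is a ridge
1e-8·trace(S)/14 added (duplicated or constant indices). The metric is
invariant under any fixed invertible affine transformation of pattern
space.

Developmental Noise: d²(x,y) = Σ wᵢ(xᵢ−yᵢ)² with wᵢ the inverse of the
mean over geckos of the two-point variance (FLᵢ−FRᵢ)²/2 between front-leg
patterns, restricted to geckos with qualifying patterns on all four legs.
Back legs never enter the weights. Each wᵢ carries the inverse squared
unit of its index, so per-index rescaling cancels exactly. An index with
identical front-leg values in every gecko would get infinite weight; this
is reported as an error naming the index.

Both distances are reported as squares, scaled so that the mean squared
distance over all unordered pairs of qualifying leg patterns from
different geckos equals 1 (any leg against any leg — the pool is not
restricted to matching leg identities). Within/between summaries for a
body-part pair (A, B) are restricted to geckos with both parts usable:
within is the mean of d²(A_g, B_g); between averages
(d²(A_g, B_h) + d²(A_h, B_g))/2 over unordered gecko pairs — the
symmetric average resolves the ordered/unordered ambiguity of cross
pairs. Patterns with missing indices are excluded from fitting and
evaluation, not imputed.

## Statistical analyses

- **Permutation test** (one-sided, "within < between"): the gecko labels
  of the B-part vectors are uniformly permuted against the A-part vectors;
  the statistic is the within/between ratio; p = (1 + #{null ≤ observed})
  / (1 + n_perm), never exactly zero. Default n_perm = 10,000. Since the
  total of the cross-distance matrix is permutation-invariant, each
  permutation costs O(n).
- **Correlations**: Pearson r; p-values by permutation of one variable
  (two-sided), for consistency with the rest of the nonparametric testing;
  a parametric t option exists. Body-part correlation cells need ≥ 4
  geckos with both parts. Stars at p < 0.05 / 0.01 / 0.001 / 0.00001. No
  multiple-testing correction is applied across cells.
- **PCA** on the correlation matrix (the 14 indices mix cm, cm² and
  dimensionless quantities, so standardization is required); components
  ordered by eigenvalue, sign fixed by making the largest-magnitude
  loading positive.
- **Coefficient of variation**: sample sd / mean per index, per body part
  and pooled; NaN for zero means.
- **Replicate error**: per region, the mean squared distance of replicate
  index vectors from their centroid, aggregated per body part and set
  against the part's between-individual distances and, for legs, the
  within-individual left–right distance.
- **Sides × individuals ANOVA** (sides fixed, individuals random,
  balanced): F_sides = MS_S/MS_SI tests directional asymmetry,
  F_interaction = MS_SI/MS_E tests fluctuating asymmetry against
  measurement error; df = (n−1, 1, n−1, 2n(r−1)); the SS decomposition is
  exact (additivity to 1e-9 is a test invariant).
- **Hierarchy check**: per gecko, the implications {any leg patterned ⇒
  trunk patterned} and {trunk ⇒ head and tail patterned}, with violation
  counts and violators.

## Synthetic data: what it emulates

`generate_pattern` rasterizes dark ellipses at a jittered hexagonal
lattice inside a rectangle/ellipse/limb-shaped mask. The hexagonal lattice
(rather than a Poisson process) guarantees a true characteristic
wavelength for validating PL: for nearest-neighbour spacing a the first
reciprocal-lattice ring lies at the row spacing (√3/2)·a, and the truth
record stores both numbers; PL recovery is judged against the spectral
wavelength. Non-overlap (a ≥ 5-px gap, so the 2-iteration closing can
never merge spots) is enforced by per-spot rejection with up to 100
redraws, keeping the true count and per-spot geometry unambiguous.
Rendering draws per-pixel Gaussian noise per channel (background green
180 ± 8, spot green 45 ± 8 by default), with spots nearly invisible in
blue, an optional planar shadow gradient and an optional glare bump.

Default single-region geometry: spots with semi-major ~14 px (lognormal,
sd 0.08 in log), axis ratio ~1.3, lattice spacing 40–50 px, regions of
130×170 to 170×230 px at 0.004 cm/px — scaled-down relative to real
photographs (real regions are thousands of pixels across) so that a full
cohort is generated and measured in seconds, while every pipeline stage
still operates far from degenerate limits (spots ≈ 400–900 px against the
350-px filter).

`generate_cohort` layers the biological structure on top: a per-gecko
latent vector (log spot size, log spacing, spot intensity, log axis
ratio) drawn from a multivariate normal (sds 0.20/0.10/8.0/0.08, size and
spacing correlated 0.5), deterministic body-part offsets (head and tail
spots 1.15× larger and wider-spaced than legs), independent per-part
developmental noise (sds 0.05/0.03/3.0/0.02, globally scaled by
`dev_scale`), and per-replicate rigid sub-pixel translations (≤ 3 px)
plus fresh pixel noise. Spot parameters are drawn per lattice site from
seeds keyed to the region, so replicates re-rasterize the *same* spots at
an offset, as repeated photographs do. Geckos with extreme size draws get
their lattice widened to keep the packing feasible. The genetic spread is
set well above the per-region sampling noise (a region carries only
10–20 spots, so index estimates are noisy) — this is what makes
between-individual distances exceed within-individual ones at low
developmental noise and makes the within/between ratio rise monotonically
with `dev_scale`, the structure the cohort exists to emulate.

What passing the synthetic tests does **not** show: robustness to
non-planar illumination, color calibration drift, motion blur, imperfect
hand-cut masks, stripes or labyrinthine patterns, or merged/overlapping
spots — real photographs can contain all of these, and the pipeline's
behaviour there is only as good as the thresholding and smoothing rules.

## Problem sizes used in the checks

The end-to-end acceptance checks run a 25-gecko cohort (7 parts × 4
replicates = 700 images) at the default scaled-down geometry, recover SA
and EE within 5%, PL within 10% and FM within 0.02 of ground truth on
average, and verify that the within/between ratio increases across
developmental-noise scales 0.3/1.0/3.0 on leg-only cohorts (12 geckos, 2
replicates, 1.3× region scale). Permutation-test calibration uses 1,000
null datasets of 10 geckos at n_perm = 500. These sizes were chosen as the
smallest at which the estimates are stable.

## Known limitations

- The threshold statistics after artifact exclusion can rest on few pixels
  for strongly bimodal limb images; the full-mask fallback then applies.
- PL is quantized to N/r values (one annulus step ≈ 5–15% at these region
  sizes) and is NaN for spotless or fully dark regions.
- The interior-spot rule (no 8-adjacency to mask boundary) is a simple
  stand-in for more elaborate boundary-exclusion rules; with small regions
  it can classify a large fraction of spots as boundary.
- `sides_anova` requires a balanced design; regions with missing
  replicates are skipped rather than imputed.
- The Developmental Noise metric needs at least one gecko with all four
  legs patterned; otherwise only the Mahalanobis metric is produced (with
  a warning).
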