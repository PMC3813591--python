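# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic generator does and does not emulate, and
the known limitations.

## Conventions

0-based (row, col) pixel indexing; 8-connectivity for all connected
components; area = pixel count × `pixel_size_um`² with a default lateral
sampling of 0.12 µm/px. Intensities are arbitrary camera units (a.u.).
All randomness flows through `numpy.random.default_rng` seeded from the
scene or run configuration, so identical configurations produce
bit-identical images, tables and truth.

## Synthetic scene model

The generator renders one confocal slice at the cell–glass contact plane:

* **Stripes.** The stamped class occupies the fraction
  `stripe_fraction_stamped` of each `stripe_period_px`-pixel period along
  the stripe normal; orientation is arbitrary. The stripe channel is
  `stamp_level`/`overlay_level` plus noise; the true stamped mask is kept
  noiselessly.
* **Cells.** Footprints are pixelated ellipses with effective radius
  `cell_radius_um` (default 7.3 ± 0.8 µm, i.e. ~170 µm² contact area) and
  axis ratio uniform in [1, 3]. Placement is rejection sampling with a
  one-pixel separation so connected-component counting recovers the
  planted number; after a bounded budget (500 attempts per cell) a
  "frame too crowded" error is raised. Cells may be clipped by the frame
  edge (as in real fields) down to 60% of their nominal area.
* **Surface preference.** `surface_preference = s` is the odds multiplier
  for a cell pixel to land on the stamped class. It is realized by
  shrinking the footprint's chords on the non-preferred class by 1/s
  *along the stripe direction*. Because every stripe-parallel chord lies
  in a single stripe class, this yields the expected on-stamped pixel
  fraction s·f/(s·f + 1 − f) exactly (f = stamped area fraction) while
  keeping footprints connected. With an active preference, edge clipping
  is restricted to the across-stripe direction: cutting whole chords is
  phase-uniform and leaves the odds ratio unbiased, whereas lengthwise
  clipping would shorten the full-length preferred chords more than the
  already-shrunk ones. The default preference of 1.5 reflects the clear
  spreading preference for costimulatory stripes seen in this system.
* **Clusters.** Within each cell and stripe class, cluster counts are
  Poisson with rate `cluster_density_per_100um2[(population, surface)]`
  × area/100. The defaults (8.9–11.7 per 100 µm², higher on the stamped
  = costimulatory class) are the measured phosphotyrosine magnitudes in
  this system. Spots are isotropic Gaussians of sd `cluster_sigma_um`
  (default 0.15 µm, ≈ 1.25 px — a diffraction-limited spot), amplitude
  normal (default 80 ± 20 a.u.) truncated at zero, added on top of a
  diffuse in-cell level (default 15 a.u.) and a global camera offset
  (default 10 a.u.).
* **Tracer.** Labeled-cell footprints carry `tracer_level` (default 300)
  clipped at `tracer_clip` (default 255), i.e. recorded saturated, which
  is how CFSE is typically acquired; thresholding therefore defaults to a
  fixed low value rather than Otsu.
* **Noise.** Additive Gaussian (default sd 3 a.u.) plus an optional
  signal-proportional variance term; channels are clipped at zero.
  Against the default spot amplitudes this gives a generous but realistic
  single-spot SNR.

Default frames are 512 × 512 px with 8 cells. This is a scaled-down field
of view chosen so that a full per-image pipeline pass takes ~2 s; all
per-area and per-cell statistics are size-intensive, so conclusions do
not depend on the frame size, but edge clipping is relatively more common
than in large fields, which lowers the mean *visible* contact area per
cell below the nominal π r² (≈ 130 µm² measured vs 167 µm² nominal at
defaults).

**What the generator does not emulate:** touching or overlapping cells
(excluded to keep per-cell truth unambiguous — real fields contain them,
and connected-component counting merges them), cluster motion or
maturation over time, non-uniform illumination, stripe-printing defects,
and out-of-focus light. Passing tests therefore demonstrate correctness
of the measurement machinery under the stated image model, not robustness
to every artifact of real microscopy.

## Mask decomposition

The stripe channel is thresholded (Otsu by default, fixed value
configurable; the brighter class is taken as "stamped" with the
stimulus assignment coming from per-image metadata), the immunolabel
channel gives the mask of all cells (Otsu, hole filling, removal of
objects under `min_object_px`), and the tracer splits cells into
labeled/unlabeled. The six combo masks are exact intersections, and the
partition invariants (areas sum to the frame; intensities conserve) are
asserted rather than assumed. "Bit-exact" intensity conservation is
checked with correctly-rounded summation (`math.fsum`), since ordinary
float summation is order-dependent.

Cell counting is automated as 8-connected components with at least
`min_cell_area_um2` (default 30 µm²) — a deliberate replacement for
manual counting; touching cells count as one, a documented limitation.

## Microcluster detection

A regional maximum is a connected equal-value plateau with no higher
neighbor inside the cell mask; its representative pixel is the
lexicographically smallest of the plateau. Its prominence is the height
drop to the highest saddle connecting it to higher terrain; the global
maximum of a mask component uses peak − min, so flat regions yield
nothing. Maxima with prominence strictly above the noise tolerance are
reported. Two equal maxima that merge before meeting higher terrain
share their deeper saddle and are both reported. The implementation is a
level-by-level union-find sweep; the test suite proves set equality with
an independent exhaustive search on hundreds of random images.

The default tolerance is 5 × (1.4826 × MAD) of the in-cell pixels — a
robust noise sd estimate — so it transfers across intensity scales.
Footprints are peak-seeded super-level sets at peak − tolerance, capped
at 0.5 µm radius; contested pixels go to the higher peak, then the nearer
one, then the lexicographically smaller peak coordinate. A maxima-only
mode (`segmented=False`) uses single-pixel footprints. Clusters are
classified by the (population, surface) of the center pixel — the
simplest reproducible rule for edge-straddling clusters; cluster-pixel
intensities are corrected with the surface-specific background (a config
switch in principle could use a global background; surface-specific is
the default because stripe chemistry affects the cell-free level).

Detection recovers essentially all isolated planted spots; residual
count error (~3–5% at the default densities) comes from pairs of planted
clusters closer than the diffraction limit, which merge into a single
maximum. This loss is intrinsic to any intensity-based detector at this
sampling. Because it grows with density, it slightly compresses
between-condition density contrasts: a planted ~24% surface effect on
cluster density is recovered as ~21% by the full pipeline, while
density-independent quantities (intensities, areas, SPS) are unaffected.

## Statistics

Within each image, every property is divided by the mean over the
(strain × stimulus) combos present, so the per-image mean of normalized
values is exactly 1 and images/experiments with different staining
efficiency pool on a common scale. Missing combos are simply absent from
the denominator; zero-mean groups are flagged and excluded.

Effects are estimated on the pooled normalized values with an additive
two-factor linear model in sum-to-zero coding. A factor's effect is the
difference of its two model-predicted level means (= twice the level
coefficient for a 2-level factor, balanced or not), divided by the
overall mean of the response (≈ 1 after normalization); the 95% CI comes
from the coefficient's standard error, and the "corrected model" p is
the joint F test of both factor terms. A refit with the product term
reports the interaction p.

Because the normalization fixes each image's combo mean, the four values
of one image are negatively correlated (−1/3 for a complete image), and
a plain two-factor fit underestimates the residual variance relevant to
the factor contrasts by a factor 3/4 — inflating the type-I error to
~9% and shrinking CI coverage to ~91%. The model therefore includes the
image as a blocking factor by default (`block_by_image=True`): with a
balanced 2×2 per image the effect estimates are unchanged, but standard
errors, coverage and type-I error return to nominal, which the
simulation tests verify. The plain model remains available via
`block_by_image=False`. The unit of replication is the image throughout;
cell-level values are aggregated within image first.

Assumption checks follow the standard recipe: one-sample KS of each
subgroup against a normal with the subgroup's own mean/sd (estimating
the parameters makes this conservative — simulated pass rates run above
the nominal 95%), Levene across subgroups, subgroups with n < 3 or zero
variance flagged and skipped. Per-cell metrics (clusters per cell,
intensity per cell, contact area per cell) have no surface split and are
compared between strains with equal-variance two-sample t tests (Welch
via `equal_var=False`); the surface-preference score is tested against 1
with a one-sample t test per strain. Bonferroni correction
(p·m capped at 1) is applied where a family size is configured.

The SPS is always computed per image as stamped-vs-overlay and
reoriented to a fixed reference stimulus before pooling, so experiments
with swapped stamp/overlay configurations combine consistently — the
same mechanism that lets the dataset simulator cycle swapped
stamp/overlay and swapped tracer assignments while keeping the
(strain, stimulus) truth invariant.

## Degenerate inputs and tie-breaks

Otsu on a constant channel raises a "degenerate threshold" error rather
than returning an arbitrary mask; a stripe class with no cell-free
pixels raises an error advising a fallback background constant; zero
cell counts flag per-cell metrics as missing (NaN), never zero; zero
variance in a t test is an error unless the statistic is exactly zero;
an empty cell of the 2×2 design raises an error naming the missing cell.
All spatial tie-breaks (plateau representatives, contested footprint
pixels) resolve lexicographically so runs are reproducible to the byte.

## Problem sizes used in the checks

The test suite and the acceptance script use 20 default-sized fields for
ground-truth recovery, 200 random 64×64 images for oracle equivalence,
500 simulated 10-image experiments for SPS type-I control, 300 images
for SPS convergence, and 200 (coverage) + 1000 (type-I) simulated
40- and 10-image experiments for the ANOVA checks; the acceptance script
runs a 16-image experiment cycling all four swap configurations. These
sizes give binomial/Monte-Carlo standard errors comfortably inside the
asserted bands while keeping a full run in minutes on one CPU.
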