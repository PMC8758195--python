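# Methods

## The inference problem

A maternal eggshell signature is a hen-specific, within-clutch-consistent
combination of maculation, colour and shape traits.  Given standardized
photographs of eggs from many nests, plus nest coordinates, first-egg dates
and fates, the pipeline asks: which pairs of clutches share a mother, and
what does each shared-maternity pair mean — a female returning between
years, a conspecific brood parasite, or a within-season renest?

The chain of evidence is deliberately conservative.  Pattern matching alone
never asserts shared maternity; it nominates candidate nest pairs, which are
then gated by spatial and temporal criteria and, for Tier I, explicitly
flagged for human visual review rather than auto-confirmed.

## Pattern matching

**Keypoints and descriptors.**  Maculation features are detected with
scale-space difference-of-Gaussians and described with 128-dimensional
gradient-histogram descriptors (SIFT, scikit-image), restricted to
keypoints at least 3 px inside the segmented shell (the shell outline
itself produces edge responses that are not maculation).  Calibration on
synthetic discs shows the detector's reported sigma is an absolute scale
with sigma ≈ 0.64 × blob radius, so keypoint scales are stored in
millimetres via the image's physical scale.

**Why plain SIFT is not enough.**  SIFT descriptors are normalised to be
invariant to contrast and scale.  Those invariances are exactly wrong for
maternity assignment: spot size, spot darkness, shell ground tone, the
pole-ward concentration of pigment and egg shape are the hen-specific
traits a signature consists of.  Each descriptor is therefore augmented
with weighted appearance columns before matching:

| column | meaning | weight (default) |
|---|---|---|
| 128-d SIFT (unit norm) | local spot texture | 1 |
| log2 keypoint scale (mm) | physical spot size | 2 |
| axial position in [0, 1] | where along the long axis the spot sits | 0.5 |
| local tone / 255 | spot darkness | 4 |
| ground tone / 255 (per egg) | shell background colour | 4 |
| mean axial position (per egg) | polar concentration | 1 |
| log2 feature count (per egg) | spot density | 0.5 |
| median log2 scale (per egg) | typical spot size | 1 |
| egg aspect ratio (per egg) | shape | 5 |

Weights express how many units of descriptor distance one unit of each
appearance difference is worth; they were fixed during method development
on synthetic populations and are configurable (`FeatureConfig`).

**Dissimilarity.**  Two eggs are compared by the modified-Hausdorff
distance between their augmented descriptor sets: the mean
nearest-neighbour distance in each direction, symmetrised by the maximum.
It is zero for identical sets, symmetric, non-negative, and robust to
unequal feature counts.  A mutual-nearest-neighbour matched-fraction score
with a ratio test was implemented first and rejected: on synthetic
populations its matched-fraction term is noise-dominated (within-hen
best-match rates of 0.25–0.33 versus ≈ 0.98 for the adopted form), because
individual spot descriptors are only weakly diagnostic and the informative
signal lives in the aggregate distance.  Eggs with zero detected features
are excluded from match graphs (their dissimilarity is undefined) and
logged; against a non-empty egg the defined maximal score (10.0) is used.

**Scale handling.**  Optional resampling of every egg to a fixed long-axis
pixel length is available but off by default: physical-unit keypoint
scales already make differently-scaled photographs comparable, and
resampling images that share a scale only injects interpolation noise
between eggs of the same hen (measurably worse matching and false-link
rates on synthetic data).

## Pigment index

Images are converted to 8-bit grayscale (luminance weights
0.299/0.587/0.114), the egg is segmented by Otsu's threshold with hole
filling and a convex hull (the shell is convex; dark maculation touching
the outline otherwise leaves notches), and Bernsen local thresholding is
applied: per pixel, threshold = (local max + local min)/2 over a square
window (default radius 15 px), with pixels in windows of contrast below
the limit (default 15) assigned to background.  The original protocol
names Bernsen but not its parameters, so all reported percentages are
conditional on these defaults and both are configurable.

The measured region is an oval inscribed in a standardized 3.4 × 2.4 cm
block converted to pixels at the image scale, centred on the egg's column
centroid and slid inward from the large pole just far enough to lie
entirely inside the shell (a 1 px inset keeps the thresholding's dark rim
out of the count).  The rasterised oval uses an integer centre, so its
pixel area is identical for every egg at the same scale; eggs physically
too small for the block raise an error and are excluded from pigment
analysis (mirroring the field protocol's choice of a block that fit the
smallest egg measured there).

## Discrimination statistics

Egg vectors combine length, width, optional mass, percent black, feature
count, largest-feature scale and dominant orientation (circular, encoded
as a sin/cos pair).  Distances are Euclidean on z-scored columns; a
constant column is an error naming the column.  PERMANOVA is implemented
from Anderson's squared-distance partition: SS_total = Σ_{i<j} d²/N,
SS_within pooled per group, R² = SS_among/SS_total, pseudo-F with
(k−1, N−k) degrees of freedom, and p = (1 + #{F* ≥ F})/(1 + n_perm) under
label permutation (seed required; exhaustive enumeration available for
n ≤ 9).  scikit-bio's PERMANOVA serves as an independent cross-check in
the test suite, never as the implementation.  NMDS is non-metric SMACOF
(scikit-learn) reporting Kruskal stress-1 and a convergence flag;
non-convergence is flagged, not raised.  LDA (scikit-learn) reports both
resubstitution and leave-one-out percent correct — published analyses of
this kind rarely state which validation they used, so both are given —
with constant covariates dropped (warning) and shrinkage applied when the
within-group covariance is singular (flagged).

## Decision tree

Evidence per nest pair, computed on one batch (a year, a region across
years, or everything):

* `n_symmetrical` — reciprocal best-match pairs between the clutches;
* `n_multi` (per direction) — eggs of one clutch whose best match lies in
  the other;
* top-k tally (per direction) — occurrences of the other clutch among the
  top-k ranked matches of the query clutch's eggs (k = 8 by default, the
  population's average clutch size; both the egg-count and
  total-occurrence tallies are computed, the threshold applies to total
  occurrences).

Tiers (mutually exclusive, I first):

* **Tier I**: `max-direction n_multi ≥ 2` AND (`n_symmetrical ≥ 1` OR
  distance ≤ 150 m).  Requiring two matching eggs besides the
  symmetry/proximity criterion follows the published case table, in which
  every reported pair had at least two eggs match on two criteria; a
  single chance reciprocal pair is not evidence.  Tier I results carry
  `requires_visual_review=True` — the human inspection step is part of the
  method and is never auto-resolved.
* **Tier II**: some single direction has `n_multi ≥ 2` AND tally ≥ 4
  (same-direction, because the published criterion counts matches for the
  query clutch).  IIa between years, IIb within a season.

Link classification: different years → returning breeder (year-level only
when first-egg dates are missing); same season with first-egg dates within
21 days ("within three weeks") → CBP; gap ≥ 42 days with the earlier nest
depredated or deserted → renesting attempt (the threshold sits below the
published ≈ two-month renest example with a buffer); anything else —
including gaps in (21, 42) days and undated same-season pairs — is
`unclassified` and flagged.  Missing or qualitative dates ("Early May",
"5/13-15/2012?") parse to flagged approximate values and never raise.

Defaults: proximity 150 m (published Tier I distances are 33–91 m),
k = 8, tally ≥ 4, synchrony 21 d, renest gap 42 d — all in `TierParams`.

## Synthetic data

Each hen is an independent draw of: spots per egg (log-uniform 30–300),
mean spot radius (log-uniform 0.4–1.8 mm, log-normal spot-to-spot
variation with CV 0.2–0.7), expected pigment coverage capped at 40 % by
shrinking the radius (heavily saturated shells have no distinct features
to detect, and real maculated eggs are not solid dark), polar bias
(uniform 0–1; spot intensity rises linearly toward the large pole),
ground tone (140–235), spot contrast below ground (50–150), and egg
length/width (normal, 41 ± 2.5 mm × 30 ± 1.5 mm).  Eggs of one hen jitter
every parameter with a within-clutch CV of 0.02.  These defaults encode a
*strongly signatured* population — low within-clutch, high among-clutch
variance — which is the regime the method presumes; the within-clutch CV
is the single knob that weakens signatures, and the match rate falls
monotonically as it grows.

Eggs render as vertical ellipses (large pole up — the ROI convention) on a
dark board (tone 45), spots as filled discs with σ = 1 px Gaussian edge
blur so gradients are detector-friendly, at 0.2 mm/px.  Clutch sizes are
uniform on 7–9 (population mean 8, consistent with the average clutch size
that motivated k = 8).  Nests scatter in two 3 km regions 10 km apart;
planted links place returning-breeder nests ≤ 100 m apart across years,
CBP hosts 200–800 m from the parasite's own synchronous nest (first-egg
gap ≤ 7 d, 1–2 parasitic eggs), and renests 45–60 d after a depredated or
deserted first nest.  All randomness derives from one seed; identical
configurations reproduce byte-identical datasets.

**What the generator does not emulate** — and therefore what passing tests
do not show about field data: photographic nuisance variation (lighting,
film/scanner differences, shared per-clutch backgrounds, which in real
clutch photos both help and confound matching), dirt and repair artefacts,
non-elliptical egg geometry, heritable signature similarity among related
hens, and the true (unknown) overlap structure of wild hen signatures.
Synthetic recovery rates are an upper bound on field performance and are
read as validating the *machinery*, not the field power of the method.

## Simulation sizes and numerical choices

Long-running suites use desk-scale populations chosen as the package's own
test sizes: null calibration runs 20 unique-hen populations of 10 clutches
(false-link bound: one pair per 60 clutches, i.e. ≤ 3 pairs over 200
clutches); recovery runs 10 populations of 11 clutches with one planted
link of each type (precision and recall ≥ 0.8 pooled).  Ties in ranked
match lists break lexicographically by egg id; PERMANOVA permutation
p-values are bit-reproducible under a fixed seed; Bernsen output is
required to equal a brute-force sliding-window oracle exactly.

## Known limitations

* The matcher's appearance weights are development-time constants, not
  fitted quantities; grossly different imaging conditions would need a
  re-weighting.
* Percent-black values are Bernsen-parameter-conditional; comparisons are
  only meaningful within one parameter set.
* The published dataset-level statistics (per-year PERMANOVA tables, LDA
  accuracies on the field photographs) are not reproducible without the
  original images and are out of scope; the statistics are validated by
  oracles and null simulations instead.
* Heritability of signatures among kin — an alternative explanation for
  between-nest matches — is not modelled.
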