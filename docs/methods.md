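# Methods

## Problem setting

Toxicologic pathology workflows for drug-induced liver injury quantify how
much of a liver section is occupied by each histological finding. The
pipeline here operates on large RGB slide rasters (the source material is
20× Aperio scans at 0.4993 μm/px, cropped to 10,752 × 10,752 px) annotated
with polygons in VGG Image Annotator (VIA) 2.x JSON. Six findings are
recognised at tile level: portal area and connective tissue (normal
features), and infiltration, necrosis, fibrosis and vacuolation (lesions).
At slide level fibrosis and connective tissue are merged into one combined
group, because a pathologist cannot reliably tell them apart at that scale;
quantification therefore uses five groups.

## Geometry and rasterization

Coordinates are 0-based with x = column, y = row (the VIA convention);
polygon vertices may be continuous. A polygon's raster is defined by the
pixel-centre even-odd rule: pixel (r, c) is inside iff the point
(c + 0.5, r + 0.5) lies inside the polygon. This rule is the package's
area contract — all pixel counting, clipping-conservation guarantees and
truth/raster consistency hold exactly under it. The implementation is a
vectorised scanline crossing-number fill with the half-open edge
convention (a centre exactly on an edge is resolved deterministically;
with continuous random vertices this is a measure-zero event). The test
suite checks it against an exhaustive shapely point-in-polygon oracle on
every pixel centre of random simple polygons.

Same-finding polygon overlaps are unioned before counting (no double
counting); cross-finding overlaps are preserved at tile level and resolved
only by the slide-level priority rule.

## Tiling and splitting

Tiles are cut on a strict non-overlapping grid (448 px default). Polygons
are clipped to tile windows by exact box intersection (shapely); because
tile boundaries sit on integer coordinates and pixel centres on
half-integers, a pixel centre is inside a clipped piece iff it is inside
the original polygon, so per-finding pixel counts are conserved across the
grid and restitching tile rasters reproduces the slide bit-exactly.
Degenerate clipped slivers (zero area or fewer than three distinct
vertices) are dropped and counted in the log. Slides that do not divide
evenly are rejected unless pad mode is enabled (right/bottom zero fill).

The train/validation/test split is a seeded uniform shuffle sliced at
rounded 7:2:1 boundaries, so realized sizes are within one of
round(n·ratio) and a fixed seed is byte-reproducible. Splitting acts on
tiles, matching the upstream workflow; an optional `by_slide` flag assigns
whole slides to one subset as a leakage control (off by default).
Background-only tiles are kept.

## Augmentation

"Eight-fold" is interpreted as the full dihedral group of the square: four
rotations × optional horizontal reversal, the identity included as fold 1.
Each fold receives an independent multiplicative brightness factor drawn
from [0.9, 1.1] (config-exposed), clipped to valid intensities.
Annotations undergo exactly the raster's geometric map — on an n-px square,
reversal is x → n − x and a quarter-turn is (x, y) → (y, n − x) — which
maps pixel centres to pixel centres, so rasterize∘transform =
transform∘rasterize holds exactly and per-finding pixel counts are
invariant. Brightness never touches geometry. Brightness-only duplicates
are not counted as folds.

## Segmentation backend

The backend contract is an instance prediction: binary 448² mask, finding,
confidence in [0, 1], and a tight bounding box. One multi-class segmenter
(MFM) or a composition of six single-class segmenters (SFMs, one
independent pass each) may be run; predictions below the detection
threshold (0.5) are discarded before merging, with the boundary kept
(score ≥ threshold). The filter is idempotent and monotone in the
threshold.

The built-in toy segmenter is deterministic and weight-free: per declared
class it thresholds the tile by euclidean RGB distance to a rule colour
(default tolerance 40), assigns each candidate pixel exclusively to the
nearest declared colour when several classes are declared (ties broken by
declaration order), takes 8-connected components, drops components below
20 px (speckle suppression), and scores each component as 1 − mean
distance / tolerance. The exclusive assignment makes colour ambiguity a
genuine inter-class competition in MFM mode, while single-class SFMs claim
everything their rule matches — the two failure modes real single- and
multi-class models exhibit. A ground-truth replay segmenter (confidence
1.0) provides the perfect-oracle limit. External models integrate through
the same contract or through a per-tile JSON interchange format
(run-length-encoded masks), so a GPU-trained network can feed the pipeline
offline; nothing downstream depends on model internals.

## Slide merging and priority resolution

Tile masks are translated by their tile origin and OR-ed into their slide
group's mask (fibrosis → combined connective group), without resampling;
instance identity is dropped because slide-level quantification is by
area. Overlaps between groups are resolved per pixel by the fixed priority
order necrosis ≻ connective tissue (incl. fibrosis) ≻ infiltration ≻
portal area ≻ vacuolation; unclaimed pixels are background. Resolution is
idempotent, independent of mask iteration order, and equals a per-pixel
first-claim-in-priority-order oracle.

Ground-truth annotations pass through the same merge map and priority
resolution as predictions. Whether the original pathologist annotations
contained cross-class overlaps needing this rule is unknowable from the
published description; symmetric treatment guarantees both sides of the
area comparison are measured under one rule, and is a no-op when ground
truth has no cross-class overlaps.

## Evaluation

Matching is greedy, per class, at IoU ≥ 0.667: predictions are visited in
descending confidence (ties broken by larger best-candidate IoU, then
input position) and claim the unmatched same-class ground truth of highest
IoU. Average precision is all-point: precision/recall is evaluated at
every distinct score cutoff and integrated under the monotone precision
envelope (an 11-point variant is available behind a flag). IoU is the
standard |A∩B| / |A∪B| and is undefined (an error) for two empty masks.

Aggregation is per image: a class's AP is the mean of per-image APs over
images holding that class, and mAP is the unweighted mean over classes —
the Matterport-style evaluation convention. The transformed mAP zeroes
every image containing a misprediction (any false positive, by class or by
IoU failure) before averaging. Under this construction transformed mAP ≤
mAP always, with equality when no image is flagged; the converse can fail
only degenerately (an image whose AP is already zero gains an FP). Classes
with no ground truth anywhere are excluded from the mean and logged.

Slide-level concordance is ordinary least squares of predicted on
annotated per-group pixel counts across slides (scipy linregress; slope,
intercept, R²), requiring at least three slides and nonzero annotated
variance per group.

## Synthetic slides

The generator emulates the four treatment-group lesion profiles: control
(normal features only), NDMA (fibrosis), APAP (necrosis + infiltration)
and corn oil (vacuolation); every slide carries portal areas and
connective tissue. Regions are sampled polygon-first — a simple
star-shaped polygon (optionally anisotropic for band-like
fibrosis/connective strands, or clustered small blobs for infiltration) is
rasterized with the package's own fill rule and painted — so the stored
truth polygon reproduces the painted footprint exactly, a stronger
guarantee than tracing contours after painting. Placement uses rejection
sampling with a one-pixel dilated exclusion zone, keeping instance
footprints 8-connectivity-separated so connected components correspond
one-to-one with truth instances.

Each finding is painted in a distinct colour family with ±6 per-channel
uniform jitter over a pink parenchyma background (±4 jitter); the palette
keeps every inter-class colour distance above the toy segmenter's
tolerance, making the toy backend near-perfect by construction. A
"confusable" palette paints fibrosis in connective tissue's colour family
to reproduce the known fibrosis/connective discrimination failure: the
six-class tile-level AP for that pair collapses (the MFM mislabels by
exclusive assignment, SFMs cross-claim), while merged-group slide areas
remain accurate in both modes — which is precisely the argument for
merging the two findings at slide level. Confusing two findings that share
a slide group cannot, by construction, change that group's pixel union, so
no group-level R² degradation should be expected from this palette.

Lesion burden defaults (counts and equivalent diameters per group) are
free parameters chosen once at desk-scale realism for a 2,240² canvas
(e.g. 3–6 necrosis blobs of 120–220 px, 8–16 vacuolation blobs of
25–60 px); region counts are per-slide constants independent of canvas
size. The default synthetic slide is 2,240² (a 5 × 5 tile grid) for speed;
full 10,752² slides (24 × 24) generate on demand. The cohort default
mirrors the study design of 25 sections per group, with per-slide seeds
derived deterministically from one master seed.

What the generator does **not** emulate: nuclei-level morphology, stain
variation and deconvolution physics, scanner artefacts, diffuse or
gradient lesions, and cross-class spatial correlation. Passing tests
therefore demonstrate the correctness of the pipeline machinery (tiling,
clipping, merging, metrics) and the internal consistency of the evaluation
stack — not segmentation performance on real H&E tissue, which depends
entirely on the plugged-in model.

## Problem sizes used in checks

The automated checks run the augmentation on single tiles, tiling on one
full-size 10,752² slide, the perfect-oracle limit on a 20-slide 2,240²
cohort, AP-oracle equivalence on 200 random instance configurations,
priority resolution on random 48² mask stacks, the split contract on
1,000 tiles, and the end-to-end toy run on a 4-group × 5-slide 2,240²
cohort — sizes at which every guarantee above is exercised in full while a
complete run stays in the minutes range on one CPU.

## Known limitations

- The rasterizer's half-open boundary convention can disagree with a
  strict-interior oracle for vertices placed exactly on pixel centres;
  irrelevant for continuous coordinates.
- Polygon clipping assumes simple (non-self-intersecting) polygons;
  invalid rings are repaired via shapely's buffer(0) heuristic.
- SFM composition treats the six single-class segmenters as independent;
  no cross-model score calibration is attempted.
- The transformed-mAP reading (zero an image's contribution on any false
  positive, aggregate per image) is one of several defensible
  interpretations of a one-sentence definition; the pooled ranked-list AP
  primitive is exposed separately for alternative aggregations.
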