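# Methods

## Scope and model

The package quantifies two fluorescently labeled cell populations —
pericytes (DsRed) and microglia (GFP) — against all nuclei (DAPI) in
2-D multi-channel section images. The underlying model is deliberately
simple and fully thresholded: tissue and vessels are pixel-threshold
classifiers on smoothed channels; cells are DAPI-thresholded,
watershed-split nuclei expanded by a fixed ring; positivity is an
inclusive (`>=`) threshold on the mean raw intensity over the cell
region. No morphology, no trained classifiers. The scientific weight is
carried by how the thresholds are chosen: a grid sweep scored against
manual counts via `%difference = ((Ac − Mc)/Mc) × 100`, selecting the
grid value with the smallest |mean| across test annotations, ties by
smaller SD, then by a preference for undercounting (false negatives
over false positives), then by the larger threshold. The tie-break
cascade is a codified stand-in for what is, in practice, partly a
visual judgment; it is deterministic and auditable (the full ranking is
returned with every selection).

Percentages are reported with dual-positive cells included in the
denominator (the four classes partition all detections); dual cells
are never added to the pericyte or microglia tallies.

## Coordinate and convention choices

* Rasters are `[row, col]`, origin top-left, y down; pixel `(i, j)`
  covers the half-open square `[j, j+1) × [i, i+1)`; physical units
  only via `pixel_size_um`.
* Polygon rasterization tests the pixel **center**; polygons sharing a
  boundary rasterize to disjoint masks.
* All intensity comparisons are inclusive (`>=`). At the sweeps' grid
  resolution of 25 counts the choice is immaterial, but it is fixed.
* Point-in-polygon counting of ground-truth centroids uses shapely
  `covers`: a centroid exactly on the boundary counts as inside.
* Erosion by a disc of radius r is implemented as
  `distance_transform_edt(mask) > r_px`, which is exactly erosion by
  the inclusive Euclidean disc (verified against the
  structuring-element oracle in the tests).
* Cleanup order in the mask classifiers: threshold → fill holes
  (< min hole area) → drop components (< min area) → erode → drop
  fragments (< min fragment area). Hole filling is the only stage that
  adds pixels, and only strictly inside components.

## Detection operator chain

`detect_nuclei` runs: optional resample to a requested working pixel
size → optional median filter → optional rolling-ball background
subtraction (disabled by default: genetically encoded reporters give a
clean signal) → Gaussian smoothing (default sigma 1.5 px) → inclusive
threshold → fill single-pixel holes → distance-transform watershed →
area filter (default 10–400 µm²) → keep detections whose nucleus
centroid lies in the analysis mask → sort by (y, x) and relabel.
Watershed seeds are local maxima of the distance transform separated by
at least `sqrt(min_area/π)` µm within each connected component; a
merged pair presenting a single maximum stays one detection — a known,
deliberate failure mode of automated counting that the synthetic data
also exercises.

Cell expansion uses the nearest-label partition
(`skimage.segmentation.expand_labels`) clipped to the analysis mask,
with nucleus pixels always retained, so nucleus ⊆ cell and cell regions
are pairwise disjoint by construction. Intensity means are taken over
the **raw** channels, never the smoothed ones.

When an image is resampled for detection, the label rasters are mapped
back to the native grid (nearest neighbor) so expansion and measurement
stay aligned with the raw pixels. This is what makes percentages and
densities invariant (to within a few percent) when the same physical
section is rendered at 1 vs 2 µm/px.

## The synthetic section generator

The generator is the package's ground truth and defines the study
conditions; its defaults are frozen:

* **Geometry.** 2 × 2 mm sections at 1 µm/px; a tissue rectangle inset
  80 µm from the border; four rectangular regions (cortex,
  hippocampus, thalamus, hypothalamus) with ≥ 160 µm clearance from
  the border so they sit outside the brightened edge band.
* **Densities.** 1500 / 2100 / 1250 / 1400 nuclei per mm² (cortex /
  hippocampus / thalamus / hypothalamus) — chosen so a 300 × 200 µm
  test annotation holds roughly 50–150 nuclei, the range a manual
  counter actually faces.
* **Class fractions.** Pericytes 2.68 / 1.77 / 6.20 / 2.37 % and
  microglia 5.54 / 4.05 / 3.99 / 3.23 % of nuclei per region: the
  regional contrasts the pipeline is expected to recover (thalamus
  pericyte-rich, cortex microglia-rich).
* **Intensity model.** Arbitrary 16-bit-like counts. Backgrounds
  (DAPI/DsRed/GFP): 60/80/45 inside tissue, 5 outside. Nuclei are
  additive Gaussian discs (sigma = r/2, peak ~N(550, 80) clipped at
  ±2 SD) so the thresholded blob size tracks the nominal radius.
  Somata are flat-top soft-edged shapes, max-composited: pericytes
  ~N(460, 40) on ellipses (r+3.8 × r+2.9) aligned with a capillary;
  microglia ~N(420, 50) on discs (r+3.5) with 2–5 dim random-walk
  processes at 0.30× the soma value. All foreground draws are clipped
  at mean ± 2 SD, so the classes are separated by a *guaranteed* gap
  rather than a probable one: negative cell means stay below ~200
  (DsRed) and ~100 (GFP), positive cell means above ~380 (DsRed) and
  ~320 (GFP) — straddling the published-scale threshold grids. The
  soma sizes and brightness are bounded so that no pericyte soma
  exceeds the vessel classifier's reach (≥ 400 counts over ≥ 150 µm²),
  which would wrongly reclassify pericytes as vessels.
* **Placement.** Minimum center-to-center distance
  `max(1.6·(r1+r2), r1+r2+6.5 µm)`; the additive clearance guarantees a
  cell's expansion ring cannot reach a non-touching neighbor's soma
  interior. A configurable 5% of nuclei are placed as deliberately
  touching pairs (0.95 × the radius sum) to exercise watershed
  splitting; both members of such a pair are kept negative, and the
  class fractions are renormalized over the remaining cells so the
  marginal fractions still match the configuration exactly.
* **Artifacts.** A brightness ramp (amplitude 120, width 60 µm) inside
  the tissue edge motivates the −40 µm erosion; two large DsRed-bright
  vessels (width 25 µm, +700 counts) motivate the vessel classifier;
  5% of nuclei are dim (peak × 0.5), emulating out-of-focus nuclei that
  automated detection misses but a manual counter would still score.
* **Determinism.** One `numpy` Generator seeded from the config; the
  same config is bit-identical. Cohorts spawn per-section seeds from a
  single `SeedSequence`.

What the generator does **not** emulate — and hence what passing tests
do not show about real tissue: point-spread optics and chromatic blur,
realistic vascular topology, autofluorescence (e.g. lipofuscin),
section-to-section staining variability, NG2-positive oligodendrocyte
precursors as a DsRed-positive confound, and 3-D effects beyond the dim-
nucleus proxy. Because touching pairs are kept negative, dual-positive
cells are essentially absent from synthetic sections (real tissue shows
a small dual fraction from adjacent pericyte/microglia pairs); dual
classification logic is exercised by direct unit tests instead.

## Threshold study at desk scale

The full study (`brainquant.study`) uses eight sections — matching the
cohort size of the motivating experiment — with one 300 × 200 µm test
annotation per region per section, placed away from large vessels the
way a manual counter drew ROIs in clean tissue. Ground-truth counts
inside each rectangle stand in for the manual counts. The DAPI sweep
runs the full detector at every grid value inside a padded crop of each
annotation; the DsRed/GFP sweeps detect once per annotation at the
region's optimized DAPI threshold and re-count cell means against each
grid value (classification thresholds do not alter detections, so the
cache is exact). Mean %difference at a grid value is reported only when
every annotation scored there; SD is the sample SD (n−1).

Two residual biases are visible in the study's own numbers and are
accepted as part of the emulated conditions: dim-nucleus positives are
counted manually but partially missed by detection (≈ −2% mean
%difference at in-gap classification thresholds), and a small fraction
of pericytes under large vessels is excluded by the vessel mask
(slightly depressing recovered thalamus pericyte percentages). Both
mirror failure modes documented for the real workflow.

## Numerical and degenerate-input choices

* Sweep annotations with `Mc = 0` are excluded with a warning (the
  %difference is undefined); a region whose annotations all lack
  positive manual counts falls back to the optimum pooled over all
  regions.
* An empty tissue mask is a warning, not an error — a section may
  legitimately fail. An empty *region* mask is an error at
  quantification time; a region with zero detections is valid and
  flagged.
* The 1 mm² minimum tissue area is intended for whole coronal sections
  (~40 mm²); sub-mm² fixtures must scale it (the test suite uses
  0.1 mm²).
* `select_optimum` compares |mean| and SD rounded to 1e-9 to make
  lexicographic ties well-defined under float noise.
* Detections are sorted by (y, x) centroid and relabeled 1..n, making
  every downstream table deterministic.

## Known limitations

Parity with the original GUI tool's built-in detector is not claimable:
the operator chain here is fixed and documented, but its internals
differ, so optimal thresholds found on real slides by either tool need
not coincide. Quantitative agreement with the published regional
percentages holds only insofar as the generator encodes them as ground
truth; the package's claim is *recovery of known truth under realistic
artifacts*, not reproduction of the original tissue measurements.
Percentages pooled "across all regions" depend on the relative region
areas, which at desk scale are stylized rectangles rather than atlas
anatomy.
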