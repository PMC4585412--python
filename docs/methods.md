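# Methods

## Imaging geometry

The scanner is modelled as a tri-linear line-scan camera imaging a moving
conveyor. A `CalibrationProfile` holds the sensor pixel pitch *p* (µm),
the object-to-sensor magnification *M*, the integer row offsets of the
green and blue sensor lines relative to red, and the frame size. Derived
quantities are

* linear resolution *r* = (*p*/1000)·*M* mm/pixel,
* areal resolution *r*² mm²/pixel,
* field of view = sensor extent × *M*,
* minimum feeding-cylinder spacing = cylinder diameter + scan-direction
  field of view.

The default profile (14 µm, ×15.71, 1280×3000 frames) gives
0.21994 mm/pixel. Values are kept unrounded internally and rounded only
for reporting (2 decimals for lengths, 3 for areas), so the printed
figures 0.22 mm and 0.048 mm²/pixel are reproduced without letting the
rounding cascade into areas computed from pixel counts.

The channel offsets are free parameters of the synthetic model: the
physical line spacing of the real sensor is not published beyond being a
whole number of lines. Defaults are green = 2, blue = 4 rows; they are
config-exposed and everything downstream handles any non-negative values
smaller than the frame height.

## Channel registration

Raw frames have their green and blue planes displaced *down* the scan
axis. Correction shifts them back up by the profile offsets; red is the
reference and is never modified. The vacated bottom rows of each frame
are filled with the background colour — information that moved into the
next frame is not borrowed back, matching an instrument that corrects
each frame before mosaicking. The consequence is a lossy band of
max(offsets) rows at the bottom of every frame; a leaf continuing into
the next frame is therefore briefly off-band there.

## Segmentation

RGB is converted to HSL with all three channels quantised to 0–255
(hue 0–360° → 0–255; the hue of achromatic pixels is defined as 0).
Threshold bands are inclusive axis-aligned boxes; no circular hue
intervals are needed because no default band crosses the hue origin.
Defaults are the desktop-scanner reference values (green H 39–131,
S 34–255, L 30–233; yellow H 0–38, S 34–255, L 30–233). The greenness
classes subdivide the green band's lightness range into
156–233 (green-2, light), 106–155 (green-3, moderate) and 30–105
(green-4, dark). These sub-band boundaries are this package's defaults,
not published values; because they partition the green band exactly,
GLA = GLA₂+GLA₃+GLA₄ holds identically.

The total-leaf mask is the union of the green and yellow band masks.
Connected components smaller than `min_impurity_px` (default 50 px ≈
2.4 mm²) are removed as impurities; 8-connectivity is used throughout so
thin diagonal leaf tips do not fragment. Class masks are the raw class
band masks intersected with the cleaned total mask, which excludes
in-band dust that is not on a leaf.

8-bit quantisation limits the HSL↔RGB round trip: lightness is always
reproduced exactly, while hue and saturation are stable to ±1 only where
the chroma exceeds ~80 of 255. The synthetic generator therefore samples
leaf colours with a margin inside each band and verifies the round trip
before accepting a colour.

## Mosaicking and leaf extraction

Frames are stitched by row concatenation; labelling components globally
on the stitched canvas is equivalent to cutting a boundary-crossing leaf
and reconnecting it to its remaining portion, and is simpler to verify.
Because per-frame correction blanks the last max(offsets) rows of each
frame, a crossing leaf arrives with a thin off-band gap at the boundary.
`bridge_frame_boundaries` repairs it: in every column with foreground
immediately above the vacated band and at the boundary row, the vacated
rows are re-marked as foreground. The repair only adds pixels, only near
boundaries, and cannot merge distinct leaves unless they are vertically
within the offset distance in the same columns (the generator's packing
margins are several times larger). Components below `min_leaf_px`
(default 200 px ≈ 9.7 mm², well under the smallest rice leaf) are
discarded; fragments above it count as leaves.

## Per-leaf measurements

* **Length** — geodesic length of the longest path through the
  morphological skeleton, chosen over bounding-box extents because rice
  blades curl. The skeleton is turned into an 8-connected graph
  (diagonal steps weighted √2); spur branches shorter than 1.5× the
  inscribed radius at their junction are pruned (the medial axis of a
  rectangle grows 45° corner spurs that would otherwise inflate the
  path); the two most distant nodes are found by double Dijkstra sweeps;
  path length is measured on a polyline through every 4th path pixel
  (suppressing the ~5–8% chain-code bias on oblique curves); and the
  inscribed radius at each end is added to reach the blade tips. A
  quarter-circle blade of 100 mm centre-line length is recovered to
  within 1%.
* **Width** — 2× the maximum of the interior Euclidean distance
  transform, evaluated on a 2× upsampled mask: the plain pixel-centre EDT
  overestimates odd strip widths by one pixel, while the upsampled form
  is exact for axis-aligned strips of any integer width. The EDT maximum
  lies on the medial axis, so this equals the maximal blade width along
  the skeleton. Width is the maximum inscribed diameter, not area/length,
  because the length-to-width ratio and the perimeter–area relation treat
  width as a blade dimension.
* **Perimeter** — length of the closed marching-squares iso-contour,
  measured through every 5th contour point; the raw contour polyline
  overestimates a digital disc by ~6%, the subsampled one by <0.5%.
* **Compactness** — the isoperimetric quotient 4πA/P², a bounded (0, 1]
  shape statistic (1 for a disc; ≈0.26 for a 10:1 rectangle). Digital
  discs can exceed 1 by a few per cent of rasterisation error.
* **Colour class** — argmax of the per-class areas within the leaf; ties
  break toward the darker class; all-zero yields "unclassified".

A leaf reduced to a single pixel measures one pixel pitch in length and
width. If the width estimate exceeds the length estimate (compact,
non-blade-like masks), the two are swapped to preserve LL ≥ LW.

## Trait aggregation

Averages are arithmetic means over the leaves of a plant, maxima per-leaf
maxima, and all SDs population SDs (÷n). Ratio traits are formed from
aggregated components: ALWR = ALL/ALW, MLWR = MLL/MLW, APAR = ALP/ALA;
MPAR is the per-leaf maximum of perimeter/area (the alternative MLP/MLA
reading is rejected because the maxima may come from different leaves).
GLCC = (2·GLA₂+3·GLA₃+4·GLA₄)/GLA is an area-weighted mean of the class
indices — a monotone greenness score suitable as a quantitative trait.
Colour ratios and GLCC are reported missing (NaN) when GLA = 0. The
29-name list and its 6/7/16 grouping are fixed in `leafscore.traits` and
exposed for substitution if a different authoritative list is preferred.

## Synthetic generator

The generator defines the study conditions the tests replay:

* leaf geometry: length ~ U(150, 350) mm, maximum width ~ U(8, 18) mm
  (typical detached rice leaves), shapes uniformly rectangle / tapered
  ellipse / curved blade (arc angle U(0.3, 0.9) rad); width is capped at
  0.8× length;
* colour classes mixed 25/40/25/10% (green-2/3/4/yellow) for general
  plants; discrimination batches use a single class with 50 leaves,
  colours sampled strictly inside the class band;
* placement: shelf packing with ≥20 px margins on a 1280-column canvas,
  long axis along the scan direction; when the canvas spans multiple
  frames and no leaf happens to straddle a boundary, the packing is
  shifted so one does — boundary crossing is the case the mosaic stage
  exists for;
* artefacts: green/blue planes shifted down by the profile offsets;
  frames of 3000 rows; dust as 1–20 px random-walk specks at 5 specks
  per megapixel, half coloured inside a random leaf band.

Ground truth is analytic per leaf (rectangle: A = LW, P = 2(L+W);
ellipse: A = πLW/4, Ramanujan perimeter; curved blade: the rectangle
values of its unrolled annulus sector) and aggregated by the same trait
code the pipeline uses. Dust is placed on background only, never touching
a leaf, so the truth stays exact; real dust can occlude leaves, which
this model does not exercise. Leaves are uniformly coloured (no
within-leaf lightness gradients, venation or specularity) and never
overlap (the physical feeder separates leaves). Passing tests therefore
demonstrate the correctness of the measurement chain under the
instrument's artefact model, not robustness to illumination drift or
threshold miscalibration on real imagery.

## Evaluation statistics

MAPE and the APE SD follow the per-sample absolute per cent error
definition with the reference method in the denominator; the SD is the
population SD (the sample convention would differ by <1% at the n≈150
scales involved; the choice is documented, not inferable). R² is the
squared Pearson correlation of the two methods' values — the conventional
statistic for method-versus-method scatter — not a regression-through-
origin R²; both can be computed from the returned vectors if needed.
Discrimination error is per true class; classes with no members are
reported missing rather than 0.

## GWAS summarisation

Filtering keeps MAF ≥ 0.05 and minor-allele accession count ≥ 6, both
inclusive. Thresholds are suggestive = 1/N and significant = 0.05/N for N
effective independent markers (their ratio is 0.05 exactly). Clumping
sorts SNPs within a chromosome and starts a new locus whenever the gap to
the previous SNP is ≥ 300 kb; every input SNP belongs to exactly one
locus, loci never span chromosomes, and locus bounds are the member
extremes (not padded). The lead SNP minimises the p-value with ties going
to the smaller position (a tie-break this package fixes; the convention
is not published). Cross-trait overlap is plain interval intersection
between the loci of different (trait, stage) groups.

## Problem sizes and numerical choices

The test suite and acceptance script run synthetic tasks of 4–50 leaves
on canvases of 320–1280 columns; these sizes were chosen as the smallest
that exercise every code path (multiple shelves, multiple frames,
boundary crossings, all shapes and classes) while keeping the whole suite
in the tens of seconds. The 50-leaf single-class batches mirror the
instrument's published discrimination experiment at its original size.
All randomness flows through `numpy.random.default_rng` seeds; identical
seeds give bit-identical rasters and byte-identical CSVs.

Known limitations: no lens distortion or illumination-field modelling; no
sub-pixel channel registration (offsets are whole lines); no automatic
band or offset estimation from imagery; no separation of touching leaves
(the feeder prevents overlap); the greenness sub-bands and channel
offsets are package defaults, not published instrument values.
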