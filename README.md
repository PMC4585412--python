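# leafscore

Image-analysis toolkit for high-throughput rice leaf phenotyping with a
line-scan scanner, plus the summary rules used to interpret genome-wide
association scans of the resulting traits.

Detached rice leaves are fed on a conveyor past a tri-linear line-scan
camera. `leafscore` reimplements the full measurement chain that turns the
resulting frame sequence into a per-plant trait table:

1. **Channel registration** — the red, green and blue sensor lines are
   physically offset along the scan direction, so the raw image is colour
   distorted; the green and blue planes are shifted back into registration
   with red.
2. **HSL segmentation** — pixels are thresholded in 8-bit hue–saturation–
   lightness space with fixed, inclusive bands for green
   (H 39–131, S 34–255, L 30–233) and yellow (H 0–38, S 34–255, L 30–233)
   leaves; three lightness sub-bands of the green band grade leaf greenness
   into the light/moderate/dark classes of the IRRI leaf colour chart
   (green-2/3/4).
3. **Mosaicking** — fixed-height frames are stitched; leaves cut at frame
   boundaries are reconnected; isolated small components (dust, lint) are
   removed.
4. **Morphometrics** — each leaf yields length LL (longest skeleton path,
   robust to curled blades), maximum width LW (2× max inscribed radius),
   perimeter P (sub-pixel contour length), area A (pixel count ×
   0.048 mm²/pixel at the default calibration) and compactness C = 4πA/P².
5. **Trait aggregation** — the leaves of one plant are aggregated into 29
   named traits: 6 size (LN, TLA, GLA, ALA, MLA, LASD), 7 colour (GLA₂,
   GLA₃, GLA₄, GLAR₂, GLAR₃, GLAR₄, GLCC) and 16 shape
   (avg/max/SD of length, width, perimeter and compactness, plus ALWR,
   MLWR, APAR = ALP/ALA and MPAR).

Method agreement is quantified by

```
MAPE = (100/n) Σᵢ |x_i,ref − x_i,test| / x_i,ref ,
```

together with the SD of the per-sample absolute per cent errors, the
squared Pearson correlation R², and per-class discrimination error. For
blade-like leaves the shape traits obey the rectangular approximation
APAR ≈ 2/ALW + 2/ALL → 2/ALW, which the package exposes as a consistency
check.

A **synthetic scanner** renders plants of parameterised leaves (rectangles,
tapered ellipses, curved blades in the four colour classes) with analytic
ground truth, then applies the instrument's artefacts — channel
misalignment, frame splitting with boundary-crossing leaves, dust speckle —
so every pipeline stage is testable against a known answer.

The **GWAS summary** module post-processes a per-SNP association table:
filtering (MAF ≥ 0.05, minor-allele accessions ≥ 6), effective-marker
Bonferroni thresholds (suggestive 1/N, significant 0.05/N), clumping of
associated SNPs into loci (adjacent gaps < 300 kb, never spanning
chromosomes), lead-SNP selection and cross-trait locus overlap. It never
runs the association model itself.

## Worked example

Simulate one plant of 8 leaves, score it, and compare against the
generator's analytic truth:

```sh
leafscore simulate --plants 1 --leaves-per-plant 8 --seed 21 --outdir demo
leafscore score --frames-dir demo/plant-21 --out-prefix demo/scored
leafscore evaluate --truth demo/truth_plants.csv \
    --measured demo/scored_plant.csv \
    --traits GLA,TLA,LN,ALL,ALW,APAR --key task_id
```

which prints

```
trait  n  mape_pct  ape_sd_pct  r_squared
  GLA  1  0.024216         0.0        NaN
  TLA  1  0.024216         0.0        NaN
   LN  1  0.000000         0.0        NaN
  ALL  1  0.161796         0.0        NaN
  ALW  1  0.282503         0.0        NaN
 APAR  1  0.121831         0.0        NaN
```

i.e. the pipeline recovers the generated green leaf area to 0.02 %, the
leaf count exactly, and mean length/width to better than 0.3 % on this
task (R² needs more than one plant). The scored trait row itself:

```
 task_id  LN      TLA      GLA    ALL   ALW  APAR  GLCC
plant-21   8 25185.43 25185.43 266.13 13.03  0.17   3.0
```

— 8 leaves totalling 251.9 cm², all green (TLA = GLA), average blade
266 mm × 13 mm, perimeter-to-area ratio 0.17 mm⁻¹ (≈ 2/ALW + 2/ALL = 0.16),
and a mean greenness class of 3.0.

The same objects are available as a library:

```python
from leafscore import sample_plant, render_scan, score_task, split_frames
from leafscore.synthetic import distort_channels
from leafscore.config import default_config

cfg = default_config()
task = sample_plant(8, seed=21)
scan = render_scan(task, cfg.calibration)
raw = distort_channels(scan.rgb, cfg.calibration.channel_offsets)
result = score_task(split_frames(raw, task.frame_height_px), cfg)
print(result.per_plant)     # 29 trait columns
print(task.truth.to_dict()) # the analytic ground truth
```

## Layout

| module | contents |
| --- | --- |
| `leafscore.calibration` | optical/feeding geometry, mm-per-pixel profile |
| `leafscore.synthetic` | ground-truth scan generator and artefact models |
| `leafscore.channels` | tri-linear channel registration |
| `leafscore.segmentation` | HSL conversion, threshold bands, impurity removal |
| `leafscore.mosaic` | frame stitching, boundary reconnection, leaf extraction |
| `leafscore.morphometrics` | per-leaf length/width/perimeter/area/compactness |
| `leafscore.traits` | 29-trait aggregation, ALWN/MLWN, APAR approximations |
| `leafscore.evaluation` | MAPE, APE SD, R², discrimination error |
| `leafscore.gwas` | SNP filtering, thresholds, 300-kb locus clumping |
| `leafscore.pipeline` / `leafscore.cli` | end-to-end scoring and the CLI |

See `docs/methods.md` for the measurement definitions, parameter defaults
and known limitations.
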