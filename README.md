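# micromorph

Microglia respond to immune stimuli by remodelling their shape — from
ramified (small soma, many thin processes) through polarized/rod-like to
round/amoeboid — and by shifting their cytokine secretion between
pro-inflammatory (M1-like: IL-1β, IL-6, TNFα) and anti-inflammatory
(M2-like: IL-4, IL-10) profiles. `micromorph` is a toolkit for quantifying
both readouts from *in vitro* experiments and summarising them into
composite inflammatory scores. It is aimed at labs analysing
immunostained primary microglia cultures (e.g. genotype × treatment
designs with purinergic agonists/antagonists) together with multiplex
bead-based cytokine panels.

Because such studies rarely release raw images or plate files, the package
ships a synthetic-data generator that emulates both inputs with known
ground truth, so every stage of the analysis is verifiable end to end.

## What it computes

**Single-cell morphometry** (`micromorph.morphometry`). From a label
raster of delineated cells, per cell: area *A*, perimeter *P* (sub-pixel,
smoothed marching-squares contour), convex area, and the fitted-ellipse
axes (second-moment ellipse rescaled to preserve area). Derived
descriptors:

```
circularity  = 4πA / P²           roundness = 4A / (π·major²)
aspect ratio = major / minor      solidity  = A / convex area
complexity   = P / A              (1/µm; higher = more ramified)
```

The area-preserving ellipse convention makes `roundness × aspect_ratio = 1`
hold exactly. Cells are classed into three morphotypes by explicit rules:
no processes → round/amoeboid; aspect ratio ≥ 3 → polarized/rod-like;
≥ 3 processes → ramified. Processes are detected as skeleton branches
leaving the maximal inscribed soma disk.

**Nuclei counting** (`micromorph.counting`). Nuclear-channel chain:
Gaussian blur → Otsu threshold → hole filling → optional watershed split →
area filter; per-cell nucleus assignment flags multinucleated cells.

**Cytokine calibration** (`micromorph.cytokines`). Five-parameter logistic
standard curves per analyte,

```
y = D + (A − D) / (1 + (x/C)^B)^g
```

fitted to 6-point 10× serial-dilution duplicate standards by multi-start
least squares; closed-form inversion with range censoring (never
extrapolated); ×2 dilution correction; background subtraction against
medium-only wells; per-animal n-fold of the pooled untreated control
wells.

**Composite scoring** (`micromorph.scoring`). Quartile-fence outlier
trimming (Q1 − 1.7·IQR / Q3 + 1.7·IQR), knockout-vs-control Z tests
`z = (X − µ)/σ`, cytokine-cluster Z scores, and the combined scores
`ProIF = (z{IL-1β,IL-6,TNFα} + z_roundness)/2`,
`AntiIF = (z{IL-4,IL-10} + z_aspect-ratio)/2`.

**Inference** (`micromorph.stats`). Welch's t (two-group cytokine
n-folds), Pearson χ² on [round/amoeboid] vs [polarized+ramified]
proportions, Kruskal–Wallis + Dunn (tie-corrected, Bonferroni) for
multi-group shape/count panels, one-way ANOVA + Tukey HSD for Z panels,
with `*`…`****` significance tiers.

Analytes are keyed ASCII-safe in all tables: `TNFa, IFNg, IL-1b, IL-2,
IL-4, IL-6, IL-10, IL-12, IL-17, IL-27` (IFNg = INF-γ, IL-17 = IL-17/IL-17A).

Calibration, trimming, reference scoring and morphotype classification are
scikit-learn-style estimators (`FivePLCalibrator`, `QuartileFenceTrimmer`,
`ReferenceZScorer`, `MorphotypeClassifier`) and compose with sklearn
pipelines; module-level functions wrap them.

## Worked example

```python
import numpy as np
from micromorph import morphometry as mm, simgen as sg, cytokines as ck

# 1. an ideal disk, radius 50 µm
yy, xx = np.mgrid[:120, :120]
disk = (yy - 60) ** 2 + (xx - 60) ** 2 <= 50 ** 2
d = mm.descriptors(mm.measure_cell(disk, pixel_size_um=1.0))
print(d.circularity, d.roundness, d.complexity_index)
# circularity=0.991 roundness=1.000 complexity=0.0402   (ideal: 1, 1, 2/r = 0.04)

# 2. a synthetic ROI: 60 cells, 60/20/20 % round/polarized/ramified
roi = sg.generate_roi(mixture=(0.6, 0.2, 0.2), n_cells=60, seed=7, shape=(700, 700))
cells = mm.measure_labels(roi.labels, pixel_size_um=1.0)
print(cells["morphotype"].value_counts().to_dict())
# {'round_amoeboid': 27, 'ramified': 21, 'polarized': 12} — identical to roi.truth

# 3. a multiplex plate: calibrate, invert, normalise
design = sg.default_plate_design(n_animals_per_genotype=4, noise_cv=0.08)
std, samples, truth = sg.generate_cytokine_experiment(design, seed=7)
records, calib = ck.process_plate(std, samples)
lps = records[(records.role == "treatment") & (records.treatment == "LPS+BzATP")]
print(lps.groupby(["analyte", "genotype"])["n_fold"].mean().round(2))
```

which prints (seed 7) n-fold changes under LPS + BzATP stimulation of
`TNFa: CTRL 21.69 / KO 7.04`, `IL-6: CTRL 21.49 / KO 7.73`,
`IL-4: CTRL 0.54 / KO 0.83` — the programmed pattern that receptor-
proficient cultures mount a stronger pro-inflammatory response while IL-4
drops, attenuated in the knockout.

The whole chain runs as one seeded, reproducible pipeline from the shell:

```
micromorph run --seed 7 --out runs/demo
micromorph simulate roi --mixture 0.6,0.2,0.2 --n-cells 300 --seed 7 --out rois/
micromorph morpho --labels rois/roi_labels.tif --pixel-size 1.0 --out cells.csv
```

`runs/demo/` contains tidy CSV tables, a `report.md` with morphotype
proportions, descriptor and cytokine n-folds, Z panels and the routed
statistical tests, plus a manifest recording the seed, config hash and
every decision parameter.

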