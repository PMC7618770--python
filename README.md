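# evuptake

Quantification of engineered extracellular-vesicle (EV) cargo uptake in
cardiomyocytes, from fluorescence images to hierarchical statistics.

## The problem

Engineered EVs carrying a fluorescent cargo (NeonGreen2) are perfused into
isolated hearts; uptake is then read out on isolated cardiomyocytes imaged in
two channels — 405-nm excitation (bright Hoechst-stained nuclei over weak
cytoplasmic autofluorescence, used to outline cells) and 488-nm excitation
(the NeonGreen2 cargo signal). Turning such images into defensible group
comparisons requires several pieces that this package implements as one
tested pipeline:

- **Segmentation and shape QC** — cell outlines from 405-nm autofluorescence,
  nuclear masks from Hoechst; particles quantified by area and the
  long/short axes of the moment-equivalent ellipse. Healthy myocytes are
  rod-shaped; hypercontracted dead cells are near-circular and are excluded
  by the axis-ratio criterion, as are border-touching particles. Nuclei must
  satisfy the strict criteria area > 30 µm² and axis ratio > 3.
- **Per-cell readouts** — cytoplasmic mean 488 signal, its grey-level
  co-occurrence matrix (GLCM) homogeneity, and nuclear mean.
  Homogeneity = Σᵢ Σⱼ P(i,j)/(1+|i−j|) over the masked, normalized GLCM;
  1 means perfectly uniform signal, lower values mean patchy signal.
- **Positivity thresholding** — the threshold is the highest value measured in
  sham (EV-free) control cells after iteratively removing Gaussian outliers
  (Grubbs' test), so sham positivity is zero by construction.
- **Hierarchical statistics** — cells are nested within hearts; treating them
  as independent inflates false positives (pseudo-replication). Cells are
  averaged per heart, then groups are compared by Welch one-way ANOVA with
  Dunnett's T3 (studentized-maximum-modulus, Welch df) versus control.
- **Tissue sections** — red immunostain profiled by compartment:
  nuclear (DAPI), cytoplasmic (actinin minus nuclei), extracellular.
- **FRAP** — single-exponential recovery fit
  F(t) = F₀ + A·(1 − e^{−(t−t₀)/τ}), returning τ and the mobile/immobile
  fractions.
- **Biodistribution** — organ luminescence normalized by administered dose and
  tissue mass, expressed as per-organ fold-change versus control.

Because the original microscopy data are not deposited, the package includes a
first-class synthetic-data generator (`evuptake.simulate`) that renders
ground-truthed myocyte fields, multi-heart experiments with heart-level random
effects, section images, FRAP traces and biodistribution tables, so every
stage is testable end to end.

## Worked example

```python
from evuptake import simulate, segmentation, quantify

cfg = simulate.SimulationConfig(read_noise_sd=0, shot_noise_scale=0,
                                heterogeneity_amplitude=0)
field, truth = simulate.simulate_myocyte_field(cfg)   # 5 live + 2 dead cells
records = segmentation.analyze_field(field)
for r in records:
    print(r.cell.label, r.accepted, r.rejection_reason,
          round(r.shape.area), round(r.shape.axis_ratio, 2))
for m in quantify.measure_field(records, field):
    print(m.cell_label, m.cytoplasmic_mean, m.cytoplasmic_homogeneity)
```

prints (noiseless field, default seed):

```
1 True None 1834 4.29
2 True None 1589 4.87
3 True None 2308 4.55
4 False ratio 1552 1.07
5 True None 2131 6.14
6 True None 2372 5.45
7 False ratio 2373 1.05
1 30.0 1.0
...
```

The two near-circular dead cells (axis ratio ≈ 1) fail the rod filter with
reason `ratio`; every live rod is accepted. With zero noise and zero texture
each accepted cell's cytoplasmic mean equals background (10) + its true
NeonGreen2 level (20) and its homogeneity is exactly 1.

The full analysis lives in `analysis/01…07` (simulate → segment/measure →
hierarchical inference; sections; FRAP; biodistribution; a pseudo-replication
demonstration); each script prints what it found and writes tables under
`results/`. The same stages are scriptable via the `evuptake` CLI
(`evuptake all --config run.yaml --seed 1`).

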