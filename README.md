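# tenomac

Spatial and molecular quantification of **tendon-resident macrophages**
in mouse tendon sections, with a ground-truth synthetic-data generator
for validating every stage of the pipeline.

Tendon fascicles house a sparse population of resident macrophages
(F4/80⁺ CD206⁺, labelled by the Csf1r-EGFP "MacGreen" reporter) among
the dominant Scx/Col1a1-lineage fibroblasts. Characterising them
requires a chain of image- and plate-level quantifications: counting
reporter-positive nuclei inside a manually drawn fascicle ROI,
profiling cell depth relative to the tendon surface, measuring EdU
uptake per population, unmixing duplex chromogenic in-situ
hybridisation stains, scoring DQ-collagen internalisation, and
analysing high-throughput qPCR plates. `tenomac` implements each of
these as a tested, importable library plus a thin `tenomac` CLI, and —
because the underlying microscopy and qPCR data of such studies are
rarely deposited as analysable rasters — ships a generator that renders
synthetic sections, ISH fields, cell suspensions, and CT matrices with
known ground truth under presets encoding the study conditions.

## Methods at a glance

* **Nuclear segmentation** (`nucseg`): global Otsu threshold on the
  Hoechst channel, watershed seeded from smoothed distance-transform
  maxima, physical area bounds; per-nucleus channel means; run-level
  intensity thresholds define GFP⁺/EdU⁺ classes.
* **Abundance** (`abundance`): %GFP⁺ = 100·n⁺/n and densities
  (cells/mm²) over centroids strictly inside the fascicle polygon;
  one-way ANOVA + Tukey HSD with Shapiro–Wilk/Levene preflight.
* **Depth profiling** (`depthmap`): Euclidean distance map
  D(x) = min distance to the anterior/posterior surface polylines;
  per-cell normalized depth d = D̄/D_max binned into quartiles
  (Q1 outermost); enrichment ratio r_q = pct⁺_q / pct⁺_whole, with
  r_q ≡ 1 under spatial uniformity.
* **Proliferation** (`proliferation`): per-animal pooled EdU⁺ fractions
  within GFP⁺ and GFP⁻ populations, their ratio, paired t-test.
* **Duplex ISH** (`ishcoloc`): optical density OD = −log₁₀(I/I₀),
  stain vectors estimated from single-colour controls, per-pixel
  unmixing A = M⁻¹·OD, 50×50 µm grid means inside the ROI, Spearman ρ
  between stains (exact p at small n).
* **qPCR** (`qpcr`): technical-duplicate collapse, undetectability
  exclusions, ΔCT = mean CT(housekeeping: *18s*, *Abl1*, *Rps17*) − CT(gene),
  ΔΔCT = ΔCT(A)−ΔCT(B) = log₂ fold change with exact Mann–Whitney U,
  unit-variance PCA by SVD with deterministic PC1 orientation,
  loading-based gene subsetting, correlation/average-linkage clustering,
  and a ligand–receptor pairing report (Csf1→Csf1r, Il6→Il6ra,
  Cx3cl1→Cx3cr1, Gas6→Axl, Tgfb1→Tgfbr2, Pdgfb→Pdgfra).
* **Internalisation** (`internalization`): marker thresholds on explant
  suspension tables; %DQ-collagen⁺ within CD206⁺/F4/80⁺/Col1CFP⁺.

## Worked example

```bash
python examples/01_section_abundance.py
```

```
nuclei segmented:        3863
in-fascicle nuclei:      3602
GFP+ percentage:         7.94%   (generator truth 7.94%)
total cell density:      1201 cells/mm^2
macrophage density:      95 cells/mm^2
```

A synthetic P56 patellar section is rendered from its preset
(macrophage fraction 7.9%, density 1200 cells/mm²), segmented, and
classified; the recovered GFP⁺ percentage matches the generator's
realized truth exactly here because segmentation is error-free at
preset geometry, and matches the preset parameter up to binomial
sampling. The other scripts in `examples/` walk the depth profile, ISH
colocalization (colocalized condition: mean ρ ≈ 0.46 vs ≈ 0.03 under
the uniform null), qPCR analysis (PC1 ≈ 92% of variance, separating
macrophages from fibroblasts), and DQ-collagen scoring (≈ 73% of
CD206⁺ cells DQ⁺ vs ≈ 0.5% of Col1CFP⁺ cells).

The same stages run from a shell:

```bash
tenomac all --config cfg.yaml --seed 1 --out out/
tenomac synth --preset P56-patellar --out out/
```

Every stage writes CSV artifacts plus a JSON report of the parameters
used, and reruns are byte-identical at fixed config + seed.

## Layout

```
src/tenomac/     library (synth, nucseg, abundance, depthmap,
                 proliferation, ishcoloc, qpcr, internalization,
                 io, pipeline, cli, experiments, stats)
examples/        one narrative script per capability
tests/           pytest suite incl. end-to-end recovery checks
docs/methods.md  models, parameters, and design notes
```
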