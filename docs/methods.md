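# Methods

This note documents the models behind `tenomac`: what the synthetic
generator emulates, how each quantification stage is defined, which
parameters matter, and where the design was genuinely open.

## The measurement problem

Tendon-resident macrophages are rare (a few percent of fascicle cells),
spatially intermingled with fibroblasts arranged in linear arrays, and
are characterised through several assays — reporter imaging, EdU
pulse labelling, duplex chromogenic ISH, explant DQ-collagen uptake,
and high-throughput qPCR of sorted populations. Each assay has a
quantification procedure whose correctness is hard to audit on real
images alone. `tenomac` therefore pairs every procedure with a forward
model that generates the corresponding raw data with known ground
truth, so recovery can be tested end to end.

## Synthetic sections (`synth.SectionSpec`, `generate_section`)

A section is an elongated rectangular fascicle (long axis = tendon
axis, y-down µm coordinates) bordered by a peritenon band, rendered at
0.5 µm/px by default (20×-class sampling; configurable). Cells are
sampled by a documented recipe (see the `sample_cells` docstring):
a Poisson cell count at the target density, class labels as Bernoulli
draws of the macrophage fraction, and sequential placement that snaps
y to row centres with lateral jitter — reproducing the linear-array
texture that makes watershed segmentation non-trivial — under an
anisotropic clearance constraint (1.15× the nuclear major axis along
rows, 1.35× the minor axis across rows). Nuclei are rotated ellipses
(default 10 × 5 µm, orientation jitter 8°) with per-cell intensities
from class-conditional Gaussians; the EdU channel is rendered only for
labelled nuclei at fixed high SNR, because EdU detection difficulty is
not an object of study. Additive Gaussian background noise is applied
last.

`depth_bias` ≥ 0 controls macrophage placement: 0 is depth-uniform;
positive values thin macrophage candidates by exp(−bias·d/d_max),
where d is the distance to the nearer surface polyline. The bias
applies to macrophages only — fibroblasts are always depth-uniform —
because the depth statistic exists to detect surface infiltration of
macrophages relative to the resident population; a class-neutral bias
would leave every enrichment ratio at exactly 1 and could not produce
a positive control.

The peritenon band carries its own cells (default: same density,
30% macrophage) so that ROI exclusion is actually exercised; those
cells are flagged in the ground truth and must not appear in any
fascicle statistic.

What the generator does **not** model: collagen texture and
autofluorescence structure, optical PSF blur, sectioning artifacts,
intensity vignetting, or 3-D effects. Passing recovery tests therefore
show the *procedures* are correct and unbiased under controlled
conditions; they do not certify robustness to every real-world imaging
pathology.

### Presets

Presets pin the generator to the study conditions. Macrophage
fractions: patellar 1.6% (P4), 3.5% (P14, interpolated), 5.5% (P28,
interpolated), 7.9% (P56); Achilles 1.4% (P4), 4.8% (P56). Total cell
density falls with age (3500 → 1200 cells/mm²) as matrix synthesis
outpaces proliferation. The abundance presets use a ≈3 mm² fascicle so
that a 4-seed mean of the recovered percentage has a Monte-Carlo SE of
≈0.07–0.3 points — small relative to the quantities themselves. The
`P1-edu` preset uses smaller, denser sections (0.29 mm², 4500
cells/mm²) with EdU labelling probabilities 0.50 (macrophage) and 0.20
(fibroblast): the 2.5 ratio is the study-condition quantity; the
absolute levels are free parameters chosen for the highly
proliferative neonatal tendon, where recovery experiments image ten
sections per virtual animal (the study design images 9–14).

The intensity statistics of GFP⁺ vs GFP⁻ nuclei are not reported
anywhere we could anchor them; the defaults (180 ± 12 vs 12 ± 4) are
free parameters that make the populations well separated, and the
packaged run-level threshold (80) sits in the wide margin between
them. The same applies to the suspension marker models (positives
200 ± 12, negatives 6 ± 3, thresholds ≈100).

## Segmentation (`nucseg`)

Foreground by global threshold — Otsu by default, a fixed value for
parity with manual workflows — then watershed on the negated internal
distance transform. Seeds are maxima of the distance map *after*
Gaussian smoothing (default 1.5 µm): an elongated nucleus has a long,
nearly flat medial ridge on which every plateau pixel is a regional
maximum, and unsmoothed seeding fragments such nuclei (observed ~1.7
labels/nucleus at preset geometry; smoothing restores exactly one).
Seed separation defaults to 2 µm; components outside [8, 200] µm² are
dropped; border-touching nuclei are kept but flagged `on_border`.
Blank images segment to an empty labelling rather than erroring.
Classification thresholds are run-level constants — the same value
applies to every image of a comparison set by construction, since
per-image thresholds would bias group contrasts.

## Abundance and group statistics

Only centroids strictly inside the fascicle polygon are counted; area
comes from polygon geometry (µm² → mm² by 1e6). The statistical unit
is the animal (sections pooled or averaged per animal before testing);
whether the original workflows used sections or animals as replicates
is ambiguous, and animal-level is the conservative choice. The test
battery: Shapiro–Wilk and Levene preflight, one-way ANOVA with Tukey
HSD for percentages/densities/EDM ratios, paired t for EdU fractions,
exact Mann–Whitney U for expression contrasts, α = 0.05. A
Mann-Whitney fallback on normality failure is available but off by
default, matching the ANOVA-based original analyses.

## Depth profiling (`depthmap`)

The EDM holds, per pixel, the exact point-to-segment distance (µm) to
the nearest point of either surface polyline, computed in floating
point; the 16-bit quantized maps of interactive tooling are an
implementation artifact we deliberately do not reproduce. Rasterized
polyline pixels are forced to exactly zero. A cell's depth is the mean
EDM over its nuclear mask; normalization is by the maximum EDM over
in-ROI *pixels* (the deepest point of the map, not of any cell).
Quartiles are [0,.25), [.25,.5), [.5,.75), [.75,1] with Q1 outermost
and the upper edge closed.

"Percentage of each population per quartile" admits two readings. The
default (`convention="composition"`) takes the GFP⁺ percentage among
cells in the quartile, normalized by the whole-section GFP⁺ percentage;
the alternative (`convention="population"`) takes the fraction of the
GFP⁺ population falling in the quartile normalized by the fraction of
all cells there. The two produce identical enrichment ratios (both
equal the joint/marginal ratio), differing only in the reported
percentage column, which is why a single default suffices. By
construction the count-weighted mean of the ratios is exactly 1.
Sections with gross artifacts are excluded by a manual QC flag, never
auto-detected.

## Duplex ISH (`ishcoloc`)

The forward model renders transcript puncta as small disks of optical
density and mixes them via Beer–Lambert:
I_c = I0_c·10^(−Σ_s M[c,s]·A_s) with unit-norm stain columns. Stain
vectors are estimated from single-colour controls as the unit mean OD
direction over pixels with ‖OD‖ above a 0.05 floor; in the noise-free
limit every stained pixel's OD is exactly proportional to the true
column, so estimation and the subsequent A = M⁻¹·OD unmixing are exact
(closure to ≤1e-6 relative error is a tested invariant). The OD
transform clips intensities to [1, I0] to avoid log 0 on 8-bit-scaled
data; generator amplitudes keep maximum OD below that clip. Collinear
control vectors are rejected at condition number > 50.

The analysis grid is 50 × 50 µm in physical units, axis-aligned and
anchored at the ROI bounding-box origin (the original registration is
unstated); a unit is included iff ≥50% of its pixels are inside the
ROI, and means use in-ROI pixels only. Spearman ρ with tie-corrected
ranks is the only association statistic offered: ranks are invariant
to any monotone transform, so the choice between OD amounts and
inverted 8-bit renderings — unstated in the original workflow — cannot
change ρ. Exact two-sided p by full pairing enumeration for n ≤ 8
units, asymptotic beyond; sections aggregate as the arithmetic mean of
per-section ρ and of per-section p. The colocalization parameter
`coloc_kappa` places each macrophage within 15 µm of a random
Csf1-high fibroblast with probability κ; the colocalized preset's
density was chosen so that condition yields mean ρ ≈ 0.44, with the
uniform null (κ = 0) centring on 0.

## qPCR (`qpcr`)

Technical duplicates are averaged (one missing → the present value,
flagged; |Δ| > 1 cycle → QC warning). Undetectable = missing or
CT ≥ 40 (common convention; unstated originally). A panel gene is
excluded iff more than one macrophage sample *and* more than one
fibroblast sample are undetectable; genes with aberrant amplification
are excluded only via an explicit input list, never auto-detected.
ΔCT = mean(housekeeping CT) − gene CT, so higher ΔCT means higher
expression and ΔCT is invariant to any per-sample plate shift.
ΔΔCT = mean ΔCT(A) − mean ΔCT(B) equals log₂ fold change under
ideal amplification efficiency; 15-cycle pre-amplification is not
modelled (CT values are taken as given). No multiple-testing
adjustment gates results, matching the original reporting; a
Benjamini–Hochberg column is emitted as supplementary output.

PCA runs on centred, unit-variance-scaled ΔCT via SVD (the default
preprocessing of the web tool the original analysis used; `none` and
`pareto` scalings are available). The PC1 sign is fixed so the
macrophage marker set (*Adgre1, Mrc1, Csf1r, Cx3cr1, C1qc, Lyve1,
Folr2*) has positive mean loading — PCA signs are otherwise arbitrary
and tests need determinism. The macrophage-focused gene subset is
{g : PC1 loading > 0}. Hierarchical clustering uses correlation
distance with average linkage. On the `qpcr-study` preset PC1 carries
≈92% of variance and separates populations at p < 1e-10; the
corresponding percentage measured on the unpublished real plate is a
context anchor only, since that matrix cannot be regenerated.

## Internalisation (`internalization`)

Marker flags are run-level per-channel thresholds. The suspension
generator draws marker positivity per class × channel as a Bernoulli
mixture (rates: CD206⁺ in 0.4% and F4/80⁺ in 1.3% of CFP⁺
fibroblasts; 85% / 95% of macrophages), and DQ-collagen positivity
class-conditionally with the macrophage rate split by CD206 state
(0.754 if CD206⁺; 0.646 if CD206⁻, derived so the pooled F4/80⁺
population lands at the reported 67.9%). This mirrors the
receptor-mediated-uptake mechanism the assay probes. Because the
CD206⁺ pool contains ≈3% non-macrophage cells with near-zero DQ
rates, its expected DQ⁺ percentage is ≈73%, slightly below the
macrophage-conditional 75.4% — an intended property of the
contamination model, tested against the analytic expectation.

## Problem sizes and numerics

Recovery experiments use 4 seeds/preset (abundance, explant), 4
virtual animals × 10 sections (proliferation), and 20 seeds (depth
uniformity, ISH correlation); abundance sections are ≈3 mm² (~4k–10k
cells). These sizes put Monte-Carlo SEs well inside the effect sizes
of interest while keeping a full run at minutes on one CPU. All seeds
are explicit spec fields; derived seeds use `(base·1009 + k) mod 2³¹`.
Degenerate inputs are defined rather than fatal wherever a downstream
value exists (blank image → empty labelling; empty ROI → missing
percentage; constant channel → missing ρ; zero denominators → missing
fractions with exclusion warnings).

## Known limitations

- Segmentation is validated on ellipse-rendered nuclei; heavily
  confluent real tissue may need tuned seeding parameters.
- The ISH forward model draws expression per cell independently;
  spatial autocorrelation of expression beyond cell placement is not
  modelled, so grid-ρ magnitudes transfer only qualitatively.
- qPCR efficiency differences between assays, and pre-amplification
  bias, are outside the model.
- Manual counting workflows (EdU⁺, F4/80⁺) are replaced throughout by
  thresholded classification; manual counts are not reproducible in
  software.
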