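"""High-throughput qPCR: dCT, age contrast, PCA, ligand-receptor pairs.

Simulates the 40-sample (2 populations x 2 tissues x 2 ages x 5
replicates, in technical duplicate) plate, collapses duplicates,
applies exclusions, computes dCT against the three housekeeping genes,
and summarizes the macrophage age contrast, the global PCA, and the
fibroblast->macrophage Csf1-Csf1r axis.
"""

from tenomac import qpcr, synth

spec = synth.preset("qpcr-study", seed=1)
ct_raw, meta, _ = synth.generate_ct_matrix(spec)
em = qpcr.collapse_duplicates(ct_raw, meta)
em = qpcr.apply_exclusions(em, ("Sema4c",))
em = qpcr.delta_ct(em)

excluded = em.gene_meta.loc[em.gene_meta.role == "excluded", "gene"]
print(f"excluded genes: {', '.join(excluded)}")

volcano = qpcr.ddct_contrast(
    em, dict(population="macrophage", tissue="limb", age="P56"),
    dict(population="macrophage", tissue="limb", age="P14"))
top = volcano.dropna().nlargest(3, "ddct")
print("top P56-vs-P14 macrophage genes (ddCT = log2 fold change):")
for _, r in top.iterrows():
    print(f"  {r.gene:>8}  ddCT {r.ddct:+.2f}  p {r.p:.4f}")

pca = qpcr.pca_and_cluster(em)
print(f"PC1 explains {pca['pct_variance'].iloc[0]:.1f}% of variance; "
      f"{len(pca['pc1_positive_genes'])} genes load positively "
      "(macrophage-associated)")

lr = qpcr.ligand_receptor_report(em)
csf1 = lr[lr.ligand == "Csf1"]
print("Csf1 (fibroblast) -> Csf1r (macrophage):")
for _, r in csf1.iterrows():
    print(f"  {r.age}: ligand dCT {r.ligand_mean_dct:.2f}, "
          f"receptor dCT {r.receptor_mean_dct:.2f}")
# Higher dCT means higher expression. Rising fibroblast Csf1 with age
# alongside receptor expression in macrophages is the crosstalk pattern
# the pairing report is designed to surface.
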