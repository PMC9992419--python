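"""High-throughput qPCR expression analysis.

Raw plate CTs arrive as technical duplicate columns; duplicates are
averaged, genes with widespread undetectable measurements are excluded,
and expression is summarized as dCT = mean(housekeeping CT) - gene CT
against three housekeeping genes (so higher dCT means higher
expression).  Group contrasts report ddCT = mean dCT(A) - mean dCT(B),
which equals log2 fold change, with exact two-sided Mann-Whitney U
p-values and no multiple-testing adjustment (a Benjamini-Hochberg
column is emitted as supplementary output only).  PCA runs on centered,
unit-variance-scaled dCT via SVD with a deterministic sign convention,
and hierarchical clustering uses correlation distance with average
linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .stats import mannwhitney_exact
from .synth import HOUSEKEEPING_DEFAULT

__all__ = ["ExpressionMatrix", "collapse_duplicates", "apply_exclusions",
           "delta_ct", "ddct_contrast", "pca_and_cluster",
           "ligand_receptor_report", "DEFAULT_LR_PAIRS",
           "MACROPHAGE_MARKERS"]

MACROPHAGE_MARKERS = ("Adgre1", "Mrc1", "Csf1r", "Cx3cr1", "C1qc",
                      "Lyve1", "Folr2")

# (ligand, receptor, sender population, receiver population)
DEFAULT_LR_PAIRS = (
    ("Csf1", "Csf1r", "fibroblast", "macrophage"),
    ("Il6", "Il6ra", "fibroblast", "macrophage"),
    ("Cx3cl1", "Cx3cr1", "fibroblast", "macrophage"),
    ("Gas6", "Axl", "macrophage", "fibroblast"),
    ("Tgfb1", "Tgfbr2", "macrophage", "fibroblast"),
    ("Pdgfb", "Pdgfra", "macrophage", "fibroblast"),
)


@dataclass
class ExpressionMatrix:
    """Genes x samples CT values with sample and gene metadata.

    ``ct`` columns are sample ids (duplicates already collapsed);
    ``sample_meta`` has one row per sample (population, tissue, age,
    replicate); ``gene_meta`` assigns each gene a role in
    {panel, housekeeping, excluded}.  ``dct`` is filled by `delta_ct`.
    """

    ct: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    dct: pd.DataFrame | None = None
    qc: pd.DataFrame | None = None
    detection_limit_ct: float = 40.0
    housekeeping_genes: tuple = HOUSEKEEPING_DEFAULT

    def samples_where(self, **criteria) -> list[str]:
        m = self.sample_meta
        mask = np.ones(len(m), dtype=bool)
        for k, v in criteria.items():
            mask &= (m[k] == v).to_numpy()
        return list(m.loc[mask, "sample_id"])

    def panel_genes(self) -> list[str]:
        gm = self.gene_meta
        return list(gm.loc[gm["role"] == "panel", "gene"])


def collapse_duplicates(ct_raw: pd.DataFrame, sample_meta: pd.DataFrame,
                        housekeeping_genes=HOUSEKEEPING_DEFAULT,
                        detection_limit_ct: float = 40.0,
                        duplicate_delta_warn: float = 1.0,
                        ) -> ExpressionMatrix:
    """Average technical duplicates into one CT column per sample.

    Both duplicates missing -> missing; one missing -> the present
    value, flagged in the QC table; |duplicate difference| above
    ``duplicate_delta_warn`` cycles also raises a QC warning row.
    """
    meta = sample_meta.copy()
    required = {"column", "sample_id", "duplicate"}
    if not required.issubset(meta.columns):
        raise ValueError(f"sample_meta must contain columns {sorted(required)}")
    counts = meta.groupby("sample_id")["column"].count()
    unpaired = counts[counts != 2]
    if len(unpaired):
        raise ValueError(
            f"unpaired duplicate columns for samples: {list(unpaired.index)}")

    qc_rows = []
    data = {}
    for sid, grp in meta.groupby("sample_id", sort=False):
        cols = list(grp.sort_values("duplicate")["column"])
        pair = ct_raw[cols]
        mean = pair.mean(axis=1, skipna=True)      # one-missing -> present value
        data[sid] = mean
        one_missing = pair.isna().sum(axis=1) == 1
        for g in pair.index[one_missing]:
            qc_rows.append({"sample_id": sid, "gene": g,
                            "flag": "single_duplicate",
                            "detail": "one duplicate undetectable"})
        delta = (pair[cols[0]] - pair[cols[1]]).abs()
        for g in pair.index[(delta > duplicate_delta_warn).fillna(False)]:
            qc_rows.append({"sample_id": sid, "gene": g,
                            "flag": "duplicate_discordance",
                            "detail": f"|dCT|={delta[g]:.2f} cycles"})

    ct = pd.DataFrame(data)
    ct.index.name = "gene"
    per_sample = (meta.drop(columns=["column", "duplicate"])
                  .drop_duplicates("sample_id").reset_index(drop=True))
    gene_meta = pd.DataFrame({
        "gene": ct.index,
        "role": ["housekeeping" if g in housekeeping_genes else "panel"
                 for g in ct.index]})
    qc = pd.DataFrame(qc_rows, columns=["sample_id", "gene", "flag", "detail"])
    return ExpressionMatrix(ct=ct, sample_meta=per_sample,
                            gene_meta=gene_meta, qc=qc,
                            detection_limit_ct=detection_limit_ct,
                            housekeeping_genes=tuple(housekeeping_genes))


def _undetectable(em: ExpressionMatrix) -> pd.DataFrame:
    return em.ct.isna() | (em.ct >= em.detection_limit_ct)


def apply_exclusions(em: ExpressionMatrix,
                     manual_exclusions: tuple[str, ...] = (),
                     ) -> ExpressionMatrix:
    """Flag genes excluded by the undetectability rule or a manual list.

    Rule: a gene is excluded iff more than one sample in the macrophage
    population AND more than one sample in the fibroblast population
    are undetectable.  Genes with aberrant amplification are excluded
    only via ``manual_exclusions`` — never auto-detected.
    """
    undet = _undetectable(em)
    excluded = set(manual_exclusions)
    mac_samples = em.samples_where(population="macrophage")
    fib_samples = em.samples_where(population="fibroblast")
    for g in em.ct.index:
        if g in em.housekeeping_genes:
            continue
        n_mac = int(undet.loc[g, mac_samples].sum()) if mac_samples else 0
        n_fib = int(undet.loc[g, fib_samples].sum()) if fib_samples else 0
        if n_mac > 1 and n_fib > 1:
            excluded.add(g)
    gene_meta = em.gene_meta.copy()
    sel = gene_meta["gene"].isin(excluded) & (gene_meta["role"] != "housekeeping")
    gene_meta.loc[sel, "role"] = "excluded"
    return ExpressionMatrix(ct=em.ct, sample_meta=em.sample_meta,
                            gene_meta=gene_meta, dct=em.dct, qc=em.qc,
                            detection_limit_ct=em.detection_limit_ct,
                            housekeeping_genes=em.housekeeping_genes)


def delta_ct(em: ExpressionMatrix) -> ExpressionMatrix:
    """dCT_{g,s} = mean(housekeeping CT_s) - CT_{g,s}.

    Samples missing any housekeeping CT get all-missing dCT with a
    warning; undetectable gene CTs yield missing dCT.
    """
    hk = list(em.housekeeping_genes)
    missing_hk = [g for g in hk if g not in em.ct.index]
    if missing_hk:
        raise ValueError(f"housekeeping genes absent from matrix: {missing_hk}")
    undet = _undetectable(em)
    ct = em.ct.mask(undet)
    hk_ct = ct.loc[hk]
    hk_mean = hk_ct.mean(axis=0)
    bad = hk_ct.isna().any(axis=0)
    if bad.any():
        warnings.warn(
            f"samples with missing housekeeping CT: {list(ct.columns[bad])}; "
            "their dCT values are emitted as missing", stacklevel=2)
        hk_mean[bad] = np.nan
    dct = hk_mean - ct
    dct = dct.drop(index=hk)
    return ExpressionMatrix(ct=em.ct, sample_meta=em.sample_meta,
                            gene_meta=em.gene_meta, dct=dct, qc=em.qc,
                            detection_limit_ct=em.detection_limit_ct,
                            housekeeping_genes=em.housekeeping_genes)


def ddct_contrast(em: ExpressionMatrix, group_a: dict, group_b: dict,
                  min_n: int = 3) -> pd.DataFrame:
    """Per-gene ddCT (= log2 fold change) of group A over group B.

    ``group_a`` / ``group_b`` are sample_meta criteria, e.g.
    ``dict(age="P56", tissue="limb", population="macrophage")``.
    Returns a volcano table (gene, ddct, p, n_a, n_b, p_bh); genes with
    fewer than ``min_n`` dCT values in either group are skipped with a
    note column.  p_bh is supplementary and never gates results.
    """
    if em.dct is None:
        raise ValueError("run delta_ct first")
    a_cols = em.samples_where(**group_a)
    b_cols = em.samples_where(**group_b)
    rows = []
    for g in em.panel_genes():
        if g not in em.dct.index:
            continue
        a = em.dct.loc[g, a_cols].dropna().to_numpy()
        b = em.dct.loc[g, b_cols].dropna().to_numpy()
        if len(a) < min_n or len(b) < min_n:
            rows.append({"gene": g, "ddct": np.nan, "p": np.nan,
                         "n_a": len(a), "n_b": len(b),
                         "note": "insufficient samples"})
            continue
        mw = mannwhitney_exact(a, b)
        rows.append({"gene": g, "ddct": float(a.mean() - b.mean()),
                     "p": mw["p"], "n_a": len(a), "n_b": len(b), "note": ""})
    df = pd.DataFrame(rows)
    ok = df["p"].notna()
    df["p_bh"] = np.nan
    if ok.any():
        p = df.loc[ok, "p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            running = min(running, p[i] * m / (rank_pos + 1))
            adj[i] = running
        df.loc[ok, "p_bh"] = adj
    return df


def pca_and_cluster(em: ExpressionMatrix, scaling: str = "unit_variance",
                    marker_genes=MACROPHAGE_MARKERS) -> dict:
    """PCA of dCT with loading-based gene subsetting and clustering.

    Genes are centered and, by default, unit-variance scaled; the
    decomposition is by SVD on the samples x genes matrix.  The PC1
    sign is fixed so the macrophage marker set has positive mean PC1
    loading, making the orientation deterministic.  Returns scores,
    loadings, percent variance per PC, the gene subset with positive
    PC1 loading, and sample/gene linkage matrices (correlation
    distance, average linkage).
    """
    if em.dct is None:
        raise ValueError("run delta_ct first")
    genes = [g for g in em.panel_genes() if g in em.dct.index]
    X = em.dct.loc[genes].T            # samples x genes
    X = X.dropna(axis=1, how="any")    # listwise over genes
    genes = list(X.columns)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need >= 3 samples and >= 2 genes after "
                         "missing-value handling")
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"dropping constant genes under unit-variance "
                      f"scaling: {list(X.columns[constant])}", stacklevel=2)
        X = X.loc[:, ~constant]
        genes = list(X.columns)
        sd = sd[~constant]
    Xc = X - X.mean(axis=0)
    if scaling == "unit_variance":
        Xs = Xc / sd
    elif scaling == "pareto":
        Xs = Xc / np.sqrt(sd)
    elif scaling == "none":
        Xs = Xc
    else:
        raise ValueError(f"unknown scaling {scaling!r}")

    U, S, Vt = np.linalg.svd(Xs.to_numpy(), full_matrices=False)
    var = S ** 2
    pct_var = 100.0 * var / var.sum()
    scores = U * S                      # samples x PCs
    loadings = Vt.T                     # genes x PCs

    # deterministic orientation: macrophage markers load positively on PC1
    present = [g for g in marker_genes if g in genes]
    if present:
        idx = [genes.index(g) for g in present]
        if loadings[idx, 0].mean() < 0:
            loadings[:, 0] *= -1
            scores[:, 0] *= -1

    n_pc = len(S)
    pc_names = [f"PC{i + 1}" for i in range(n_pc)]
    scores_df = pd.DataFrame(scores, index=X.index, columns=pc_names)
    loadings_df = pd.DataFrame(loadings, index=genes, columns=pc_names)
    subset = [g for g in genes if loadings_df.loc[g, "PC1"] > 0]

    sample_link = hierarchy.linkage(pdist(Xs, metric="correlation"),
                                    method="average")
    gene_link = hierarchy.linkage(pdist(Xs.T, metric="correlation"),
                                  method="average")
    return {
        "scores": scores_df,
        "loadings": loadings_df,
        "pct_variance": pd.Series(pct_var, index=pc_names),
        "pc1_positive_genes": subset,
        "sample_linkage": sample_link,
        "gene_linkage": gene_link,
        "heatmap_table": Xs.T,          # genes x samples, scaled dCT
    }


def ligand_receptor_report(em: ExpressionMatrix,
                           pairs=DEFAULT_LR_PAIRS,
                           ages: tuple[str, ...] = ("P14", "P56"),
                           tissue: str = "limb") -> pd.DataFrame:
    """Paired ligand (sender) / receptor (receiver) expression table.

    One row per pair x age: mean ligand dCT in the sender population,
    mean receptor dCT in the receiver population, plus an age-contrast
    Mann-Whitney p per gene.  Pairs touching excluded or absent genes
    are emitted with missing values and a note, never dropped silently.
    """
    if em.dct is None:
        raise ValueError("run delta_ct first")
    excluded = set(em.gene_meta.loc[em.gene_meta["role"] == "excluded",
                                    "gene"])
    rows = []
    for ligand, receptor, sender, receiver in pairs:
        notes = []
        for g in (ligand, receptor):
            if g not in em.dct.index:
                notes.append(f"{g} absent from panel")
            elif g in excluded:
                notes.append(f"{g} excluded")
        usable = not notes

        def group_vals(gene, pop, age):
            cols = em.samples_where(population=pop, tissue=tissue, age=age)
            return em.dct.loc[gene, cols].dropna().to_numpy()

        age_p = {}
        if usable:
            for g, pop in ((ligand, sender), (receptor, receiver)):
                g1 = group_vals(g, pop, ages[0])
                g2 = group_vals(g, pop, ages[1])
                age_p[g] = (mannwhitney_exact(g2, g1)["p"]
                            if len(g1) >= 3 and len(g2) >= 3 else np.nan)
        for age in ages:
            row = {"ligand": ligand, "receptor": receptor,
                   "sender": sender, "receiver": receiver, "age": age,
                   "tissue": tissue,
                   "ligand_mean_dct": np.nan, "receptor_mean_dct": np.nan,
                   "ligand_age_p": np.nan, "receptor_age_p": np.nan,
                   "note": "; ".join(notes)}
            if usable:
                lv = group_vals(ligand, sender, age)
                rv = group_vals(receptor, receiver, age)
                row["ligand_mean_dct"] = (float(lv.mean()) if len(lv)
                                          else np.nan)
                row["receptor_mean_dct"] = (float(rv.mean()) if len(rv)
                                            else np.nan)
                row["ligand_age_p"] = age_p.get(ligand, np.nan)
                row["receptor_age_p"] = age_p.get(receptor, np.nan)
            rows.append(row)
    return pd.DataFrame(rows)
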