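"""Duplicate collapse, exclusions, dCT/ddCT, PCA, ligand-receptor."""

import dataclasses
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tenomac import qpcr, synth
from tenomac.stats import mannwhitney_exact


def _raw(genes, values_by_sample):
    """Build a raw duplicate table: values_by_sample maps sample_id ->
    {gene: (d1, d2)} plus metadata (population)."""
    data, meta = {}, []
    for sid, (pop, pairs) in values_by_sample.items():
        for dup in (1, 2):
            col = f"{sid}::d{dup}"
            data[col] = [pairs[g][dup - 1] for g in genes]
            meta.append({"column": col, "sample_id": sid, "population": pop,
                         "tissue": "limb", "age": "P14", "replicate": 1,
                         "duplicate": dup})
    return (pd.DataFrame(data, index=pd.Index(genes, name="gene")),
            pd.DataFrame(meta))


class TestCollapseDuplicates:
    def test_mean_of_duplicates(self):
        raw, meta = _raw(["18s", "Abl1", "Rps17", "G1"],
                         {"s1": ("macrophage",
                                 {"18s": (12, 12), "Abl1": (26, 26),
                                  "Rps17": (22, 22), "G1": (20.0, 20.4)})})
        em = qpcr.collapse_duplicates(raw, meta)
        assert em.ct.loc["G1", "s1"] == pytest.approx(20.2)

    def test_single_missing_duplicate_keeps_value_with_flag(self):
        raw, meta = _raw(["18s", "Abl1", "Rps17", "G1"],
                         {"s1": ("macrophage",
                                 {"18s": (12, 12), "Abl1": (26, 26),
                                  "Rps17": (22, 22),
                                  "G1": (20.0, np.nan)})})
        em = qpcr.collapse_duplicates(raw, meta)
        assert em.ct.loc["G1", "s1"] == 20.0
        assert ((em.qc["flag"] == "single_duplicate") &
                (em.qc["gene"] == "G1")).any()

    def test_discordant_duplicates_flagged(self):
        raw, meta = _raw(["18s", "Abl1", "Rps17", "G1"],
                         {"s1": ("macrophage",
                                 {"18s": (12, 12), "Abl1": (26, 26),
                                  "Rps17": (22, 22), "G1": (20.0, 21.5)})})
        em = qpcr.collapse_duplicates(raw, meta)
        assert (em.qc["flag"] == "duplicate_discordance").any()

    def test_unpaired_column_rejected(self):
        raw, meta = _raw(["18s"], {"s1": ("macrophage", {"18s": (12, 12)})})
        with pytest.raises(ValueError, match="unpaired"):
            qpcr.collapse_duplicates(raw.iloc[:, :1], meta.iloc[:1])


def _study_em(seed=0, **overrides):
    spec = dataclasses.replace(synth.preset("qpcr-study"), seed=seed,
                               **overrides)
    ct_raw, meta, truth = synth.generate_ct_matrix(spec)
    em = qpcr.collapse_duplicates(ct_raw, meta,
                                  housekeeping_genes=spec.housekeeping_genes)
    return spec, em, truth


class TestExclusions:
    def test_widespread_undetectable_gene_excluded(self):
        _, em, _ = _study_em()
        em = qpcr.apply_exclusions(em)
        roles = em.gene_meta.set_index("gene")["role"]
        assert roles["Il2"] == "excluded"
        assert roles["Il2ra"] == "excluded"

    def test_single_population_undetectability_retained(self):
        raw, meta = _raw(
            ["18s", "Abl1", "Rps17", "G1"],
            {f"m{i}": ("macrophage",
                       {"18s": (12, 12), "Abl1": (26, 26),
                        "Rps17": (22, 22), "G1": (np.nan, np.nan)})
             for i in range(3)} |
            {f"f{i}": ("fibroblast",
                       {"18s": (12, 12), "Abl1": (26, 26),
                        "Rps17": (22, 22), "G1": (20.0, 20.2)})
             for i in range(3)})
        em = qpcr.apply_exclusions(qpcr.collapse_duplicates(raw, meta))
        assert em.gene_meta.set_index("gene")["role"]["G1"] == "panel"

    def test_manual_exclusion_list(self):
        _, em, _ = _study_em()
        em = qpcr.apply_exclusions(em, ("Sema4c",))
        assert em.gene_meta.set_index("gene")["role"]["Sema4c"] == "excluded"
        em2 = qpcr.apply_exclusions(em)   # empty manual list
        roles = em2.gene_meta.set_index("gene")["role"]
        assert (roles == "excluded").sum() >= 2


class TestDeltaCt:
    def test_arithmetic(self):
        raw, meta = _raw(["18s", "Abl1", "Rps17", "G1"],
                         {"s1": ("macrophage",
                                 {"18s": (10, 10), "Abl1": (12, 12),
                                  "Rps17": (14, 14), "G1": (9.0, 9.0)})})
        em = qpcr.delta_ct(qpcr.collapse_duplicates(raw, meta))
        assert em.dct.loc["G1", "s1"] == pytest.approx(3.0)

    def test_gene_at_housekeeping_mean_gives_zero(self):
        raw, meta = _raw(["18s", "Abl1", "Rps17", "G1"],
                         {"s1": ("macrophage",
                                 {"18s": (10, 10), "Abl1": (12, 12),
                                  "Rps17": (14, 14), "G1": (12.0, 12.0)})})
        em = qpcr.delta_ct(qpcr.collapse_duplicates(raw, meta))
        assert em.dct.loc["G1", "s1"] == pytest.approx(0.0)

    def test_noise_free_matrix_recovers_generator_offsets(self):
        spec, em, truth = _study_em(noise_sd=0.0, duplicate_jitter_sd=0.0)
        em = qpcr.delta_ct(em)
        for _, row in truth.sample(20, random_state=0).iterrows():
            cols = em.samples_where(population=row.population,
                                    tissue=row.tissue, age=row.age)
            vals = em.dct.loc[row.gene, cols].dropna()
            if len(vals):
                np.testing.assert_allclose(vals, row.offset, atol=1e-9)

    def test_plate_shift_invariance(self):
        _, em, _ = _study_em()
        em1 = qpcr.delta_ct(em)
        shifted = dataclasses.replace(em, ct=em.ct + 1.7)
        em2 = qpcr.delta_ct(shifted)
        pd.testing.assert_frame_equal(em1.dct, em2.dct)


class TestDdctContrast:
    A = dict(population="macrophage", tissue="limb", age="P56")
    B = dict(population="macrophage", tissue="limb", age="P14")

    def test_identical_groups_null(self):
        spec, em, _ = _study_em(noise_sd=0.0, duplicate_jitter_sd=0.0)
        em = qpcr.delta_ct(em)
        v = qpcr.ddct_contrast(
            em, dict(population="fibroblast", tissue="limb", age="P14"),
            dict(population="fibroblast", tissue="tail", age="P14"))
        row = v.set_index("gene").loc["Col1a1"]
        assert row["ddct"] == pytest.approx(0.0, abs=1e-9)
        assert row["p"] == pytest.approx(1.0)

    def test_separated_groups_match_enumeration_oracle(self):
        """U = 0 and the exact p equals full enumeration of rank splits."""
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([6.0, 7.0, 8.0, 9.0, 10.0])
        res = mannwhitney_exact(a, b)
        assert res["U"] == 0.0
        pooled = np.concatenate([a, b])
        obs_u = 0.0
        count = 0
        total = 0
        for idx in combinations(range(10), 5):
            ga = pooled[list(idx)]
            gb = pooled[[i for i in range(10) if i not in idx]]
            u = sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)
            u = min(u, 25 - u)
            if u <= min(obs_u, 25 - obs_u):
                count += 1
            total += 1
        assert res["p"] == pytest.approx(count / total)

    def test_antisymmetry(self):
        _, em, _ = _study_em(seed=3)
        em = qpcr.delta_ct(em)
        v1 = qpcr.ddct_contrast(em, self.A, self.B).set_index("gene")["ddct"]
        v2 = qpcr.ddct_contrast(em, self.B, self.A).set_index("gene")["ddct"]
        pd.testing.assert_series_equal(v1, -v2)

    def test_power_for_two_cycle_shift(self):
        """A +2 dCT offset at n=5/5, noise 0.3 is detected >= 90% of runs."""
        spec = synth.QpcrSpec(
            gene_panel={"G1": {("macrophage", "limb", "P56"): 2.0}},
            noise_sd=0.3, n_samples_per_group=5,
            tissues=("limb",), ages=("P14", "P56"))
        hits = 0
        for s in range(100):
            ct_raw, meta, _ = synth.generate_ct_matrix(
                dataclasses.replace(spec, seed=s))
            em = qpcr.delta_ct(qpcr.collapse_duplicates(ct_raw, meta))
            v = qpcr.ddct_contrast(
                em, dict(population="macrophage", age="P56"),
                dict(population="macrophage", age="P14"))
            hits += v.set_index("gene").loc["G1", "p"] < 0.05
        assert hits >= 90

    def test_offset_recovery_unbiased(self):
        """Generator dCT offsets recovered with |bias| < 0.05 cycles."""
        spec = synth.QpcrSpec(
            gene_panel={"G1": {("macrophage", "limb", "P56"): 2.0}},
            noise_sd=0.3, n_samples_per_group=5,
            tissues=("limb",), ages=("P14", "P56"))
        est = []
        for s in range(400):
            ct_raw, meta, _ = synth.generate_ct_matrix(
                dataclasses.replace(spec, seed=s))
            em = qpcr.delta_ct(qpcr.collapse_duplicates(ct_raw, meta))
            v = qpcr.ddct_contrast(
                em, dict(population="macrophage", age="P56"),
                dict(population="macrophage", age="P14"))
            est.append(v.set_index("gene").loc["G1", "ddct"])
        assert abs(np.mean(est) - 2.0) < 0.05


class TestPcaAndCluster:
    def test_variance_conservation_and_separation(self):
        _, em, _ = _study_em(seed=1)
        em = qpcr.apply_exclusions(em, ("Sema4c",))
        em = qpcr.delta_ct(em)
        pca = qpcr.pca_and_cluster(em)
        assert pca["pct_variance"].sum() == pytest.approx(100.0, abs=1e-9)
        sc = pca["scores"]["PC1"]
        mac = em.samples_where(population="macrophage")
        fib = em.samples_where(population="fibroblast")
        assert mannwhitney_exact(sc[mac], sc[fib])["p"] < 0.001
        assert sc[mac].mean() > sc[fib].mean()   # deterministic orientation

    def test_duplicated_samples_leave_loadings_unchanged(self):
        _, em, _ = _study_em(seed=2)
        em = qpcr.delta_ct(em)
        p1 = qpcr.pca_and_cluster(em)
        doubled = dataclasses.replace(
            em,
            ct=pd.concat([em.ct, em.ct.add_suffix("_b")], axis=1),
            dct=pd.concat([em.dct, em.dct.add_suffix("_b")], axis=1),
            sample_meta=pd.concat([
                em.sample_meta,
                em.sample_meta.assign(
                    sample_id=em.sample_meta.sample_id + "_b")],
                ignore_index=True))
        p2 = qpcr.pca_and_cluster(doubled)
        np.testing.assert_allclose(np.abs(p1["loadings"]["PC1"]),
                                   np.abs(p2["loadings"]["PC1"]), atol=1e-8)

    def test_pc1_positive_subset_matches_loadings(self):
        _, em, _ = _study_em(seed=1)
        em = qpcr.delta_ct(em)
        pca = qpcr.pca_and_cluster(em)
        lo = pca["loadings"]["PC1"]
        assert set(pca["pc1_positive_genes"]) == set(lo.index[lo > 0])
        assert set(qpcr.MACROPHAGE_MARKERS) <= set(pca["pc1_positive_genes"])

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=1000))
    def test_variance_sums_to_100_property(self, seed):
        _, em, _ = _study_em(seed=seed)
        em = qpcr.delta_ct(em)
        pca = qpcr.pca_and_cluster(em)
        assert pca["pct_variance"].sum() == pytest.approx(100.0, abs=1e-9)


class TestLigandReceptorReport:
    def test_absent_gene_flagged_not_crashing(self):
        _, em, _ = _study_em()
        em = qpcr.delta_ct(em)
        rep = qpcr.ligand_receptor_report(
            em, pairs=(("NotAGene", "Csf1r", "fibroblast", "macrophage"),))
        assert len(rep) == 2
        assert rep["note"].str.contains("absent").all()
        assert rep["ligand_mean_dct"].isna().all()

    def test_csf1_age_contrast_significant(self):
        _, em, _ = _study_em(seed=5)
        em = qpcr.delta_ct(em)
        rep = qpcr.ligand_receptor_report(em)
        csf1 = rep[rep.ligand == "Csf1"].iloc[0]
        assert csf1["ligand_age_p"] < 0.05
        p56 = rep[(rep.ligand == "Csf1") & (rep.age == "P56")].iloc[0]
        p14 = rep[(rep.ligand == "Csf1") & (rep.age == "P14")].iloc[0]
        assert p56["ligand_mean_dct"] > p14["ligand_mean_dct"]

    def test_null_generator_type_one_error_controlled(self):
        """With no age effect, significant age contrasts stay near alpha."""
        panel = {"Csf1": {}, "Csf1r": {}}
        spec = synth.QpcrSpec(gene_panel=panel, noise_sd=0.3,
                              n_samples_per_group=5, tissues=("limb",),
                              ages=("P14", "P56"))
        sig = 0
        total = 0
        for s in range(100):
            ct_raw, meta, _ = synth.generate_ct_matrix(
                dataclasses.replace(spec, seed=s))
            em = qpcr.delta_ct(qpcr.collapse_duplicates(ct_raw, meta))
            rep = qpcr.ligand_receptor_report(
                em, pairs=(("Csf1", "Csf1r", "fibroblast", "macrophage"),))
            p = rep["ligand_age_p"].iloc[0]
            if np.isfinite(p):
                sig += p < 0.05
                total += 1
        # binomial(100, 0.05): 3-sigma upper bound ~ 11.5
        assert sig <= 12
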