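"""Generator: ground-truth consistency, presets, and forward models."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from shapely.geometry import Polygon

from tenomac import synth


class TestSectionGeneration:
    def test_zero_macrophage_fraction_yields_no_macrophages(
            self, small_section_spec):
        spec = dataclasses.replace(small_section_spec,
                                   macrophage_fraction=0.0,
                                   peritenon_macrophage_fraction=0.0)
        _, truth = synth.generate_section(spec)
        assert (truth["cell_class"] == "fibroblast").all()

    def test_cell_count_matches_independent_rerun_of_sampling_recipe(
            self, small_section_spec):
        """First RNG draw of the documented recipe is the Poisson count."""
        _, truth = synth.generate_section(small_section_spec)
        area_mm2 = Polygon(small_section_spec.fascicle_polygon).area / 1e6
        expected_n = np.random.default_rng(small_section_spec.seed).poisson(
            small_section_spec.cell_density_per_mm2 * area_mm2)
        assert int(truth["in_fascicle"].sum()) == int(expected_n)

    def test_determinism_bit_identical(self, small_section_spec):
        img1, truth1 = synth.generate_section(small_section_spec)
        img2, truth2 = synth.generate_section(
            dataclasses.replace(small_section_spec))
        for c in img1.channel_names:
            np.testing.assert_array_equal(img1.channels[c], img2.channels[c])
        pd.testing.assert_frame_equal(truth1, truth2)

    def test_truth_centroids_lie_in_rendered_nuclei(self, small_section_spec):
        spec = dataclasses.replace(small_section_spec, background_sd=0.0)
        img, truth = synth.generate_section(spec)
        h = img.channels["hoechst"]
        px = spec.pixel_size_um
        for _, row in truth.iterrows():
            val = h[int(row.y_um / px), int(row.x_um / px)]
            assert val > spec.background_level + 50

    def test_realized_macrophage_fraction_unbiased(self, small_section_spec):
        fracs = []
        for s in range(50):
            spec = dataclasses.replace(small_section_spec, seed=s,
                                       peritenon_band_um=0.0)
            truth = synth.sample_cells(spec, np.random.default_rng(s))
            fracs.append((truth["cell_class"] == "macrophage").mean())
        fracs = np.asarray(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - spec.macrophage_fraction) < 2 * se

    def test_edu_channel_only_when_labelling_requested(
            self, small_section_spec):
        img, _ = synth.generate_section(small_section_spec)
        assert "edu" not in img.channels
        spec = dataclasses.replace(small_section_spec,
                                   edu_fraction_macrophage=0.5,
                                   edu_fraction_fibroblast=0.2)
        img, truth = synth.generate_section(spec)
        assert "edu" in img.channels

    @pytest.mark.parametrize("bad", [
        dict(macrophage_fraction=1.5),
        dict(cell_density_per_mm2=-1.0),
        dict(pixel_size_um=4.0),                       # nucleus < 2 px
        dict(fascicle_polygon=np.array(               # self-intersecting
            [[0, 0], [100, 100], [100, 0], [0, 100]], float)),
    ])
    def test_invalid_spec_rejected(self, small_section_spec, bad):
        spec = dataclasses.replace(small_section_spec, **bad)
        with pytest.raises(ValueError):
            synth.generate_section(spec)


class TestDuplexIsh:
    def test_beer_lambert_pure_channel(self):
        amounts = np.zeros((3, 1, 1))
        amounts[0] = 1.0
        rgb = synth.beer_lambert(amounts, np.eye(3), (255.0, 255.0, 255.0))
        np.testing.assert_allclose(rgb[0, 0], [25.5, 255.0, 255.0])

    def test_blank_slide_equals_illumination(self, small_ish_spec):
        spec = dataclasses.replace(small_ish_spec, punctum_od=0.0,
                                   nucleus_od=0.0)
        rgb, _, _ = synth.generate_duplex_ish(spec)
        np.testing.assert_allclose(
            rgb, np.broadcast_to(np.asarray(spec.background_white),
                                 rgb.shape))

    def test_nonunit_stain_columns_rejected(self, small_ish_spec):
        spec = dataclasses.replace(small_ish_spec,
                                   stain_od_matrix=np.eye(3) * 2.0)
        with pytest.raises(ValueError, match="unit-norm"):
            synth.generate_duplex_ish(spec)

    def test_kappa_zero_matches_uniform_null(self, small_ish_spec):
        """Macrophage-to-nearest-Csf1-high-fibroblast distances under
        kappa=0 are indistinguishable from Monte-Carlo uniform placement."""
        from scipy.spatial import cKDTree

        spec = dataclasses.replace(small_ish_spec, coloc_kappa=0.0, seed=11)
        _, truth, _ = synth.generate_duplex_ish(spec)
        high = truth.loc[truth["csf1_high"], ["x_um", "y_um"]].to_numpy()
        mac = truth.loc[truth["cell_class"] == "macrophage",
                        ["x_um", "y_um"]].to_numpy()
        tree = cKDTree(high)
        observed = tree.query(mac)[0]

        rng = np.random.default_rng(99)
        poly = Polygon(spec.roi_polygon)
        minx, miny, maxx, maxy = poly.bounds
        pts = []
        while len(pts) < 4000:
            cand = rng.uniform((minx, miny), (maxx, maxy), size=(5000, 2))
            import shapely
            keep = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
            pts.extend(cand[keep].tolist())
        null = tree.query(np.asarray(pts[:4000]))[0]
        assert stats.ks_2samp(observed, null).pvalue > 0.05

    def test_kappa_one_places_macrophages_adjacent(self, small_ish_spec):
        from scipy.spatial import cKDTree

        spec = dataclasses.replace(small_ish_spec, coloc_kappa=1.0, seed=5)
        _, truth, _ = synth.generate_duplex_ish(spec)
        high = truth.loc[truth["csf1_high"], ["x_um", "y_um"]].to_numpy()
        mac = truth.loc[truth["cell_class"] == "macrophage",
                        ["x_um", "y_um"]].to_numpy()
        d = cKDTree(high).query(mac)[0]
        assert np.median(d) <= spec.adjacency_radius_um


class TestSuspension:
    def test_noise_free_intensities_identical_within_state(self):
        models = {
            cls: {ch: synth.MarkerModel(p_pos=p, pos_mean=200, pos_sd=0,
                                        neg_mean=5, neg_sd=0)
                  for ch, p in zip(("CFP", "CD206", "F4/80"),
                                   probs)}
            for cls, probs in [("fibroblast", (1.0, 0.0, 0.0)),
                               ("macrophage", (0.0, 1.0, 1.0)),
                               ("other", (0.0, 0.0, 0.0))]}
        spec = synth.SuspensionSpec(
            n_cells=500, marker_models=models,
            dq_intensity=(180.0, 0.0, 5.0, 0.0), seed=2)
        df = synth.generate_suspension(spec)
        for ch in ("CFP", "CD206", "F4/80", "DQ"):
            assert set(np.round(df[ch].unique(), 9)) <= {5.0, 180.0, 200.0}

    def test_class_counts_within_binomial_interval(self):
        """Realized counts stay inside the 99% binomial band across seeds."""
        spec = synth.SuspensionSpec(n_cells=2000)
        p = spec.class_fractions["macrophage"]
        lo, hi = stats.binom.ppf([0.005, 0.995], spec.n_cells, p)
        inside = 0
        for s in range(100):
            df = synth.generate_suspension(
                dataclasses.replace(spec, seed=s))
            k = int((df["true_class"] == "macrophage").sum())
            inside += lo <= k <= hi
        assert inside >= 95       # ~99% coverage, allow MC slack

    def test_invalid_fractions_rejected(self):
        spec = synth.SuspensionSpec(
            class_fractions={"fibroblast": 0.5, "macrophage": 0.4,
                             "other": 0.2})
        with pytest.raises(ValueError, match="sum to 1"):
            synth.generate_suspension(spec)


class TestCtMatrix:
    def test_noise_free_duplicates_recover_offsets(self):
        spec = synth.QpcrSpec(
            gene_panel={"GeneA": {("macrophage", "limb", "P56"): 2.5}},
            noise_sd=0.0, duplicate_jitter_sd=0.0, n_samples_per_group=2)
        ct_raw, meta, truth = synth.generate_ct_matrix(spec)
        cols = meta.loc[(meta.population == "macrophage") &
                        (meta.tissue == "limb") & (meta.age == "P56"),
                        "column"]
        hk_mean = np.mean([spec.housekeeping_levels[g]
                           for g in spec.housekeeping_genes])
        dct = hk_mean - ct_raw.loc["GeneA", cols]
        # hk levels average to ct_baseline, so dCT equals the offset
        np.testing.assert_allclose(dct, 2.5)

    def test_study_design_is_forty_samples_in_duplicate(self):
        ct_raw, meta, _ = synth.generate_ct_matrix(synth.preset("qpcr-study"))
        assert ct_raw.shape[1] == 80
        assert meta["sample_id"].nunique() == 40

    def test_housekeeping_gene_with_offset_rejected(self):
        spec = synth.QpcrSpec(gene_panel={
            "Abl1": {("macrophage", "limb", "P56"): 1.0}})
        with pytest.raises(ValueError, match="housekeeping"):
            synth.generate_ct_matrix(spec)

    def test_detection_limit_emits_missing(self):
        spec = synth.QpcrSpec(
            gene_panel={"Rare": {}}, ct_baseline=45.0, noise_sd=0.0,
            duplicate_jitter_sd=0.0, n_samples_per_group=2)
        ct_raw, _, _ = synth.generate_ct_matrix(spec)
        assert ct_raw.loc["Rare"].isna().all()


class TestPresets:
    @pytest.mark.parametrize("name,field,value", [
        ("P4-patellar", "macrophage_fraction", 0.016),
        ("P56-patellar", "macrophage_fraction", 0.079),
        ("P4-achilles", "macrophage_fraction", 0.014),
        ("P56-achilles", "macrophage_fraction", 0.048),
        ("ish-uniform", "coloc_kappa", 0.0),
    ])
    def test_preset_fields(self, name, field, value):
        assert getattr(synth.preset(name), field) == value

    def test_p1_edu_fraction_ratio(self):
        spec = synth.preset("P1-edu")
        assert spec.edu_fraction_macrophage / spec.edu_fraction_fibroblast \
            == pytest.approx(2.5)

    def test_explant_dq_macrophage_probability(self):
        assert synth.preset("explant-dq").dq_positive_prob["macrophage"] \
            == 0.754

    def test_paper_derived_fields_carry_provenance_notes(self):
        assert "macrophage_fraction" in synth.preset("P56-patellar").notes

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError, match="unknown preset"):
            synth.preset("P99-tail")

    def test_preset_abundance_monotone_with_age(self):
        names = ["P4-patellar", "P14-patellar", "P28-patellar",
                 "P56-patellar"]
        fracs = [synth.preset(n).macrophage_fraction for n in names]
        assert fracs == sorted(fracs)
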