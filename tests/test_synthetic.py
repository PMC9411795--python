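"""Synthetic-data generator: determinism, generative formulas, ground truth."""

import numpy as np
import pandas as pd
import pytest

from fishmet import synthetic, untargeted
from fishmet.quantitation import CalibrationPoint, fit_calibration, quantify
from fishmet.synthetic import (GeneratorConfig, generate_biodistribution_samples,
                               generate_calibration_series, generate_desi_grid,
                               generate_feature_tables, generate_qc_replicates,
                               generate_tracing_dataset)
from fishmet.tracing import RouteFractions


class TestDeterminism:
    def test_identical_config_identical_outputs(self, default_config):
        twin = GeneratorConfig(seed=default_config.seed)
        for gen in (lambda c: generate_calibration_series(c, "pooled")[0],
                    lambda c: generate_biodistribution_samples(c)[0],
                    lambda c: generate_tracing_dataset(c)[0]):
            pd.testing.assert_frame_equal(gen(default_config), gen(twin))
        g1, _ = generate_desi_grid(default_config)
        g2, _ = generate_desi_grid(twin)
        assert np.array_equal(g1.intensities, g2.intensities)
        t1, _ = generate_feature_tables(default_config)
        t2, _ = generate_feature_tables(twin)
        pd.testing.assert_frame_equal(t1["liver"], t2["liver"])

    def test_different_seed_changes_outputs(self, default_config):
        other = GeneratorConfig(seed=default_config.seed + 1)
        a, _ = generate_calibration_series(default_config, "pooled")
        b, _ = generate_calibration_series(other, "pooled")
        assert not np.allclose(a["analyte_area"], b["analyte_area"])


class TestCalibrationSeries:
    def test_five_levels_spanning_four_decades(self, default_config):
        table, _ = generate_calibration_series(default_config, "pooled")
        levels = sorted(table["nominal_concentration"].unique())
        assert len(levels) == 5
        assert levels[0] == pytest.approx(0.01)      # 10 ng/ml
        assert levels[-1] == pytest.approx(100.0)    # 100 µg/ml
        assert np.allclose(np.diff(np.log10(levels)), 1.0)  # 1:10 series

    def test_zero_noise_replicates_identical(self, noiseless_config):
        table, _ = generate_calibration_series(noiseless_config, "serum")
        spread = table.groupby("nominal_concentration")["analyte_area"].std()
        assert (spread == 0).all()

    def test_suppression_halves_areas_but_not_ratios(self):
        base = GeneratorConfig(seed=4, noise_cv=0.0,
                               suppression_factors={o: 1.0 for o in
                                                    synthetic.DEFAULT_ORGANS})
        halved = GeneratorConfig(seed=4, noise_cv=0.0,
                                 suppression_factors={o: 0.5 for o in
                                                      synthetic.DEFAULT_ORGANS})
        a, _ = generate_calibration_series(base, "liver")
        b, _ = generate_calibration_series(halved, "liver")
        assert np.allclose(b["analyte_area"], 0.5 * a["analyte_area"])
        ratio_a = a["analyte_area"] / a["istd_area"]
        ratio_b = b["analyte_area"] / b["istd_area"]
        assert np.allclose(ratio_a, ratio_b)
        assert np.allclose(ratio_a, a["nominal_concentration"])

    def test_unknown_matrix_rejected(self, default_config):
        with pytest.raises(ValueError, match="unknown matrix"):
            generate_calibration_series(default_config, "gills")


class TestBiodistribution:
    def test_row_count(self, default_config):
        table, _ = generate_biodistribution_samples(default_config)
        assert len(table) == default_config.n_fish_per_group * 9

    def test_liver_to_muscle_area_ratio_before_noise(self):
        cfg = GeneratorConfig(seed=0, noise_cv=0.0,
                              suppression_factors={o: 1.0 for o in
                                                   synthetic.DEFAULT_ORGANS})
        table, _ = generate_biodistribution_samples(cfg)
        liver = table.query("matrix_id == 'liver'")["analyte_area"].mean()
        muscle = table.query("matrix_id == 'muscle'")["analyte_area"].mean()
        assert liver / muscle == pytest.approx(4.0)

    def test_quant_pipeline_recovers_truth(self):
        """Monte-Carlo over seeds: fit+quantify bias within 3·CV/sqrt(n)."""
        errors: dict[str, list[float]] = {}
        for seed in range(5):
            cfg = GeneratorConfig(seed=seed)
            table, truth = generate_biodistribution_samples(cfg)
            cal, _ = generate_calibration_series(cfg, "pooled")
            fit = fit_calibration(
                [CalibrationPoint(r.nominal_concentration, r.analyte_area,
                                  r.istd_area) for r in cal.itertuples()],
                weighting="1/x2")
            merged = table.merge(
                truth.true_concentrations[["sample_id",
                                           "true_extract_concentration"]],
                on="sample_id")
            for organ, grp in merged.groupby("matrix_id"):
                est = np.mean([quantify(r.analyte_area / r.istd_area,
                                        fit).concentration
                               for r in grp.itertuples()])
                true = grp["true_extract_concentration"].iloc[0]
                errors.setdefault(organ, []).append((est - true) / true)
        cfg = GeneratorConfig()
        bound = 3 * cfg.noise_cv / np.sqrt(cfg.n_fish_per_group)
        for organ, errs in errors.items():
            assert abs(np.mean(errs)) < bound, organ

    def test_tissue_masses_in_range(self, default_config):
        table, _ = generate_biodistribution_samples(default_config)
        masses = table.loc[table["matrix_id"] != "serum", "tissue_mass_mg"]
        assert masses.between(2.0, 20.0).all()
        assert table.loc[table["matrix_id"] == "serum",
                         "tissue_mass_mg"].isna().all()


class TestTracingDataset:
    def test_no_tracer_no_natural_abundance_all_m0(self):
        cfg = GeneratorConfig(seed=2, tracer_enrichment=0.0,
                              natural_abundance=0.0, noise_cv=0.0,
                              route_fractions_by_group={
                                  "control": RouteFractions(),
                                  "hcq": RouteFractions()})
        table, _ = generate_tracing_dataset(cfg)
        labeled = table[table["isotopologue"] > 0]
        assert (labeled["intensity"] == 0).all()

    def test_pc_only_truth_gives_pure_m3_naa(self):
        cfg = GeneratorConfig(seed=2, natural_abundance=0.0, noise_cv=0.0,
                              route_fractions_by_group={
                                  "control": RouteFractions(asp_m3=1.0),
                                  "hcq": RouteFractions(asp_m3=1.0)})
        table, _ = generate_tracing_dataset(cfg)
        naa = table[table["metabolite"] == "naa_brain"]
        nonzero = naa[naa["intensity"] > 0]["isotopologue"].unique()
        assert list(nonzero) == [3]

    def test_raw_equals_forward_convolution_oracle(self, nat_abundance_oracle):
        cfg = GeneratorConfig(seed=6, noise_cv=0.0)
        table, truth = generate_tracing_dataset(cfg)
        for (group, metabolite), sub in table.groupby(["group", "metabolite"]):
            t = truth.true_mids.query(
                "group == @group and metabolite == @metabolite"
            ).sort_values("isotopologue")["true_fraction"].to_numpy()
            one_fish = sub[sub["fish"] == 1].sort_values("isotopologue")
            raw = one_fish["intensity"].to_numpy()
            expected = nat_abundance_oracle(t, t.size - 1, cfg.natural_abundance)
            assert np.allclose(raw / raw.sum(), expected / expected.sum(),
                               atol=1e-12)

    def test_invalid_route_fractions_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(route_fractions_by_group={
                "control": {"acetyl_labeled": 0.1, "asp_m1": 0.6,
                            "asp_m2": 0.6, "asp_m3": 0.0},
                "hcq": {"acetyl_labeled": 0.1, "asp_m1": 0.0,
                        "asp_m2": 0.0, "asp_m3": 0.0}})


class TestDesiGrid:
    def test_swim_bladder_void_has_zero_tic(self, default_config):
        grid, truth = generate_desi_grid(default_config)
        void = truth.organ_masks["swim_bladder"]
        assert void.any()
        assert np.all(grid.tic[void] == 0.0)

    def test_uniform_biodistribution_gives_equal_roi_means(self):
        cfg = GeneratorConfig(seed=8, noise_cv=0.0,
                              biodistribution={o: 1.0 for o in
                                               synthetic.DEFAULT_ORGANS})
        grid, truth = generate_desi_grid(cfg)
        from fishmet.imaging import extract_ion_image, roi_statistics
        img = extract_ion_image(grid, synthetic.DESI_CHANNELS["hcq"])
        masks = {o: m for o, m in truth.organ_masks.items()
                 if o != "swim_bladder"}
        stats = roi_statistics(img, masks)
        assert stats["mean"].max() == pytest.approx(stats["mean"].min())

    def test_liver_ranks_first_when_highest(self):
        from fishmet.imaging import extract_ion_image, roi_statistics
        for seed in range(5):
            cfg = GeneratorConfig(seed=seed)
            grid, truth = generate_desi_grid(cfg)
            img = extract_ion_image(grid, synthetic.DESI_CHANNELS["hcq"])
            masks = {o: m for o, m in truth.organ_masks.items()
                     if o != "swim_bladder"}
            stats = roi_statistics(img, masks)
            assert set(stats.head(2)["organ"]) == {"liver", "intestine"}

    def test_out_of_bounds_organ_rejected(self, default_config):
        cfg = GeneratorConfig(seed=0)
        cfg.organ_layout = dict(cfg.organ_layout)
        cfg.organ_layout["liver"] = (0.95, 0.5, 0.2, 0.05)
        with pytest.raises(ValueError, match="exceeds grid bounds"):
            generate_desi_grid(cfg)

    def test_at_least_four_channels(self, default_config):
        grid, _ = generate_desi_grid(default_config)
        assert grid.mzs.size >= 4


class TestFeatureTables:
    def test_contaminants_have_unit_sample_blank_ratio(self, default_config):
        tables, truth = generate_feature_tables(default_config)
        ctrl, trt, blank = synthetic.feature_sample_columns(default_config)
        liver = tables["liver"].set_index("id")
        contam = liver.loc[sorted(truth.contaminant_features["liver"])]
        ratio = (contam[ctrl + trt].mean(axis=1)
                 / contam[blank].mean(axis=1))
        assert ratio.mean() == pytest.approx(1.0, abs=0.25)

    def test_satellite_mass_shifts_match_table(self, default_config):
        tables, truth = generate_feature_tables(default_config)
        all_feats = pd.concat(tables.values()).set_index("id")
        assert truth.degeneracy_map          # satellites were generated
        for sat_id, parent_id in truth.degeneracy_map.items():
            shift_name = sat_id.rsplit(":", 1)[1]
            delta = all_feats.loc[sat_id, "mz"] - all_feats.loc[parent_id, "mz"]
            assert delta == pytest.approx(
                synthetic.SATELLITE_SHIFTS[shift_name], abs=1e-4)

    def test_ground_truth_closure(self, default_config):
        tables, truth = generate_feature_tables(default_config)
        for organ, table in tables.items():
            ids = set(table["id"])
            assert truth.perturbed_features[organ] <= ids
            assert truth.contaminant_features[organ] <= ids
        sat_ids = set(truth.degeneracy_map)
        all_ids = set(pd.concat(tables.values())["id"])
        assert sat_ids <= all_ids

    def test_untargeted_pipeline_recovers_perturbed_features(self, default_config):
        """>=90% of configured 2x effects recovered at defaults (fixed seed)."""
        tables, truth = generate_feature_tables(default_config)
        ctrl, trt, blank = synthetic.feature_sample_columns(default_config)
        organ = "intestine"
        retained, _ = untargeted.blank_filter(tables[organ], ctrl + trt, blank)
        reps, _ = untargeted.collapse_degeneracies(retained, ctrl + trt)
        results = untargeted.differential_analysis(reps, ctrl, trt, organ=organ)
        hits = set(results.loc[results["significant_raw"], "id"])
        true_set = truth.perturbed_features[organ]
        recovered = len(hits & true_set) / len(true_set)
        assert recovered >= 0.9


class TestQcPanel:
    def test_shape_and_determinism(self, default_config):
        a = generate_qc_replicates(default_config)
        b = generate_qc_replicates(GeneratorConfig(seed=default_config.seed))
        assert a.shape == (20, 10)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_noise_gives_constant_rows(self, noiseless_config):
        panel = generate_qc_replicates(noiseless_config)
        assert (panel.std(axis=1) < 1e-12).all()


class TestConfigRoundTrip:
    def test_yaml_round_trip_preserves_config(self, tmp_path, default_config):
        path = tmp_path / "config.yaml"
        default_config.to_yaml(path)
        loaded = GeneratorConfig.from_yaml(path)
        assert loaded == default_config

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(noise_cv=-0.1)
        with pytest.raises(ValueError):
            GeneratorConfig(tracer_enrichment=1.5)
        with pytest.raises(ValueError):
            GeneratorConfig(suppression_factors={o: 0.0 for o in
                                                 synthetic.DEFAULT_ORGANS})
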