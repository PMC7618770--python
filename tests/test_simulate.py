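"""Synthetic-data generator: ground-truth fidelity, determinism, statistical structure."""

import dataclasses

import numpy as np
import pytest

from evuptake import simulate
from evuptake.simulate import (
    ConfigError,
    ExperimentDesign,
    SectionConfig,
    SimulationConfig,
    Treatment,
)


class TestMyocyteField:
    def test_empty_noiseless_field_is_flat_background(self):
        cfg = SimulationConfig(
            n_live_cells=0,
            n_dead_cells=0,
            autofluorescence_level=0.0,
            read_noise_sd=0.0,
            shot_noise_scale=0.0,
        )
        field, truth = simulate.simulate_myocyte_field(cfg)
        assert np.all(field.channel_405 == cfg.background_level)
        assert truth.particles == [] and not truth.cell_labels.any()

    def test_noiseless_488_pixels_equal_cell_mean(self, noiseless_config, noiseless_field):
        # zero texture amplitude and zero noise: every within-cell 488 pixel is
        # background + the cell's true NeonGreen2 level
        field, truth = noiseless_field
        for p in truth.particles:
            vals = field.channel_488[truth.cell_labels == p.label]
            assert np.allclose(vals, noiseless_config.background_level + p.neon_mean)

    def test_truth_lists_requested_particle_counts(self):
        cfg = SimulationConfig(n_live_cells=5, n_dead_cells=2, seed=42)
        _, truth = simulate.simulate_myocyte_field(cfg)
        kinds = [p.kind for p in truth.particles]
        assert len(truth.particles) + truth.placement_failures == 7
        assert truth.placement_failures == 0
        assert kinds.count("live") == 5 and kinds.count("dead") == 2
        # label grid agrees with the particle list
        labels = set(np.unique(truth.cell_labels)) - {0}
        assert labels == {p.label for p in truth.particles}

    def test_label_grids_are_exclusive_and_nuclei_lie_in_cells(self, noiseless_field):
        _, truth = noiseless_field
        nuc = truth.nucleus_labels > 0
        assert np.all(truth.cell_labels[nuc] > 0)
        for p in truth.particles:
            for nl in p.nucleus_labels:
                nmask = truth.nucleus_labels == nl
                assert np.all(truth.cell_labels[nmask] == p.label)

    def test_border_cells_are_flagged(self):
        cfg = SimulationConfig(n_border_cells=1, read_noise_sd=0.0, shot_noise_scale=0.0)
        _, truth = simulate.simulate_myocyte_field(cfg)
        flags = [p.touches_border for p in truth.particles]
        assert sum(flags) == 1

    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(seed=9)
        f1, t1 = simulate.simulate_myocyte_field(cfg)
        f2, t2 = simulate.simulate_myocyte_field(cfg)
        assert np.array_equal(f1.channel_405, f2.channel_405)
        assert np.array_equal(f1.channel_488, f2.channel_488)
        assert np.array_equal(t1.cell_labels, t2.cell_labels)

    def test_cell_longer_than_field_is_invalid(self):
        cfg = SimulationConfig(field_shape=(128, 128), live_length=(90.0, 130.0))
        with pytest.raises(ConfigError):
            simulate.simulate_myocyte_field(cfg)


class TestExperiment:
    def test_zero_variance_design_shares_group_mean(self):
        design = ExperimentDesign(
            treatments=[Treatment("a", 10.0), Treatment("b", 30.0)],
            hearts_per_group=2,
            cells_per_heart=5,
            heart_sd=0.0,
            cell_sd=0.0,
        )
        df = simulate.simulate_cell_values(design)
        assert set(df[df.treatment == "a"].value) == {10.0}
        assert set(df[df.treatment == "b"].value) == {30.0}

    def test_same_seed_gives_identical_datasets(self):
        design = ExperimentDesign(treatments=[Treatment("a", 10.0)], seed=5)
        df1 = simulate.simulate_cell_values(design)
        df2 = simulate.simulate_cell_values(design)
        assert df1.equals(df2)

    def test_between_heart_variance_dominates_when_heart_sd_large(self):
        design = ExperimentDesign(
            treatments=[Treatment("a", 20.0)],
            hearts_per_group=20,
            cells_per_heart=50,
            heart_sd=10.0,
            cell_sd=1.0,
            seed=3,
        )
        df = simulate.simulate_cell_values(design)
        heart_means = df.groupby("heart_id").value.mean()
        within = df.groupby("heart_id").value.var().mean()
        assert heart_means.var() > within

    def test_heart_intercept_sd_matches_design_at_large_n(self):
        design = ExperimentDesign(
            treatments=[Treatment("a", 0.0)],
            hearts_per_group=400,
            cells_per_heart=200,
            heart_sd=4.0,
            cell_sd=1.0,
            seed=11,
        )
        df = simulate.simulate_cell_values(design)
        heart_means = df.groupby("heart_id").value.mean()
        # heart-mean variance = heart_sd^2 + cell_sd^2/n_cells
        expected = np.sqrt(4.0**2 + 1.0**2 / 200)
        assert abs(heart_means.std() - expected) / expected < 0.10

    def test_image_experiment_is_keyed_and_deterministic(self):
        design = ExperimentDesign(
            treatments=[Treatment("sham", 5.0), Treatment("ev", 40.0)],
            hearts_per_group=2,
            cells_per_heart=4,
            seed=1,
        )
        cfg = SimulationConfig(field_shape=(384, 384), n_live_cells=2, n_dead_cells=0)
        out = simulate.simulate_experiment(design, cfg)
        assert {k[0] for k in out} == {"sham", "ev"}
        assert all(len(t.particles) <= 2 for _, t in out.values())
        out2 = simulate.simulate_experiment(design, cfg)
        key = next(iter(out))
        assert np.array_equal(out[key][0].channel_488, out2[key][0].channel_488)


class TestSection:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            simulate.simulate_section(SectionConfig(fractions=(0.5, 0.5, 0.5)))

    def test_compartment_pixel_counts_match_fractions(self):
        cfg = SectionConfig(seed=2)
        _, truth = simulate.simulate_section(cfg)
        total = truth.compartment_labels.size
        for comp, frac in enumerate(cfg.fractions):
            observed = truth.mask(comp).sum() / total
            assert abs(observed - frac) <= 0.02

    def test_truth_compartment_means_ordered_as_configured(self):
        # nuclear mean configured highest -> nuclear > cytoplasmic > extracellular
        cfg = SectionConfig(red_means=(10.0, 25.0, 45.0), seed=0)
        img, truth = simulate.simulate_section(cfg)
        means = [img.red[truth.mask(c)].mean() for c in range(3)]
        assert means[2] > means[1] > means[0]

    def test_equal_means_no_noise_gives_constant_red(self):
        cfg = SectionConfig(red_means=(20.0, 20.0, 20.0), red_sd=0.0, noise_sd=0.0)
        img, _ = simulate.simulate_section(cfg)
        assert np.all(img.red == 20.0)


class TestFRAPTrace:
    def test_immobile_trace_is_flat_after_bleach(self):
        tr = simulate.simulate_frap_trace(8.0, 0.0, bleach_depth=0.5, noise_sd=0.0)
        _, post = tr.post
        assert np.allclose(post, post[0])

    def test_recovered_fraction_at_one_tau(self):
        tau = 8.0
        tr = simulate.simulate_frap_trace(tau, 0.7, bleach_depth=0.5, noise_sd=0.0)
        t, y = tr.post
        i = int(np.argmin(np.abs(t - tau)))
        span = 0.7 * (100.0 - 50.0)
        frac = (y[i] - 50.0) / span
        assert abs(frac - (1 - np.exp(-1))) < 1e-9

    def test_bleach_depth_sets_post_bleach_floor(self):
        tr = simulate.simulate_frap_trace(8.0, 0.4, bleach_depth=0.5, noise_sd=0.0)
        assert tr.intensity[tr.bleach_index] == pytest.approx(50.0)
        assert np.allclose(tr.intensity[: tr.bleach_index], 100.0)

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            simulate.simulate_frap_trace(8.0, 0.4, times=np.array([-1.0, 0.0, 0.0, 1.0, 2.0, 3.0]))


class TestBiodistribution:
    def test_unit_folds_no_noise_identical_across_groups(self):
        tab = simulate.simulate_biodistribution({"g": {"heart": 1.0}}, noise_cv=0.0)
        norm = tab.luminescence / (tab.dose * tab.tissue_mass)
        assert np.allclose(norm, norm.iloc[0], rtol=1e-12)

    def test_geometric_mean_near_requested_fold_with_noise(self):
        tab = simulate.simulate_biodistribution(
            {"g": {"heart": 9.0}}, n_per_group=6, noise_cv=0.2, seed=4
        )
        norm = tab.assign(n=tab.luminescence / (tab.dose * tab.tissue_mass))
        gm = norm.groupby("group").n.apply(lambda x: np.exp(np.log(x).mean()))
        assert abs(gm["g"] / gm["control"] - 9.0) / 9.0 < 0.15

    def test_invalid_folds_rejected(self):
        with pytest.raises(ConfigError):
            simulate.simulate_biodistribution({"g": {"heart": -1.0}})


def test_substreams_stable_when_fields_added():
    # adding cells (hence fields) to a heart must not perturb earlier streams
    a = simulate.child_rng(7, 3, 0, 0, 0).standard_normal(4)
    b = simulate.child_rng(7, 3, 0, 0, 0).standard_normal(4)
    c = simulate.child_rng(7, 3, 0, 0, 1).standard_normal(4)
    assert np.array_equal(a, b) and not np.array_equal(a, c)


def test_invalid_ranges_raise():
    with pytest.raises(ConfigError):
        SimulationConfig(live_length=(0.0, 10.0)).validate()
    cfg = dataclasses.replace(SimulationConfig(), live_width=(30.0, 95.0))
    with pytest.raises(ConfigError):
        cfg.validate()
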