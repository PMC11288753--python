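"""Segmentation and feature-extraction contracts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import fretleaf as fl
from fretleaf.evaluation import match_to_truth, small_scene_config


class TestSegmentNuclei:
    def test_one_label_per_truth_nucleus(self, analytic_bundle):
        truth = analytic_bundle["truth"]
        labels = analytic_bundle["labels"]
        recs = analytic_bundle["records"]
        assert labels.max() == len(truth)
        m = match_to_truth(recs, truth)
        assert (m["match_dist_um"] < 3.0).all()
        # one-to-one: every truth nucleus claimed exactly once
        tree_hits = m.groupby("true_class").size().sum()
        assert tree_hits == len(truth)

    def test_all_zero_channel_gives_no_labels(self):
        stack = fl.ImageStack(
            np.zeros((8, 16, 16), np.float32),
            np.zeros((8, 16, 16), np.float32),
            np.zeros((8, 16, 16), np.float32),
            voxel_size_zyx=(1.0, 1.0, 1.0),
        )
        labels = fl.segment_nuclei(stack)
        assert labels.max() == 0

    def test_fixed_threshold_above_max_warns_zero_labels(self, analytic_bundle, caplog):
        import logging

        params = fl.SegmentationParams(threshold_method="fixed",
                                       fixed_threshold=1e9)
        with caplog.at_level(logging.WARNING, logger="fretleaf.segmentation"):
            labels = fl.segment_nuclei(analytic_bundle["stack"], params)
        assert labels.max() == 0
        assert any("threshold" in r.message for r in caplog.records)

    def test_min_volume_filter_drops_small_nuclei(self, analytic_bundle):
        truth = analytic_bundle["truth"]
        stack = analytic_bundle["stack"]
        n_stomata = (truth["cell_type"] == "stomata").sum()
        n_vascular = (truth["cell_type"] == "vascular_bundle").sum()
        # raise the floor above the small-nucleus classes' volumes
        vols = (4 / 3 * np.pi * truth["semi_a_um"] * truth["semi_b_um"]
                * truth["semi_c_um"])
        floor = float(vols[truth["cell_type"].isin(
            ["stomata", "vascular_bundle"])].max()) * 1.2
        params = fl.SegmentationParams(min_volume_um3=floor)
        labels = fl.segment_nuclei(stack, params)
        assert labels.max() == len(truth) - n_stomata - n_vascular

    def test_labels_consecutive(self, noisy_bundle):
        labels = noisy_bundle["labels"]
        present = np.unique(labels)
        assert present[0] == 0
        np.testing.assert_array_equal(present[1:],
                                      np.arange(1, labels.max() + 1))

    def test_otsu_invariant_to_intensity_rescaling(self, analytic_bundle):
        stack = analytic_bundle["stack"]
        scaled = fl.ImageStack(stack.dxdm, stack.dxam, stack.axam * 3.0,
                               voxel_size_zyx=stack.voxel_size_zyx)
        assert (fl.segment_nuclei(scaled).max()
                == fl.segment_nuclei(stack).max())


class TestExtractFeatures:
    # sigma 0 isolates the moment estimator from the smoothing halo, which
    # otherwise dilates thin axes by ~10% (a known, documented mask effect)
    def test_ellipsoid_semi_axes_recovery(self, make_single_nucleus):
        cfg, truth = make_single_nucleus(semi_axes=(6.0, 3.0, 2.0))
        stack = fl.render_stack(truth, cfg)
        labels = fl.segment_nuclei(stack, fl.SegmentationParams(gaussian_sigma_um=0.0))
        feats = fl.extract_features(labels, stack)
        assert len(feats) == 1
        row = feats.iloc[0]
        assert row.semi_a_um == pytest.approx(6.0, rel=0.10)
        assert row.semi_b_um == pytest.approx(3.0, rel=0.10)
        assert row.semi_c_um == pytest.approx(2.0, rel=0.10)
        assert row.elongation == pytest.approx(2.0, rel=0.10)

    def test_rotated_ellipsoid_recovery(self, make_single_nucleus):
        cfg, truth = make_single_nucleus(semi_axes=(6.0, 3.0, 2.0),
                                         theta=np.pi / 5)
        stack = fl.render_stack(truth, cfg)
        feats = fl.extract_features(fl.segment_nuclei(stack), stack)
        assert feats.iloc[0].semi_a_um == pytest.approx(6.0, rel=0.10)

    def test_sphere_is_isotropic(self, make_single_nucleus):
        cfg, truth = make_single_nucleus(semi_axes=(4.0, 4.0, 4.0))
        stack = fl.render_stack(truth, cfg)
        feats = fl.extract_features(fl.segment_nuclei(stack), stack)
        assert feats.iloc[0].elongation == pytest.approx(1.0, abs=0.12)
        assert feats.iloc[0].flatness == pytest.approx(1.0, abs=0.12)

    def test_neighbor_density_definition(self):
        # two spheres 5 um apart, r_nb 10 -> each sees one neighbour
        labels = np.zeros((10, 40, 40), np.int32)
        labels[4:6, 10:14, 10:14] = 1
        labels[4:6, 10:14, 20:24] = 2  # 5 um away at 0.5 um xy voxels
        stack = fl.ImageStack(
            np.ones(labels.shape, np.float32),
            np.ones(labels.shape, np.float32),
            np.ones(labels.shape, np.float32),
            voxel_size_zyx=(1.0, 0.5, 0.5),
        )
        feats = fl.extract_features(labels, stack, r_nb=10.0)
        assert (feats["neighbor_density"] == 1).all()

    def test_degenerate_single_voxel_flagged(self):
        labels = np.zeros((6, 6, 6), np.int32)
        labels[2, 2, 2] = 1
        labels[4, 1:5, 1:5] = 2  # companion object to keep the map non-trivial
        stack = fl.ImageStack(*(np.ones((6, 6, 6), np.float32),) * 3,
                              voxel_size_zyx=(1.0, 1.0, 1.0))
        feats = fl.extract_features(labels, stack)
        row = feats.set_index("nucleus_id").loc[1]
        assert "degenerate_shape" in row.qc_flags
        assert row.semi_a_um == pytest.approx(0.5)

    def test_depth_measured_from_shallowest(self, analytic_bundle):
        feats = analytic_bundle["records"]
        assert feats["depth_um"].min() == 0.0
        assert (feats["depth_um"] >= 0).all()

    def test_deterministic(self, analytic_bundle):
        stack = analytic_bundle["stack"]
        labels = analytic_bundle["labels"]
        f1 = fl.extract_features(labels, stack)
        f2 = fl.extract_features(labels, stack)
        pd.testing.assert_frame_equal(f1, f2)

    def test_intensity_means_on_raw_channels(self, make_single_nucleus):
        cfg, truth = make_single_nucleus(ratio=2.0, total=300.0)
        stack = fl.render_stack(truth, cfg)
        feats = fl.extract_features(fl.segment_nuclei(stack), stack)
        # zero background: mask dilution affects both bands equally,
        # but the means themselves come from the unsmoothed voxels
        assert feats.iloc[0].mean_dxam / feats.iloc[0].mean_dxdm == pytest.approx(2.0, rel=1e-6)


class TestEstimateBackground:
    def test_constant_background_exact(self, make_single_nucleus):
        cfg, truth = make_single_nucleus()
        cfg = dataclasses.replace(cfg, background_level=(5.0, 7.0, 9.0))
        stack = fl.render_stack(truth, cfg)
        labels = fl.segment_nuclei(stack)
        bg = fl.estimate_background(stack, labels)
        assert (bg["DxDm"], bg["DxAm"], bg["AxAm"]) == (5.0, 7.0, 9.0)

    def test_zero_background(self, analytic_bundle):
        bg = fl.estimate_background(analytic_bundle["stack"],
                                    analytic_bundle["labels"])
        assert bg == {"DxDm": 0.0, "DxAm": 0.0, "AxAm": 0.0}

    def test_gaussian_noise_median_close(self, make_single_nucleus):
        cfg, truth = make_single_nucleus()
        cfg = dataclasses.replace(
            cfg, background_level=(10.0, 10.0, 10.0),
            noise=fl.NoiseModel.gaussian(2.0))
        stack = fl.render_stack(truth, cfg)
        labels = fl.segment_nuclei(stack)
        bg = fl.estimate_background(stack, labels)
        for v in bg.values():
            assert v == pytest.approx(10.0, abs=0.1)

    def test_fully_labeled_stack_rejected(self):
        labels = np.ones((4, 4, 4), np.int32)
        stack = fl.ImageStack(*(np.ones((4, 4, 4), np.float32),) * 3,
                              voxel_size_zyx=(1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="unlabeled"):
            fl.estimate_background(stack, labels)
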