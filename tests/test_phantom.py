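"""Generator contracts: counts, dropout, rendering algebra, determinism, I/O."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import fretleaf as fl
from fretleaf.evaluation import small_scene_config
from fretleaf.phantom import STAIN_COLORS


class TestLeafScene:
    def test_counts_match_configuration(self):
        cfg = small_scene_config("control", seed=3)
        truth = fl.generate_leaf_scene(cfg)
        counts = truth["cell_type"].value_counts().to_dict()
        expected = {k: v.count for k, v in cfg.classes.items()}
        assert counts == expected
        assert truth["nucleus_id"].is_unique

    def test_default_counts_forty_nuclei(self):
        truth = fl.generate_leaf_scene(fl.default_scene_config("control", seed=0))
        assert len(truth) == 40
        assert (truth["cell_type"] == "stomata").sum() == 10

    def test_dropout_disabled_counts_condition_invariant(self):
        for seed in range(5):
            c = fl.generate_leaf_scene(
                small_scene_config("control", seed=seed, mesophyll_dropout=0.0))
            i = fl.generate_leaf_scene(
                small_scene_config("infested", seed=seed, mesophyll_dropout=0.0))
            assert (c["cell_type"].value_counts().to_dict()
                    == i["cell_type"].value_counts().to_dict())

    def test_dropout_only_touches_mesophyll(self):
        for seed in range(10):
            t = fl.generate_leaf_scene(
                small_scene_config("infested", seed=seed, mesophyll_dropout=0.5))
            counts = t["cell_type"].value_counts()
            for cls in ("stomata", "pavement", "bundle_sheath", "vascular_bundle"):
                assert counts.get(cls, 0) == small_scene_config().classes[cls].count

    def test_dropout_binomial_mean(self):
        # 10 mesophyll nuclei, dropout 0.4 -> expected retained 6.0
        totals = []
        for seed in range(400):
            cfg = fl.default_scene_config("infested", seed=seed,
                                          shape_zyx=(40, 256, 256),
                                          mesophyll_dropout=0.4)
            t = fl.generate_leaf_scene(cfg)
            totals.append((t["cell_type"] == "spongy_mesophyll").sum())
        assert abs(np.mean(totals) - 6.0) < 0.3

    def test_deterministic_given_seed(self):
        cfg = small_scene_config("infested", seed=5)
        t1 = fl.generate_leaf_scene(cfg)
        t2 = fl.generate_leaf_scene(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        s1 = fl.render_stack(t1, cfg)
        s2 = fl.render_stack(t2, cfg)
        for c1, c2 in zip(s1.channels.values(), s2.channels.values()):
            np.testing.assert_array_equal(c1, c2)

    def test_delta_strictly_increases_class_mean_ratio(self):
        cfg_lo = small_scene_config("infested", seed=4)
        hi_classes = {
            k: dataclasses.replace(
                v, infested_delta_ratio=v.infested_delta_ratio + 0.2)
            for k, v in cfg_lo.classes.items()
        }
        cfg_hi = dataclasses.replace(cfg_lo, classes=hi_classes)
        lo = fl.generate_leaf_scene(cfg_lo)
        hi = fl.generate_leaf_scene(cfg_hi)
        for cls in fl.CELL_TYPES:
            m_lo = lo.loc[lo.cell_type == cls, "true_ratio"].mean()
            m_hi = hi.loc[hi.cell_type == cls, "true_ratio"].mean()
            assert m_hi > m_lo

    def test_separation_constraint_holds(self):
        t = fl.generate_leaf_scene(small_scene_config(seed=9))
        pts = t[["z_um", "y_um", "x_um"]].to_numpy()
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 8.0

    def test_placement_failure_names_class(self):
        prior = fl.ClassPrior(
            count=200, semi_axes_um=(9.0, 7.0, 2.8), semi_axes_sd_um=0.1,
            depth_range_um=(0.0, 15.0), baseline_ratio=0.6,
            infested_delta_ratio=0.0,
        )
        cfg = fl.SceneConfig(
            shape_zyx=(20, 96, 96), voxel_size_zyx=(1.0, 0.5, 0.5),
            classes={"pavement": prior}, max_attempts=30,
        )
        with pytest.raises(fl.PlacementError, match="pavement"):
            fl.generate_leaf_scene(cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            small_scene_config(mesophyll_dropout=1.5).validate()
        bad = dataclasses.replace(
            small_scene_config(),
            classes={"stomata": fl.ClassPrior(
                count=1, semi_axes_um=(2.5, 2.4, 2.2), semi_axes_sd_um=0.1,
                depth_range_um=(0.0, 200.0),  # outside the 80 um stack
                baseline_ratio=0.6, infested_delta_ratio=0.0)},
        )
        with pytest.raises(ValueError, match="depth range"):
            bad.validate()


class TestRendering:
    def test_ratio_algebra_and_conservation(self, make_single_nucleus):
        cfg, truth = make_single_nucleus(ratio=2.0, total=300.0)
        stack = fl.render_stack(truth, cfg)
        inside = stack.axam > 0
        assert inside.any()
        np.testing.assert_allclose(stack.dxdm[inside], 100.0, rtol=1e-6)
        np.testing.assert_allclose(stack.dxam[inside], 200.0, rtol=1e-6)
        np.testing.assert_allclose(
            stack.dxdm[inside] + stack.dxam[inside], 300.0, rtol=1e-6)

    def test_unit_ratio_symmetry(self, make_single_nucleus):
        cfg, truth = make_single_nucleus(ratio=1.0)
        stack = fl.render_stack(truth, cfg)
        np.testing.assert_array_equal(stack.dxdm, stack.dxam)

    def test_background_outside_nuclei(self, make_single_nucleus):
        cfg, truth = make_single_nucleus()
        cfg = dataclasses.replace(cfg, background_level=(5.0, 7.0, 9.0))
        stack = fl.render_stack(truth, cfg)
        outside = stack.axam == 9.0
        assert outside.mean() > 0.95
        assert (stack.dxdm[outside] == 5.0).all()
        assert (stack.dxam[outside] == 7.0).all()

    def test_overlapping_nuclei_rejected(self, make_single_nucleus):
        cfg, truth = make_single_nucleus()
        twin = truth.copy()
        twin["nucleus_id"] = 2
        twin["x_um"] += 1.0  # well inside the first ellipsoid
        both = pd.concat([truth, twin], ignore_index=True)
        with pytest.raises(fl.RenderOverlapError):
            fl.render_stack(both, cfg)

    def test_quantized_matches_16bit_write(self, make_single_nucleus):
        cfg, truth = make_single_nucleus(ratio=0.7, total=250.0)
        stack = fl.render_stack(truth, cfg)
        q = stack.quantized()
        assert float(q.dxdm.max()) == np.rint(250.0 / 1.7)
        assert (q.dxdm == np.rint(stack.dxdm)).all()

    def test_tiff_roundtrip(self, tmp_path, make_single_nucleus):
        cfg, truth = make_single_nucleus()
        stack = fl.render_stack(truth, cfg)
        path = tmp_path / "stack.tif"
        stack.to_tiff(path)
        back = fl.ImageStack.from_tiff(path)
        assert back.voxel_size_zyx == pytest.approx(cfg.voxel_size_zyx)
        q = stack.quantized()
        np.testing.assert_array_equal(back.dxdm, q.dxdm)
        np.testing.assert_array_equal(back.dxam, q.dxam)
        np.testing.assert_array_equal(back.axam, q.axam)


class TestImpression:
    def test_truth_density_and_count(self):
        img, truth = fl.generate_impression_image(30, seed=1)
        assert len(truth) == 30
        area_mm2 = img.shape[0] * img.shape[1] * 0.7**2 / 1e6
        assert truth.shape[0] / area_mm2 == pytest.approx(30 / area_mm2)
        np.testing.assert_allclose(truth["width_um"] / truth["length_um"],
                                   truth["aperture_ratio"])

    def test_unit_aperture_ratio_gives_circles(self):
        _, truth = fl.generate_impression_image(
            10, aperture_ratio_range=(1.0, 1.0), seed=2)
        assert (truth["aperture_ratio"] == 1.0).all()
        assert (truth["width_um"] == truth["length_um"]).all()

    def test_byte_identical_regeneration(self):
        a, _ = fl.generate_impression_image(20, seed=3)
        b, _ = fl.generate_impression_image(20, seed=3)
        assert a.tobytes() == b.tobytes()


class TestStainedDisk:
    def test_zero_fraction_zero_pixels(self):
        _, truth = fl.generate_stained_disk(stained_fraction=0.0, seed=0)
        assert truth["stained_px"] == 0

    def test_exact_fraction(self):
        img, truth = fl.generate_stained_disk(
            disk_radius_px=200, stained_fraction=0.25, seed=1)
        target = 0.25 * np.pi * 200**2
        assert abs(truth["stained_px"] - target) / target < 0.01
        assert truth["stained_mask"].sum() == truth["stained_px"]

    def test_same_geometry_different_colors(self):
        a_img, a = fl.generate_stained_disk(stained_fraction=0.2, seed=4,
                                            stain="trypan_blue")
        b_img, b = fl.generate_stained_disk(stained_fraction=0.2, seed=4,
                                            stain="dab")
        np.testing.assert_array_equal(a["stained_mask"], b["stained_mask"])
        ca = a_img[a["stained_mask"]][0]
        cb = b_img[b["stained_mask"]][0]
        assert tuple(ca) == STAIN_COLORS["trypan_blue"]["stain"]
        assert tuple(cb) == STAIN_COLORS["dab"]["stain"]

    def test_overfull_fraction_rejected(self):
        with pytest.raises(ValueError, match="packing"):
            fl.generate_stained_disk(stained_fraction=0.95)
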