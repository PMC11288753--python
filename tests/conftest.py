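import dataclasses

import pytest
from hypothesis import settings

import fretleaf as fl
from fretleaf.evaluation import small_scene_config

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def analytic_bundle():
    """Noise-free, zero-background small scene processed end to end
    (through 16-bit quantization), shared across precision tests."""
    cfg = small_scene_config("infested", seed=11, analytic=True)
    truth = fl.generate_leaf_scene(cfg)
    stack = fl.render_stack(truth, cfg).quantized()
    labels = fl.segment_nuclei(stack)
    feats = fl.extract_features(labels, stack)
    bg = fl.estimate_background(stack, labels)
    recs = fl.add_emission_ratios(feats, bg)
    recs, counts = fl.classify_all(recs)
    return {
        "config": cfg,
        "truth": truth,
        "stack": stack,
        "labels": labels,
        "records": recs,
        "background": bg,
        "counts": counts,
    }


@pytest.fixture(scope="session")
def noisy_bundle():
    """Default-noise small scene (Poisson + read noise, nonzero background)."""
    cfg = small_scene_config("control", seed=7)
    truth = fl.generate_leaf_scene(cfg)
    stack = fl.render_stack(truth, cfg)
    labels = fl.segment_nuclei(stack)
    feats = fl.extract_features(labels, stack)
    bg = fl.estimate_background(stack, labels)
    recs = fl.add_emission_ratios(feats, bg)
    recs, counts = fl.classify_all(recs)
    return {
        "config": cfg,
        "truth": truth,
        "stack": stack,
        "labels": labels,
        "records": recs,
        "background": bg,
        "counts": counts,
    }


def single_nucleus_config(semi_axes=(6.0, 3.0, 2.0), theta=0.0, ratio=2.0,
                          total=300.0, acceptor=500.0, depth_range=(10.0, 70.0),
                          voxel=(1.0, 0.5, 0.5), shape=(80, 128, 128)):
    """A one-nucleus scene with fully pinned geometry, for moment tests."""
    import pandas as pd

    prior = fl.ClassPrior(
        count=1, semi_axes_um=semi_axes, semi_axes_sd_um=0.0,
        depth_range_um=depth_range, baseline_ratio=ratio,
        infested_delta_ratio=0.0,
    )
    cfg = fl.SceneConfig(
        shape_zyx=shape, voxel_size_zyx=voxel,
        classes={"spongy_mesophyll": prior},
        noise=fl.NoiseModel.none(), background_level=(0.0, 0.0, 0.0),
        ratio_jitter_sd=0.0, donor_total_mean=total, donor_total_sd=0.0,
        acceptor_mean=acceptor, acceptor_sd=0.0,
    )
    ez, ey, ex = cfg.extent_um
    truth = pd.DataFrame([{
        "nucleus_id": 1, "cell_type": "spongy_mesophyll",
        "x_um": ex / 2, "y_um": ey / 2, "z_um": (depth_range[0] + depth_range[1]) / 2,
        "semi_a_um": semi_axes[0], "semi_b_um": semi_axes[1],
        "semi_c_um": semi_axes[2], "theta_rad": theta,
        "true_ratio": ratio, "donor_total": total, "acceptor_signal": acceptor,
    }])
    return cfg, truth


@pytest.fixture()
def make_single_nucleus():
    return single_nucleus_config
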