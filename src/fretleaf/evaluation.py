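"""Phantom-suite evaluation studies.

Reusable measurement routines over the synthetic phantom suite: analytic
ratio recovery, Poisson-noise ratio bias, segmentation precision/recall,
classification accuracy, recovery of the configured infestation pattern,
null calibration of the statistical layer, and morphometric/stain accuracy.
Both the test suite and the reproduction script call these, so the numbers
they report come from one implementation.

Problem sizes: the segmentation/typing suite uses the full default stack
(512×512×40 voxels); noise-bias and pattern-recovery studies use smaller
fields (192- or 256-pixel) with proportionally fewer nuclei, which keeps a
complete evaluation within minutes on one CPU without changing any of the
modelled effect sizes, noise levels or replicate counts.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .celltype import ClassifierConfig, classify_all, confusion_matrix
from .morphometrics import detect_stomata, stomatal_density
from .phantom import (
    CELL_TYPES,
    SceneConfig,
    analytic_scene_config,
    default_scene_config,
    generate_impression_image,
    generate_stained_disk,
    generate_leaf_scene,
    render_stack,
)
from .pipeline import PipelineConfig, run_pipeline
from .ratiometry import RatioParams, add_emission_ratios
from .segmentation import SegmentationParams, estimate_background, extract_features, segment_nuclei
from .stain import StainParams, stained_mask

__all__ = [
    "small_scene_config",
    "zero_effect_priors",
    "process_scene",
    "match_to_truth",
    "ratio_recovery_study",
    "poisson_bias_study",
    "segmentation_typing_study",
    "infestation_pattern_study",
    "null_calibration_study",
    "aperture_recovery_study",
    "stain_recovery_study",
]

SMALL_COUNTS = {
    "stomata": 5,
    "pavement": 4,
    "spongy_mesophyll": 5,
    "bundle_sheath": 3,
    "vascular_bundle": 4,
}


def small_scene_config(
    condition: str = "control",
    seed: int = 0,
    shape_zyx: tuple[int, int, int] = (40, 192, 192),
    analytic: bool = False,
    **overrides,
) -> SceneConfig:
    """Reduced field (96×96 µm) with proportionally fewer nuclei per class."""
    factory = analytic_scene_config if analytic else default_scene_config
    base = factory(condition=condition, seed=seed, shape_zyx=shape_zyx)
    classes = {
        k: dataclasses.replace(v, count=SMALL_COUNTS[k])
        for k, v in base.classes.items()
    }
    return dataclasses.replace(base, classes=classes, **overrides)


def zero_effect_priors(classes: dict) -> dict:
    """Copy of class priors with every infestation delta set to zero."""
    return {
        k: dataclasses.replace(v, infested_delta_ratio=0.0)
        for k, v in classes.items()
    }


def process_scene(
    config: SceneConfig,
    seg: SegmentationParams | None = None,
    ratio: RatioParams | None = None,
    classifier: ClassifierConfig | None = None,
    quantize: bool = True,
):
    """Generate, render (through 16-bit quantization), segment, ratio, classify.

    Returns (truth table, classified record table).
    """
    classifier = classifier or ClassifierConfig()
    truth = generate_leaf_scene(config)
    stack = render_stack(truth, config)
    if quantize:
        stack = stack.quantized()
    labels = segment_nuclei(stack, seg)
    feats = extract_features(labels, stack, r_nb=classifier.r_nb)
    bg = estimate_background(stack, labels)
    recs = add_emission_ratios(feats, bg, ratio)
    recs, _ = classify_all(recs, classifier)
    return truth, recs


def match_to_truth(records: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Attach true_ratio / true class columns by nearest truth centroid."""
    tree = cKDTree(truth[["z_um", "y_um", "x_um"]].to_numpy())
    dist, idx = tree.query(records[["z_um", "y_um", "x_um"]].to_numpy())
    out = records.copy()
    out["match_dist_um"] = dist
    out["true_ratio"] = truth["true_ratio"].to_numpy()[idx]
    out["true_class"] = truth["cell_type"].to_numpy()[idx]
    return out


def ratio_recovery_study(seed: int = 0, shape_zyx=(40, 192, 192)) -> dict:
    """Noiseless, zero-background phantom through the 16-bit file contract:
    maximum relative per-nucleus ratio error vs generator truth."""
    cfg = small_scene_config("infested", seed=seed, shape_zyx=shape_zyx, analytic=True)
    truth, recs = process_scene(cfg, quantize=True)
    m = match_to_truth(recs, truth)
    rel = np.abs(m["emission_ratio"] - m["true_ratio"]) / m["true_ratio"]
    return {
        "max_rel_error": float(rel.max()),
        "n_nuclei": int(len(m)),
    }


def poisson_bias_study(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Per-class mean-ratio bias under Poisson noise at the default donor
    total (300 counts), pooled over seeds."""
    frames = []
    for k in range(n_seeds):
        cfg = small_scene_config("infested", seed=base_seed + k)
        truth, recs = process_scene(cfg)
        frames.append(match_to_truth(recs, truth))
    df = pd.concat(frames, ignore_index=True)
    df = df[~df["excluded"]]
    bias = (
        df.groupby("true_class", observed=True)
        .apply(
            lambda g: (g["emission_ratio"].mean() - g["true_ratio"].mean())
            / g["true_ratio"].mean(),
            include_groups=False,
        )
    )
    return {
        "per_class_bias": bias.to_dict(),
        "max_abs_bias": float(bias.abs().max()),
        "n_nuclei": int(len(df)),
        "n_seeds": n_seeds,
    }


def segmentation_typing_study(
    n_seeds: int = 20, base_seed: int = 0, shape_zyx=(40, 512, 512),
    match_radius_um: float = 4.0,
) -> dict:
    """Default separated-phantom suite: segmentation precision/recall and
    cell-typing accuracy/confusion against generator truth."""
    tp = n_pred = n_true = 0
    conf = None
    for k in range(n_seeds):
        cond = ("control", "infested")[k % 2]
        cfg = default_scene_config(cond, seed=base_seed + k, shape_zyx=shape_zyx)
        truth, recs = process_scene(cfg)
        res = confusion_matrix(recs, truth, match_radius_um=match_radius_um)
        tp += res.n_matched
        n_pred += len(recs)
        n_true += len(truth)
        conf = res.matrix if conf is None else conf + res.matrix
    acc = float(np.trace(conf.to_numpy()) / conf.to_numpy().sum())
    return {
        "precision": tp / n_pred if n_pred else float("nan"),
        "recall": tp / n_true if n_true else float("nan"),
        "typing_accuracy": acc,
        "confusion": conf,
        "n_seeds": n_seeds,
        "n_true_nuclei": n_true,
    }


def infestation_pattern_study(n_runs: int = 20, base_seed: int = 0) -> dict:
    """End-to-end recovery of the configured infestation pattern.

    Per run: (a) infested mean ratio above control in all five classes,
    (b) stomata + vascular bundle the top-2 recovered deltas, (c) spongy
    mesophyll the only class with q < 0.05 in the nucleus-count comparison.
    Returns the fraction of runs satisfying each property.
    """
    hits = {"all_classes_increase": 0, "top2_stomata_vascular": 0,
            "mesophyll_only_count_q": 0}
    for k in range(n_runs):
        cfg = PipelineConfig(seed=base_seed + k)
        rep = run_pipeline(cfg)
        if (rep.deltas["delta"] > 0).all():
            hits["all_classes_increase"] += 1
        if set(rep.top2_delta_classes) == {"stomata", "vascular_bundle"}:
            hits["top2_stomata_vascular"] += 1
        cc = rep.count_comparison.set_index("cell_type")
        sig = cc.loc[list(CELL_TYPES), "q"] < 0.05
        if sig.get("spongy_mesophyll", False) and sig.sum() == 1:
            hits["mesophyll_only_count_q"] += 1
    return {k: v / n_runs for k, v in hits.items()} | {"n_runs": n_runs}


def null_calibration_study(n_runs: int = 200, base_seed: int = 0) -> dict:
    """All infestation effects zeroed; fraction of truth-mode pipeline runs
    with any q < 0.05 across the ratio and count comparisons."""
    priors = zero_effect_priors(default_scene_config().classes)
    false_pos = 0
    for k in range(n_runs):
        cfg = PipelineConfig(
            seed=base_seed + k,
            imaging=False,
            scene_overrides={"classes": priors, "mesophyll_dropout": 0.0},
        )
        rep = run_pipeline(cfg)
        qs = np.concatenate([
            rep.ratio_comparison["q"].to_numpy(),
            rep.count_comparison["q"].to_numpy(),
        ])
        if (qs < 0.05).any():
            false_pos += 1
    return {"any_q_rate": false_pos / n_runs, "n_runs": n_runs}


def aperture_recovery_study(seed: int = 0, n_pores: int = 30) -> dict:
    """Detect pores on a synthetic impression and compare to truth."""
    pixel = 0.7
    img, truth = generate_impression_image(
        n_pores, pixel_size_um=pixel, seed=seed
    )
    records = detect_stomata(img, pixel)
    tree = cKDTree(truth[["y_um", "x_um"]].to_numpy())
    dist, idx = tree.query(records[["y_um", "x_um"]].to_numpy())
    true_ratio = truth["aperture_ratio"].to_numpy()[idx]
    rel = np.abs(records["aperture_ratio"].to_numpy() - true_ratio) / true_ratio
    major_px = truth["length_um"].to_numpy()[idx] / pixel
    area_mm2 = img.shape[0] * img.shape[1] * pixel**2 / 1e6
    density = stomatal_density(records, area_mm2)
    return {
        "n_true": len(truth),
        "n_detected": len(records),
        "max_rel_error": float(rel.max()),
        "max_rel_error_ge30px": float(rel[major_px >= 30].max())
        if (major_px >= 30).any() else float("nan"),
        "density_per_mm2": density["density_per_mm2"],
        "true_density_per_mm2": len(truth) / area_mm2,
        "max_match_dist_um": float(dist.max()) if len(records) else float("nan"),
    }


def stain_recovery_study(
    fractions=(0.05, 0.1, 0.25, 0.5), n_seeds: int = 10, stain: str = "trypan_blue"
) -> dict:
    """Recovered stained fraction vs exact generator truth."""
    errs = []
    for frac in fractions:
        for seed in range(n_seeds):
            img, truth = generate_stained_disk(
                disk_radius_px=150, stained_fraction=frac, stain=stain, seed=seed
            )
            params = StainParams(stain=stain)
            mask = stained_mask(img, params)
            measured = mask.sum() / truth["disk_px"]
            errs.append(abs(measured - truth["stained_fraction"]))
    return {
        "max_abs_fraction_error": float(max(errs)),
        "n_images": len(errs),
    }
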