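"""End-to-end experiment runner: simulate → segment → ratio → classify → stats.

A run simulates a control and an infested batch of leaf scenes, pushes every
image through segmentation, ratiometry and cell typing, and assembles the
statistical report: per-class emission-ratio summaries and deltas, the
condition × cell-type factorial ANOVA, per-class ratio comparisons and the
per-class nucleus-count (viability) comparison, both BH-FDR corrected.

Stages are selectable: ``imaging=False`` skips rendering/segmentation and
feeds the generator's ground-truth tables directly into the statistical
layer, which is the appropriate mode for calibration studies of the
statistics themselves (hundreds of runs at negligible cost).

Everything is deterministic given ``PipelineConfig.seed``; a JSON manifest
records the configuration and derived per-image seeds so any run can be
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .celltype import ClassifierConfig, classify_all
from .phantom import CELL_TYPES, SceneConfig, default_scene_config, generate_leaf_scene, render_stack
from .ratiometry import (
    RatioParams,
    add_emission_ratios,
    ratio_increase_by_class,
    summarize_ratios,
)
from .segmentation import SegmentationParams, estimate_background, extract_features, segment_nuclei
from .stats import FactorialResult, bh_fdr, count_comparison, two_way_factorial, welch_t

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "PipelineStageError"]

CONDITIONS = ("control", "infested")


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    n_images_per_condition: int = 8
    shape_zyx: tuple[int, int, int] = (40, 256, 256)
    scene_overrides: dict = field(default_factory=dict)
    imaging: bool = True
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    ratio: RatioParams = field(default_factory=RatioParams)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    alpha: float = 0.05
    posthoc: str = "tukey"
    make_figure: bool = False

    def scene_config(self, condition: str, scene_seed: int) -> SceneConfig:
        return default_scene_config(
            condition=condition,
            seed=scene_seed,
            shape_zyx=tuple(self.shape_zyx),
            **self.scene_overrides,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shape_zyx"] = list(self.shape_zyx)
        return d


@dataclass
class PipelineReport:
    nuclei: pd.DataFrame
    class_summary: pd.DataFrame
    deltas: pd.DataFrame
    top2_delta_classes: tuple[str, str]
    ratio_comparison: pd.DataFrame
    count_comparison: pd.DataFrame
    anova: FactorialResult
    manifest: dict


def _scene_seed(base_seed: int, condition: str, index: int) -> int:
    return int((base_seed * 1009 + CONDITIONS.index(condition) * 503 + index) % (2**31))


def _records_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    out = truth.rename(columns={"true_ratio": "emission_ratio"}).copy()
    out["excluded"] = False
    return out[["nucleus_id", "cell_type", "x_um", "y_um", "z_um",
                "emission_ratio", "excluded"]]


def _image_records(cfg: PipelineConfig, condition: str, index: int) -> pd.DataFrame:
    scene_seed = _scene_seed(cfg.seed, condition, index)
    scene = cfg.scene_config(condition, scene_seed)
    stage = "simulate"
    try:
        truth = generate_leaf_scene(scene)
        if cfg.imaging:
            stage = "render"
            stack = render_stack(truth, scene)
            stage = "segment"
            labels = segment_nuclei(stack, cfg.segmentation)
            stage = "features"
            feats = extract_features(labels, stack, r_nb=cfg.classifier.r_nb)
            stage = "ratio"
            bg = estimate_background(stack, labels)
            recs = add_emission_ratios(feats, bg, cfg.ratio)
            stage = "classify"
            recs, _counts = classify_all(recs, cfg.classifier)
        else:
            recs = _records_from_truth(truth)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineStageError(
            f"stage {stage!r} failed for condition={condition} image={index} "
            f"(scene seed {scene_seed}): {exc}"
        ) from exc
    recs = recs.copy()
    recs["condition"] = condition
    recs["image_id"] = f"{condition}_{index:02d}"
    recs["scene_seed"] = scene_seed
    return recs


def _per_class_ratio_tests(nuclei: pd.DataFrame) -> pd.DataFrame:
    """Welch t per cell type (plus all cells pooled) on per-nucleus ratios, BH-FDR."""
    df = nuclei[~nuclei["excluded"]].dropna(subset=["emission_ratio"])
    rows = []
    groups = [*CELL_TYPES, "all"]
    for cls in groups:
        sub = df if cls == "all" else df[df["cell_type"] == cls]
        a = sub.loc[sub["condition"] == "infested", "emission_ratio"]
        b = sub.loc[sub["condition"] == "control", "emission_ratio"]
        if len(a) >= 2 and len(b) >= 2:
            r = welch_t(a, b, labels=("infested", "control"))
            rows.append({"cell_type": cls, "effect": r.effect,
                         "statistic": r.statistic, "p": r.p,
                         "n_infested": r.n_a, "n_control": r.n_b, "note": r.note})
        else:
            rows.append({"cell_type": cls, "effect": np.nan, "statistic": np.nan,
                         "p": 1.0, "n_infested": len(a), "n_control": len(b),
                         "note": "insufficient_n"})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def _count_table(nuclei: pd.DataFrame) -> pd.DataFrame:
    counts = (
        nuclei.groupby(["condition", "image_id", "cell_type"], observed=True)
        .size().unstack(fill_value=0)
    )
    for cls in CELL_TYPES:
        if cls not in counts.columns:
            counts[cls] = 0
    counts = counts[list(CELL_TYPES)].reset_index()
    counts["total"] = counts[list(CELL_TYPES)].sum(axis=1)
    return counts


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> PipelineReport:
    """Run the full experiment and return (and optionally write) the report."""
    records = [
        _image_records(cfg, cond, i)
        for cond in CONDITIONS
        for i in range(cfg.n_images_per_condition)
    ]
    nuclei = pd.concat(records, ignore_index=True)

    class_summary = summarize_ratios(nuclei, by="condition_cell_type")
    ctl = summarize_ratios(nuclei[nuclei["condition"] == "control"], by="cell_type")
    inf = summarize_ratios(nuclei[nuclei["condition"] == "infested"], by="cell_type")
    deltas = ratio_increase_by_class(ctl, inf)
    ranked = deltas.sort_values("delta", ascending=False, kind="stable")
    top2 = tuple(ranked["cell_type"].head(2))

    ratio_cmp = _per_class_ratio_tests(nuclei)
    counts = _count_table(nuclei)
    count_cmp = count_comparison(counts)

    kept = nuclei[~nuclei["excluded"]].dropna(subset=["emission_ratio"])
    anova = two_way_factorial(
        kept["emission_ratio"], kept["condition"], kept["cell_type"],
        alpha=cfg.alpha, posthoc=cfg.posthoc,
    )

    manifest = {
        "fretleaf_version": __version__,
        "numpy_version": np.__version__,
        "config": cfg.to_dict(),
        "scene_seeds": {
            cond: [_scene_seed(cfg.seed, cond, i)
                   for i in range(cfg.n_images_per_condition)]
            for cond in CONDITIONS
        },
        "n_nuclei": int(len(nuclei)),
    }

    report = PipelineReport(
        nuclei=nuclei,
        class_summary=class_summary,
        deltas=deltas,
        top2_delta_classes=top2,
        ratio_comparison=ratio_cmp,
        count_comparison=count_cmp,
        anova=anova,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_report(report, cfg, Path(out_dir))
    return report


def _write_report(report: PipelineReport, cfg: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report.nuclei.to_csv(out / "nuclei.csv", index=False)
    report.class_summary.to_csv(out / "class_summary.csv", index=False)
    report.deltas.to_csv(out / "ratio_deltas.csv", index=False)
    report.ratio_comparison.to_csv(out / "ratio_comparison.csv", index=False)
    report.count_comparison.to_csv(out / "count_comparison.csv", index=False)
    report.anova.anova.to_csv(out / "anova.csv")
    if report.anova.posthoc is not None:
        report.anova.posthoc.to_csv(out / "anova_posthoc.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True)
    if cfg.make_figure:
        _summary_figure(report, out / "class_summary.png")


def _summary_figure(report: PipelineReport, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    summary = report.class_summary
    x = np.arange(len(CELL_TYPES))
    width = 0.38
    for off, (cond, color) in zip(
        (-width / 2, width / 2), [("control", "#4477aa"), ("infested", "#cc6677")]
    ):
        sub = summary[summary["condition"] == cond].set_index("cell_type")
        sub = sub.reindex(list(CELL_TYPES))
        ax.bar(x + off, sub["mean_ratio"], width, yerr=sub["sem_ratio"],
               label=cond, color=color, capsize=3)
    ax.set_xticks(x)
    ax.set_xticklabels([c.replace("_", "\n") for c in CELL_TYPES], fontsize=8)
    ax.set_ylabel("emission ratio (DxAm/DxDm)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
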