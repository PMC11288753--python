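"""Shape/position-based classification of nuclei into five leaf cell types.

A deterministic rule cascade over the extracted per-nucleus features:

1. shallow nuclei (depth ≤ ``epidermis_max_depth``) are epidermal — small
   ones are stomatal guard-cell nuclei, large ones pavement nuclei, with a
   configured tie-break for the intermediate band;
2. deep nuclei that sit in a spatial cluster (``neighbor_density``) are
   vascular-bundle nuclei (vein nuclei are strung along the vein axis);
3. remaining elongated nuclei at intermediate/deep depth are bundle-sheath;
4. everything else is spongy mesophyll.

Depth is measured from the shallowest segmented nucleus, not the first
z-slice, so a mounting offset does not shift the rules. All thresholds are
configurable; the defaults sit midway between the *measured* feature
distributions of adjacent classes on default phantoms (segmentation erodes
objects, so measured diameters and elongations run below the generative
shape priors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import CELL_TYPES

__all__ = [
    "ClassifierConfig",
    "classify_nucleus",
    "classify_all",
    "confusion_matrix",
    "ConfusionResult",
]

logger = logging.getLogger(__name__)

_REQUIRED_FEATURES = (
    "depth_um",
    "equiv_diam_um",
    "elongation",
    "neighbor_density",
)


@dataclass(frozen=True)
class ClassifierConfig:
    epidermis_max_depth: float = 12.0  # µm below shallowest nucleus
    vascular_min_depth: float = 45.0
    stomata_max_equiv_diam: float = 7.0
    pavement_min_equiv_diam: float = 9.0
    bundle_sheath_min_elongation: float = 1.6
    vascular_min_neighbor_density: int = 2
    r_nb: float = 20.0
    # Pavement precedes stomata: thresholding erodes large flat nuclei into
    # the intermediate diameter band far more often than it inflates compact
    # guard-cell nuclei, so the ambiguous band belongs to pavement.
    tie_break_order: tuple[str, ...] = (
        "pavement", "stomata", "spongy_mesophyll", "bundle_sheath",
        "vascular_bundle",
    )

    def validate(self) -> None:
        for name in (
            "epidermis_max_depth", "vascular_min_depth", "stomata_max_equiv_diam",
            "pavement_min_equiv_diam", "bundle_sheath_min_elongation", "r_nb",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epidermis_max_depth >= self.vascular_min_depth:
            raise ValueError("epidermis_max_depth must be < vascular_min_depth")
        if set(self.tie_break_order) - set(CELL_TYPES):
            raise ValueError("tie_break_order contains unknown classes")


def classify_nucleus(features, config: ClassifierConfig | None = None) -> str:
    """Assign one of the five cell types to a feature row (Series/dict/namedtuple).

    The cascade is exhaustive and exclusive: every feature vector maps to
    exactly one class. Raises ``ValueError`` naming any missing feature.
    """
    config = config or ClassifierConfig()
    config.validate()
    get = (features.get if hasattr(features, "get")
           else lambda k, d=None: getattr(features, k, d))
    vals = {}
    for name in _REQUIRED_FEATURES:
        v = get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"missing feature {name!r} for classification")
        vals[name] = v

    if vals["depth_um"] <= config.epidermis_max_depth:
        if vals["equiv_diam_um"] < config.stomata_max_equiv_diam:
            return "stomata"
        if vals["equiv_diam_um"] >= config.pavement_min_equiv_diam:
            return "pavement"
        for cls in config.tie_break_order:
            if cls in ("stomata", "pavement"):
                return cls
    if (
        vals["depth_um"] >= config.vascular_min_depth
        and vals["neighbor_density"] >= config.vascular_min_neighbor_density
    ):
        return "vascular_bundle"
    if vals["elongation"] >= config.bundle_sheath_min_elongation:
        return "bundle_sheath"
    return "spongy_mesophyll"


def classify_all(
    records: pd.DataFrame, config: ClassifierConfig | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Label every nucleus; returns (records with ``cell_type``, per-class counts).

    Per-class counts cover all five classes (zeros included) and sum to the
    number of records. Raises on an empty record list.
    """
    if len(records) == 0:
        raise ValueError("cannot classify an empty record list")
    config = config or ClassifierConfig()
    out = records.copy()
    out["cell_type"] = [
        classify_nucleus(row, config) for row in out.to_dict("records")
    ]
    counts = (
        out["cell_type"].value_counts().reindex(list(CELL_TYPES), fill_value=0)
    )
    counts.name = "n"
    return out, counts


@dataclass
class ConfusionResult:
    matrix: pd.DataFrame  # rows = truth, columns = predicted
    accuracy: float
    n_matched: int
    n_unmatched_predicted: int
    n_unmatched_truth: int


def confusion_matrix(
    predicted: pd.DataFrame,
    truth: pd.DataFrame,
    match_radius_um: float = 5.0,
) -> ConfusionResult:
    """Score predictions against generator truth by nearest-centroid matching.

    Pairs within ``match_radius_um`` are assigned greedily nearest-first;
    collisions (a nucleus already taken by a closer pair) are logged and the
    conflicting pair skipped. Unmatched nuclei on either side are reported
    separately and excluded from the accuracy.
    """
    pred_pts = predicted[["z_um", "y_um", "x_um"]].to_numpy(float)
    true_pts = truth[["z_um", "y_um", "x_um"]].to_numpy(float)
    if len(pred_pts) and len(true_pts):
        d = np.linalg.norm(pred_pts[:, None, :] - true_pts[None, :, :], axis=-1)
        pairs = np.argwhere(d <= match_radius_um)
        order = np.argsort(d[pairs[:, 0], pairs[:, 1]], kind="stable")
        used_p: set[int] = set()
        used_t: set[int] = set()
        matches: list[tuple[int, int]] = []
        collisions = 0
        for pi, ti in pairs[order]:
            if pi in used_p or ti in used_t:
                collisions += 1
                continue
            used_p.add(int(pi))
            used_t.add(int(ti))
            matches.append((int(pi), int(ti)))
        if collisions:
            logger.warning(
                "%d candidate matches discarded by greedy nearest-first resolution",
                collisions,
            )
    else:
        matches, used_p, used_t = [], set(), set()

    classes = list(CELL_TYPES)
    mat = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for pi, ti in matches:
        t_cls = truth.iloc[ti]["cell_type"]
        p_cls = predicted.iloc[pi]["cell_type"]
        mat.loc[t_cls, p_cls] += 1
    total = int(mat.to_numpy().sum())
    acc = float(np.trace(mat.to_numpy()) / total) if total else float("nan")
    return ConfusionResult(
        matrix=mat,
        accuracy=acc,
        n_matched=total,
        n_unmatched_predicted=len(pred_pts) - len(matches),
        n_unmatched_truth=len(true_pts) - len(matches),
    )
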