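"""Per-nucleus biosensor emission ratios and group summaries.

The emission ratio is the acceptor-band over donor-band intensity under
donor excitation, DxAm/DxDm, computed on background-corrected per-nucleus
mean intensities (not voxelwise ratios, which amplify noise). Band
assignment follows the band physics — DxAm is the 525–560 nm acceptor
emission band, DxDm the 460–500 nm donor band; ``invert_ratio`` is provided
for datasets whose channel convention is the other way around.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import CELL_TYPES

__all__ = [
    "RatioParams",
    "compute_emission_ratio",
    "add_emission_ratios",
    "summarize_ratios",
    "ratio_increase_by_class",
]


@dataclass(frozen=True)
class RatioParams:
    """``background_mode`` "global_median" subtracts the supplied per-channel
    background; "none" ignores it. Nuclei whose corrected donor mean falls
    below ``denominator_floor`` counts are excluded (flag
    ``low_donor_signal``) rather than producing unstable ratios."""

    background_mode: str = "global_median"
    denominator_floor: float = 5.0
    invert_ratio: bool = False

    def validate(self) -> None:
        if self.background_mode not in ("none", "global_median"):
            raise ValueError(f"unknown background_mode {self.background_mode!r}")
        if self.denominator_floor <= 0:
            raise ValueError("denominator_floor must be > 0")


def compute_emission_ratio(
    mean_dxam: float,
    mean_dxdm: float,
    background: tuple[float, float] = (0.0, 0.0),
    params: RatioParams | None = None,
) -> tuple[float | None, list[str]]:
    """Ratio of background-corrected means; returns (ratio, qc flags).

    ``background`` is (bg_dxdm, bg_dxam). A corrected denominator below the
    floor yields ``(None, ["low_donor_signal"])``; a negative corrected
    numerator is clamped to ratio 0 with a ``negative_numerator`` flag —
    ratios are never negative.
    """
    params = params or RatioParams()
    params.validate()
    if params.background_mode == "global_median":
        bg_d, bg_a = background
    else:
        bg_d = bg_a = 0.0
    num = mean_dxam - bg_a
    den = mean_dxdm - bg_d
    if params.invert_ratio:
        num, den = den, num
    flags: list[str] = []
    if den < params.denominator_floor:
        return None, ["low_donor_signal"]
    if num < 0:
        return 0.0, ["negative_numerator"]
    return num / den, flags


def add_emission_ratios(
    records: pd.DataFrame,
    background: dict[str, float] | None = None,
    params: RatioParams | None = None,
) -> pd.DataFrame:
    """Attach ``emission_ratio`` and ``excluded`` columns to a feature table.

    ``background`` is the dict from ``estimate_background`` (keys DxDm/DxAm);
    required when ``background_mode="global_median"``, ignored otherwise.
    """
    params = params or RatioParams()
    params.validate()
    if params.background_mode == "global_median":
        if background is None:
            raise ValueError("global_median background_mode requires a background")
        bg = (background["DxDm"], background["DxAm"])
    else:
        bg = (0.0, 0.0)
    out = records.copy()
    ratios = np.full(len(out), np.nan)
    excluded = np.zeros(len(out), dtype=bool)
    flags = []
    for i, row in enumerate(out.itertuples(index=False)):
        r, fl = compute_emission_ratio(row.mean_dxam, row.mean_dxdm, bg, params)
        prior = getattr(row, "qc_flags", "") or ""
        if r is None:
            excluded[i] = True
        else:
            ratios[i] = r
        flags.append(";".join(x for x in [prior, *fl] if x))
    out["emission_ratio"] = ratios
    out["excluded"] = excluded
    out["qc_flags"] = flags
    return out


_GROUP_KEYS = {
    "image": ["image_id"],
    "cell_type": ["cell_type"],
    "condition_cell_type": ["condition", "cell_type"],
}


def summarize_ratios(records: pd.DataFrame, by: str = "cell_type") -> pd.DataFrame:
    """Per-group n / mean / sd / sem of the emission ratio.

    ``by`` is one of "image", "cell_type", "condition_cell_type". Excluded
    records are dropped first. When grouping involves cell types, classes
    with no retained nuclei appear as rows with n = 0 and an
    ``empty_group`` flag rather than being silently dropped.
    """
    if by not in _GROUP_KEYS:
        raise ValueError(f"unknown grouping {by!r}")
    keys = _GROUP_KEYS[by]
    df = records
    if "excluded" in df.columns:
        df = df[~df["excluded"]]
    df = df.dropna(subset=["emission_ratio"])

    grouped = df.groupby(keys, observed=True)["emission_ratio"]
    summary = grouped.agg(n="count", mean_ratio="mean", sd_ratio="std").reset_index()
    summary["sem_ratio"] = summary["sd_ratio"] / np.sqrt(summary["n"])

    if "cell_type" in keys:
        if by == "condition_cell_type":
            conditions = sorted(records["condition"].unique()) if len(records) else []
            full = pd.MultiIndex.from_product(
                [conditions, list(CELL_TYPES)], names=keys
            ).to_frame(index=False)
        else:
            full = pd.DataFrame({"cell_type": list(CELL_TYPES)})
        summary = full.merge(summary, on=keys, how="left")
        summary["n"] = summary["n"].fillna(0).astype(int)
    summary["qc"] = np.where(summary["n"] == 0, "empty_group", "")
    return summary.sort_values(keys, kind="stable").reset_index(drop=True)


def ratio_increase_by_class(
    control_summary: pd.DataFrame, infested_summary: pd.DataFrame
) -> pd.DataFrame:
    """Per-class infested-minus-control mean-ratio delta with propagated SE.

    Both summaries must be per-cell-type tables covering the same class set
    (a class present in only one raises, naming it). The SE is the
    independent-groups propagation sqrt(sem_c² + sem_i²).
    """
    c = control_summary.set_index("cell_type")
    i = infested_summary.set_index("cell_type")
    only_c = set(c.index) - set(i.index)
    only_i = set(i.index) - set(c.index)
    if only_c or only_i:
        missing = sorted(only_c | only_i)
        raise ValueError(f"class set mismatch between summaries: {missing}")
    out = pd.DataFrame({
        "cell_type": c.index,
        "mean_control": c["mean_ratio"].to_numpy(),
        "mean_infested": i.loc[c.index, "mean_ratio"].to_numpy(),
    })
    out["delta"] = out["mean_infested"] - out["mean_control"]
    se_c = c["sem_ratio"].to_numpy()
    se_i = i.loc[c.index, "sem_ratio"].to_numpy()
    out["se_delta"] = np.sqrt(se_c**2 + se_i**2)
    return out.reset_index(drop=True)
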