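"""3D nucleus segmentation and per-nucleus feature extraction.

The sensor-abundance channel (AxAm) is smoothed, globally thresholded and
connected-component labeled; components outside the configured volume bounds
are removed and labels compacted to 1..N. Features (centroid, second-moment
ellipsoid semi-axes, neighbour density, per-channel mean intensity) are
measured in physical µm on the *raw* channels — smoothing only influences the
mask, never the intensities entering the emission ratio.

Anisotropic voxels are handled by physical-unit conversion at feature time
(no resampling). The second-moment covariance gets the standard per-axis
``h²/12`` voxel-binning correction before the ellipsoid semi-axes
``a = sqrt(5·λ)`` are derived, which matters for nuclei only a few z-slices
thick.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .phantom import ImageStack

__all__ = [
    "SegmentationParams",
    "segment_nuclei",
    "extract_features",
    "estimate_background",
    "NUCLEUS_FEATURE_COLUMNS",
]

logger = logging.getLogger(__name__)

NUCLEUS_FEATURE_COLUMNS = (
    "nucleus_id",
    "voxel_count",
    "volume_um3",
    "x_um",
    "y_um",
    "z_um",
    "depth_um",
    "equiv_diam_um",
    "semi_a_um",
    "semi_b_um",
    "semi_c_um",
    "elongation",
    "flatness",
    "neighbor_density",
    "mean_dxdm",
    "mean_dxam",
    "mean_axam",
    "qc_flags",
)


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the threshold/label stage.

    ``threshold_method`` is "otsu" or "fixed" (with ``fixed_threshold`` in
    counts); connectivity is 6 (faces) or 26 (faces+edges+corners); volume
    bounds are in µm³.
    """

    gaussian_sigma_um: float = 1.0
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    connectivity: int = 26
    min_volume_um3: float = 15.0
    max_volume_um3: float = 4000.0

    def validate(self) -> None:
        if self.gaussian_sigma_um < 0:
            raise ValueError("gaussian_sigma_um must be >= 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold_method requires fixed_threshold")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if not 0 <= self.min_volume_um3 < self.max_volume_um3:
            raise ValueError("require 0 <= min_volume < max_volume")


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    return np.ones((3, 3, 3), dtype=bool)


def segment_nuclei(
    stack: ImageStack, params: SegmentationParams | None = None
) -> np.ndarray:
    """Segment nuclei from the AxAm channel; returns an int32 label map.

    Labels are consecutive 1..N after volume filtering, 0 is background.
    An empty or constant channel yields an all-zero map (not an error); a
    fixed threshold above the intensity maximum yields zero labels with a
    logged warning.
    """
    params = params or SegmentationParams()
    params.validate()
    dz, dy, dx = stack.voxel_size_zyx
    axam = stack.axam.astype(np.float32)
    if params.gaussian_sigma_um > 0:
        sigma_vox = (
            params.gaussian_sigma_um / dz,
            params.gaussian_sigma_um / dy,
            params.gaussian_sigma_um / dx,
        )
        smoothed = ndimage.gaussian_filter(axam, sigma=sigma_vox)
    else:
        smoothed = axam

    if params.threshold_method == "fixed":
        thr = float(params.fixed_threshold)
        if thr > smoothed.max():
            logger.warning(
                "fixed threshold %.3g above channel maximum %.3g: 0 labels",
                thr, smoothed.max(),
            )
            return np.zeros(stack.shape, dtype=np.int32)
    else:
        if smoothed.max() == smoothed.min():
            return np.zeros(stack.shape, dtype=np.int32)
        thr = threshold_otsu(smoothed)

    binary = smoothed > thr
    labels, n = ndimage.label(binary, structure=_structure(params.connectivity))
    if n == 0:
        return labels.astype(np.int32)

    voxel_vol = dz * dy * dx
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    volumes = counts * voxel_vol
    keep = (volumes >= params.min_volume_um3) & (volumes <= params.max_volume_um3)
    keep[0] = False
    mapping = np.zeros(n + 1, dtype=np.int32)
    mapping[keep] = np.arange(1, int(keep.sum()) + 1, dtype=np.int32)
    return mapping[labels]


def extract_features(
    labels: np.ndarray, stack: ImageStack, r_nb: float = 20.0
) -> pd.DataFrame:
    """One feature row per label, with geometry in physical µm.

    ``depth_um`` is measured from the shallowest nucleus centroid (robust to
    mounting offset); ``neighbor_density`` counts other nuclei centroids
    within ``r_nb`` µm. Single/few-voxel objects get voxel-sized semi-axes
    and a ``degenerate_shape`` qc flag.
    """
    dz, dy, dx = stack.voxel_size_zyx
    spacing = np.array([dz, dy, dx])
    voxel_vol = float(np.prod(spacing))
    n = int(labels.max())
    rows = []
    objects = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        if sl is None:
            continue
        sub = labels[sl] == lab
        coords = np.argwhere(sub).astype(np.float64)
        coords += [s.start for s in sl]
        coords *= spacing  # physical z, y, x of voxel centres
        count = coords.shape[0]
        centroid = coords.mean(axis=0)
        qc = []
        if count < 4:
            semi = np.sort(spacing / 2.0)[::-1]
            qc.append("degenerate_shape")
        else:
            cov = np.cov(coords, rowvar=False, bias=True)
            cov += np.diag(spacing**2 / 12.0)  # voxel-binning correction
            eigvals = np.linalg.eigvalsh(cov)[::-1]
            semi = np.sqrt(5.0 * np.clip(eigvals, 1e-12, None))
        means = {
            name: float(ch[sl][sub].mean())
            for name, ch in stack.channels.items()
        }
        volume = count * voxel_vol
        rows.append({
            "nucleus_id": lab,
            "voxel_count": count,
            "volume_um3": volume,
            "x_um": centroid[2],
            "y_um": centroid[1],
            "z_um": centroid[0],
            "equiv_diam_um": (6.0 * volume / np.pi) ** (1.0 / 3.0),
            "semi_a_um": semi[0],
            "semi_b_um": semi[1],
            "semi_c_um": semi[2],
            "elongation": semi[0] / semi[1] if semi[1] > 0 else np.inf,
            "flatness": semi[1] / semi[2] if semi[2] > 0 else np.inf,
            "mean_dxdm": means["DxDm"],
            "mean_dxam": means["DxAm"],
            "mean_axam": means["AxAm"],
            "qc_flags": ";".join(qc),
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=list(NUCLEUS_FEATURE_COLUMNS))
    df["depth_um"] = df["z_um"] - df["z_um"].min()
    pts = df[["z_um", "y_um", "x_um"]].to_numpy()
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    df["neighbor_density"] = ((d <= r_nb).sum(axis=1) - 1).astype(int)
    return df[list(NUCLEUS_FEATURE_COLUMNS)]


def estimate_background(stack: ImageStack, labels: np.ndarray) -> dict[str, float]:
    """Per-channel median intensity over unlabeled voxels.

    Requires at least 1% of voxels to be background (unlabeled).
    """
    unlabeled = labels == 0
    frac = unlabeled.mean()
    if frac < 0.01:
        raise ValueError(
            f"only {frac:.2%} of voxels are unlabeled; background estimation "
            "needs at least 1%"
        )
    return {
        name: float(np.median(ch[unlabeled]))
        for name, ch in stack.channels.items()
    }
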