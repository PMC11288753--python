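"""Synthetic leaf phantoms with full ground truth.

Three generators stand in for the raw microscopy of a leaf-infestation
experiment:

* :func:`generate_leaf_scene` / :func:`render_stack` — 3D confocal z-stacks
  of biosensor-expressing nuclei in five leaf cell types, with a layered
  depth model (epidermis shallowest, vascular bundle deepest), class-dependent
  nuclear shapes, and a ratiometric FRET rendering in three channels
  (DxDm, DxAm, AxAm).
* :func:`generate_impression_image` — 2D epidermal-impression fields of dark
  elliptical stomatal pores with known length/width.
* :func:`generate_stained_disk` — RGB leaf disks with a known stained area
  (trypan blue, DAB brown, or chlorotic yellow).

Every generator returns an exact ground-truth table alongside the image, so
the downstream segmentation, ratiometry, classification and morphometric
stages can be validated without any real data.

Rendering model
---------------
A nucleus with true emission ratio ``R`` and donor-excited total emission
``T`` is rendered voxelwise as ``DxDm = T / (1 + R)`` and
``DxAm = T * R / (1 + R)``, so that the measured band ratio ``DxAm / DxDm``
recovers ``R`` exactly in the noiseless limit and ``DxDm + DxAm = T`` is
conserved. The AxAm channel carries an independent sensor-abundance signal
``A`` and is the segmentation channel.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "CELL_TYPES",
    "NoiseModel",
    "ClassPrior",
    "SceneConfig",
    "ImageStack",
    "PlacementError",
    "RenderOverlapError",
    "default_scene_config",
    "analytic_scene_config",
    "generate_leaf_scene",
    "render_stack",
    "generate_impression_image",
    "generate_stained_disk",
    "STAIN_COLORS",
]

#: Canonical class labels, ordered superficial -> deep.
CELL_TYPES = (
    "stomata",
    "pavement",
    "spongy_mesophyll",
    "bundle_sheath",
    "vascular_bundle",
)

#: Columns of the ground-truth table (one row per rendered nucleus).
TRUTH_COLUMNS = (
    "nucleus_id",
    "cell_type",
    "x_um",
    "y_um",
    "z_um",
    "semi_a_um",
    "semi_b_um",
    "semi_c_um",
    "theta_rad",
    "true_ratio",
    "donor_total",
    "acceptor_signal",
)


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place a nucleus."""


class RenderOverlapError(RuntimeError):
    """Raised when two nuclei would overlap in the rendered stack."""


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: optional Poisson shot noise plus Gaussian read noise.

    ``poisson_scale`` rescales intensities before drawing Poisson counts
    (counts are divided back), emulating detector gain; ``read_noise_sd`` is
    additive Gaussian noise in counts. The default emulates a
    photon-counting detector with a small read-noise floor.
    """

    poisson: bool = True
    poisson_scale: float = 1.0
    read_noise_sd: float = 2.0

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(poisson=False, read_noise_sd=0.0)

    @classmethod
    def gaussian(cls, sd: float) -> "NoiseModel":
        return cls(poisson=False, read_noise_sd=float(sd))

    @classmethod
    def shot(cls, scale: float = 1.0, read_noise_sd: float = 2.0) -> "NoiseModel":
        return cls(poisson=True, poisson_scale=float(scale), read_noise_sd=float(read_noise_sd))

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.poisson:
            lam = image * self.poisson_scale if self.poisson_scale != 1.0 else image
            out = rng.poisson(lam).astype(np.float32)
            if self.poisson_scale != 1.0:
                out /= self.poisson_scale
        else:
            out = image.astype(np.float32, copy=True)
        if self.read_noise_sd > 0:
            noise = rng.standard_normal(out.shape, dtype=np.float32)
            noise *= self.read_noise_sd
            out += noise
        np.clip(out, 0.0, None, out=out)
        return out


@dataclass(frozen=True)
class ClassPrior:
    """Shape/position/ratio prior for one cell-type class.

    Semi-axes are (a, b, c) in µm: a and b lie in the leaf plane (a along the
    orientation angle), c along the optical axis. ``depth_range_um`` is the
    tissue layer the nucleus must lie inside (its centre is inset by c so the
    whole nucleus fits the layer).
    """

    count: int
    semi_axes_um: tuple[float, float, float]
    semi_axes_sd_um: float
    depth_range_um: tuple[float, float]
    baseline_ratio: float
    infested_delta_ratio: float
    vein_clustered: bool = False

    def validate(self, name: str, stack_depth_um: float) -> None:
        if self.count < 0:
            raise ValueError(f"{name}: count must be >= 0")
        if any(ax <= 0 for ax in self.semi_axes_um):
            raise ValueError(f"{name}: semi-axes must be positive")
        lo, hi = self.depth_range_um
        if not (0 <= lo < hi <= stack_depth_um):
            raise ValueError(
                f"{name}: depth range {self.depth_range_um} outside stack depth "
                f"[0, {stack_depth_um}]"
            )
        if self.baseline_ratio <= 0:
            raise ValueError(f"{name}: baseline_ratio must be > 0")
        if self.infested_delta_ratio < 0:
            raise ValueError(f"{name}: infested_delta_ratio must be >= 0")


@dataclass(frozen=True)
class SceneConfig:
    """Full specification of a synthetic leaf scene.

    Arrays and shapes use numpy (z, y, x) axis order throughout; physical
    coordinates in tables are reported as x/y/z in µm.
    """

    shape_zyx: tuple[int, int, int]
    voxel_size_zyx: tuple[float, float, float]
    classes: dict[str, ClassPrior]
    condition: str = "control"  # "control" | "infested"
    seed: int = 0
    mesophyll_dropout: float = 0.3
    min_center_separation_um: float = 8.0
    background_level: tuple[float, float, float] = (2.0, 2.0, 2.0)  # DxDm, DxAm, AxAm
    noise: NoiseModel = field(default_factory=NoiseModel)
    ratio_jitter_sd: float = 0.05
    donor_total_mean: float = 300.0
    donor_total_sd: float = 30.0
    acceptor_mean: float = 500.0
    acceptor_sd: float = 50.0
    max_attempts: int = 2000

    def validate(self) -> None:
        if self.condition not in ("control", "infested"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if not 0.0 <= self.mesophyll_dropout <= 1.0:
            raise ValueError("mesophyll_dropout must be in [0, 1]")
        if len(self.shape_zyx) != 3 or any(s <= 0 for s in self.shape_zyx):
            raise ValueError("shape_zyx must be three positive integers")
        if any(v <= 0 for v in self.voxel_size_zyx):
            raise ValueError("voxel sizes must be positive")
        depth = self.shape_zyx[0] * self.voxel_size_zyx[0]
        for name, prior in self.classes.items():
            if name not in CELL_TYPES:
                raise ValueError(f"unknown cell type {name!r}")
            prior.validate(name, depth)
        if self.donor_total_mean <= 0 or self.acceptor_mean <= 0:
            raise ValueError("signal levels must be positive")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size (z, y, x) of the stack in µm."""
        return tuple(s * v for s, v in zip(self.shape_zyx, self.voxel_size_zyx))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classes"] = {k: dataclasses.asdict(v) for k, v in self.classes.items()}
        return d


def _default_class_priors() -> dict[str, ClassPrior]:
    # Layered abaxial leaf model: epidermal classes 0-15 um, spongy mesophyll
    # 15-60, bundle sheath 35-70, vascular bundle 50-80 of an 80 um stack.
    return {
        "stomata": ClassPrior(
            count=10, semi_axes_um=(2.6, 2.4, 2.2), semi_axes_sd_um=0.25,
            depth_range_um=(0.0, 15.0), baseline_ratio=0.60,
            infested_delta_ratio=0.30,
        ),
        "pavement": ClassPrior(
            count=10, semi_axes_um=(9.0, 7.0, 2.8), semi_axes_sd_um=0.8,
            depth_range_um=(0.0, 15.0), baseline_ratio=0.60,
            infested_delta_ratio=0.12,
        ),
        "spongy_mesophyll": ClassPrior(
            count=10, semi_axes_um=(4.2, 3.4, 3.0), semi_axes_sd_um=0.45,
            depth_range_um=(15.0, 60.0), baseline_ratio=0.60,
            infested_delta_ratio=0.12,
        ),
        "bundle_sheath": ClassPrior(
            count=5, semi_axes_um=(8.0, 2.8, 2.5), semi_axes_sd_um=0.4,
            depth_range_um=(35.0, 70.0), baseline_ratio=0.60,
            infested_delta_ratio=0.15,
        ),
        "vascular_bundle": ClassPrior(
            count=5, semi_axes_um=(2.8, 2.5, 2.3), semi_axes_sd_um=0.25,
            depth_range_um=(50.0, 80.0), baseline_ratio=0.60,
            infested_delta_ratio=0.28, vein_clustered=True,
        ),
    }


def default_scene_config(
    condition: str = "control",
    seed: int = 0,
    shape_zyx: tuple[int, int, int] = (40, 512, 512),
    **overrides,
) -> SceneConfig:
    """Default study scenario: 512x512x40 stack, 0.5x0.5x2 µm voxels, 40 nuclei."""
    classes = overrides.pop("classes", None) or _default_class_priors()
    cfg = SceneConfig(
        shape_zyx=shape_zyx,
        voxel_size_zyx=(2.0, 0.5, 0.5),
        classes=classes,
        condition=condition,
        seed=seed,
        **overrides,
    )
    cfg.validate()
    return cfg


def analytic_scene_config(
    condition: str = "control",
    seed: int = 0,
    shape_zyx: tuple[int, int, int] = (40, 512, 512),
) -> SceneConfig:
    """Noise-free, zero-background, bright scenario for analytic checks.

    A bright acquisition (donor total 12000 counts) keeps 16-bit integer
    quantization below ~2e-4 relative so ratio recovery can be asserted
    analytically.
    """
    cfg = default_scene_config(
        condition=condition,
        seed=seed,
        shape_zyx=shape_zyx,
        noise=NoiseModel.none(),
        background_level=(0.0, 0.0, 0.0),
        donor_total_mean=12000.0,
        donor_total_sd=600.0,
        acceptor_mean=20000.0,
        acceptor_sd=1000.0,
    )
    return cfg


# ---------------------------------------------------------------------------
# Scene generation


def _sample_semi_axes(rng: np.random.Generator, prior: ClassPrior) -> np.ndarray:
    # truncate at +/- 2 sd with a 1.2 um floor: real nuclei are never
    # thinner than the axial resolution, and an untruncated tail would
    # occasionally produce unimageable sub-voxel ellipsoids
    mean = np.asarray(prior.semi_axes_um, dtype=float)
    sd = prior.semi_axes_sd_um
    ax = rng.normal(mean, sd)
    ax = np.clip(ax, np.maximum(mean - 2 * sd, 1.2), mean + 2 * sd)
    # keep a >= b in-plane; c stays the axial extent
    if ax[1] > ax[0]:
        ax[0], ax[1] = ax[1], ax[0]
    return ax


def _separation_ok(
    center: np.ndarray,
    max_semi: float,
    placed_centers: list[np.ndarray],
    placed_radii: list[float],
    min_sep: float,
) -> bool:
    for other, r in zip(placed_centers, placed_radii):
        need = max(min_sep, max_semi + r + 0.5)
        if np.linalg.norm(center - other) < need:
            return False
    return True


def generate_leaf_scene(config: SceneConfig) -> pd.DataFrame:
    """Place nuclei of all configured classes and return the ground-truth table.

    Placement is rejection sampling under two constraints: centres at least
    ``min_center_separation_um`` apart, and at least the sum of the two
    nuclei's largest semi-axes (+0.5 µm), which guarantees the rendered
    ellipsoids never overlap. Under ``condition="infested"`` each spongy
    mesophyll nucleus is independently dropped with probability
    ``mesophyll_dropout`` (the viability effect). Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 0])
    ez, ey, ex = config.extent_um

    placed_centers: list[np.ndarray] = []
    placed_radii: list[float] = []
    rows: list[dict] = []
    infested = config.condition == "infested"

    # place big classes first to ease packing
    order = sorted(
        config.classes.items(), key=lambda kv: -max(kv[1].semi_axes_um)
    )
    for name, prior in order:
        if prior.count == 0:
            continue
        if prior.vein_clustered:
            _place_vein_class(
                name, prior, config, rng, placed_centers, placed_radii, rows,
            )
            continue
        for _ in range(prior.count):
            placed = False
            for _attempt in range(config.max_attempts):
                axes = _sample_semi_axes(rng, prior)
                theta = rng.uniform(0.0, np.pi)
                margin = max(axes[0], axes[1]) + 0.5
                if ex - 2 * margin <= 0 or ey - 2 * margin <= 0:
                    continue
                zlo = prior.depth_range_um[0] + axes[2]
                zhi = prior.depth_range_um[1] - axes[2]
                if zhi <= zlo:
                    continue
                center = np.array([
                    rng.uniform(zlo, zhi),
                    rng.uniform(margin, ey - margin),
                    rng.uniform(margin, ex - margin),
                ])
                if _separation_ok(
                    center, float(axes.max()), placed_centers, placed_radii,
                    config.min_center_separation_um,
                ):
                    placed = True
                    break
            if not placed:
                raise PlacementError(
                    f"could not place a {name!r} nucleus after "
                    f"{config.max_attempts} attempts under the "
                    f"{config.min_center_separation_um} µm separation constraint"
                )
            placed_centers.append(center)
            placed_radii.append(float(axes.max()))
            rows.append(_truth_row(name, center, axes, theta, prior, config, rng))

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS[1:])

    if infested and config.mesophyll_dropout > 0:
        meso = truth["cell_type"] == "spongy_mesophyll"
        keep = rng.random(len(truth)) >= config.mesophyll_dropout
        truth = truth[~meso | keep].reset_index(drop=True)

    truth.insert(0, "nucleus_id", np.arange(1, len(truth) + 1))
    return truth


def _truth_row(name, center, axes, theta, prior, config, rng) -> dict:
    infested = config.condition == "infested"
    ratio = prior.baseline_ratio + (prior.infested_delta_ratio if infested else 0.0)
    if config.ratio_jitter_sd > 0:
        ratio += rng.normal(0.0, config.ratio_jitter_sd)
    ratio = max(ratio, 0.05)
    total = max(rng.normal(config.donor_total_mean, config.donor_total_sd), 10.0)
    acceptor = max(rng.normal(config.acceptor_mean, config.acceptor_sd), 10.0)
    return {
        "cell_type": name,
        "x_um": center[2],
        "y_um": center[1],
        "z_um": center[0],
        "semi_a_um": axes[0],
        "semi_b_um": axes[1],
        "semi_c_um": axes[2],
        "theta_rad": theta,
        "true_ratio": ratio,
        "donor_total": total,
        "acceptor_signal": acceptor,
    }


def _place_vein_class(name, prior, config, rng, placed_centers, placed_radii, rows):
    """Place vein-associated nuclei clustered along a random line (the vein axis)."""
    ez, ey, ex = config.extent_um
    for _attempt in range(config.max_attempts):
        axes_list = [_sample_semi_axes(rng, prior) for _ in range(prior.count)]
        theta = rng.uniform(0.0, np.pi)
        direction = np.array([0.0, np.sin(theta), np.cos(theta)])
        spacings = rng.uniform(8.5, 9.5, size=max(prior.count - 1, 0))
        ts = np.concatenate([[0.0], np.cumsum(spacings)])
        chain = ts[-1] if len(ts) else 0.0
        margin = max(max(a[0], a[1]) for a in axes_list) + 0.5
        span_y = abs(direction[1]) * chain
        span_x = abs(direction[2]) * chain
        if ey - 2 * margin - span_y <= 0 or ex - 2 * margin - span_x <= 0:
            continue
        y0 = rng.uniform(margin + max(0.0, -direction[1] * chain),
                         ey - margin - max(0.0, direction[1] * chain))
        x0 = rng.uniform(margin + max(0.0, -direction[2] * chain),
                         ex - margin - max(0.0, direction[2] * chain))
        # a vein runs at a coherent depth; nuclei scatter a little around it
        cmax = max(a[2] for a in axes_list)
        z_vein = rng.uniform(prior.depth_range_um[0] + cmax + 2.0,
                             prior.depth_range_um[1] - cmax - 2.0)
        centers = []
        ok = True
        for t, axes in zip(ts, axes_list):
            zlo = prior.depth_range_um[0] + axes[2]
            zhi = prior.depth_range_um[1] - axes[2]
            if zhi <= zlo:
                ok = False
                break
            perp = rng.normal(0.0, 1.2)
            c = np.array([
                float(np.clip(z_vein + rng.normal(0.0, 1.5), zlo, zhi)),
                y0 + direction[1] * t - direction[2] * perp,
                x0 + direction[2] * t + direction[1] * perp,
            ])
            if not (margin <= c[1] <= ey - margin and margin <= c[2] <= ex - margin):
                ok = False
                break
            if not _separation_ok(
                c, float(axes.max()), placed_centers + centers,
                placed_radii + [float(a.max()) for a in axes_list[: len(centers)]],
                config.min_center_separation_um,
            ):
                ok = False
                break
            centers.append(c)
        if ok and len(centers) == prior.count:
            for c, axes in zip(centers, axes_list):
                placed_centers.append(c)
                placed_radii.append(float(axes.max()))
                rows.append(_truth_row(name, c, axes, theta, prior, config, rng))
            return
    raise PlacementError(
        f"could not place the {name!r} vein cluster after "
        f"{config.max_attempts} attempts under the "
        f"{config.min_center_separation_um} µm separation constraint"
    )


# ---------------------------------------------------------------------------
# Stack rendering and I/O


CHANNEL_NAMES = ("DxDm", "DxAm", "AxAm")


@dataclass
class ImageStack:
    """Three-channel confocal z-stack in (z, y, x) voxel order, float counts."""

    dxdm: np.ndarray
    dxam: np.ndarray
    axam: np.ndarray
    voxel_size_zyx: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not (self.dxdm.shape == self.dxam.shape == self.axam.shape):
            raise ValueError("all three channels must share the same shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dxdm.shape

    @property
    def channels(self) -> dict[str, np.ndarray]:
        return {"DxDm": self.dxdm, "DxAm": self.dxam, "AxAm": self.axam}

    def quantized(self) -> "ImageStack":
        """Return a copy with intensities clipped to [0, 65535] and rounded,
        i.e. exactly what a 16-bit write would store."""
        q = [
            np.clip(np.rint(ch), 0, 65535).astype(np.float32)
            for ch in (self.dxdm, self.dxam, self.axam)
        ]
        return ImageStack(*q, voxel_size_zyx=self.voxel_size_zyx)

    def to_tiff(self, path) -> None:
        """Write as a 16-bit ImageJ hyperstack (ZCYX) with voxel-size metadata."""
        data = np.stack(
            [np.clip(np.rint(ch), 0, 65535).astype(np.uint16)
             for ch in (self.dxdm, self.dxam, self.axam)],
            axis=1,
        )  # (Z, C, Y, X)
        dz, dy, dx = self.voxel_size_zyx
        tifffile.imwrite(
            str(path),
            data,
            imagej=True,
            resolution=(1.0 / dx, 1.0 / dy),
            metadata={
                "spacing": dz,
                "unit": "um",
                "axes": "ZCYX",
                "Info": json.dumps({"channels": list(CHANNEL_NAMES),
                                    "voxel_size_zyx": [dz, dy, dx]}),
            },
        )

    @classmethod
    def from_tiff(cls, path, voxel_size_zyx=None) -> "ImageStack":
        """Read a 3-channel stack; voxel size from metadata unless overridden."""
        with tifffile.TiffFile(str(path)) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
            meta = tif.imagej_metadata or {}
        if voxel_size_zyx is None:
            dz = dy = dx = None
            info = meta.get("Info")
            if info:
                try:
                    dz, dy, dx = json.loads(info)["voxel_size_zyx"]
                except (KeyError, ValueError, TypeError):
                    pass
            if dz is None:
                dz = float(meta.get("spacing", 1.0))
                dy = dx = 1.0
            voxel_size_zyx = (float(dz), float(dy), float(dx))
        data = np.asarray(data)
        if axes == "ZCYX":
            chans = [data[:, i] for i in range(3)]
        elif axes == "CZYX":
            chans = [data[i] for i in range(3)]
        elif data.ndim == 4 and data.shape[1] == 3:
            chans = [data[:, i] for i in range(3)]
        elif data.ndim == 4 and data.shape[0] == 3:
            chans = [data[i] for i in range(3)]
        else:
            raise ValueError(f"cannot interpret TIFF axes {axes!r} shape {data.shape}")
        chans = [c.astype(np.float32) for c in chans]
        return cls(*chans, voxel_size_zyx=tuple(voxel_size_zyx))


def render_stack(truth: pd.DataFrame, config: SceneConfig) -> ImageStack:
    """Render the ground-truth nuclei into a three-channel stack.

    Inside each ellipsoid: ``DxDm = T/(1+R)``, ``DxAm = T*R/(1+R)``,
    ``AxAm = A``; outside, each channel sits at its background level. Noise
    is applied after signal composition per ``config.noise``. Raises
    :class:`RenderOverlapError` if two nuclei would overlap (never blends
    silently). Deterministic given ``config.seed``.
    """
    config.validate()
    shape = tuple(config.shape_zyx)
    dz, dy, dx = config.voxel_size_zyx
    bg = config.background_level
    dxdm = np.full(shape, bg[0], dtype=np.float32)
    dxam = np.full(shape, bg[1], dtype=np.float32)
    axam = np.full(shape, bg[2], dtype=np.float32)
    occupied = np.zeros(shape, dtype=bool)

    for row in truth.itertuples(index=False):
        a, b, c = row.semi_a_um, row.semi_b_um, row.semi_c_um
        cz, cy, cx = row.z_um, row.y_um, row.x_um
        theta = row.theta_rad
        rmax_xy = max(a, b)
        z0 = max(int(np.floor((cz - c) / dz)), 0)
        z1 = min(int(np.ceil((cz + c) / dz)) + 1, shape[0])
        y0 = max(int(np.floor((cy - rmax_xy) / dy)), 0)
        y1 = min(int(np.ceil((cy + rmax_xy) / dy)) + 1, shape[1])
        x0 = max(int(np.floor((cx - rmax_xy) / dx)), 0)
        x1 = min(int(np.ceil((cx + rmax_xy) / dx)) + 1, shape[2])
        zz, yy, xx = np.ogrid[z0:z1, y0:y1, x0:x1]
        pz = zz * dz - cz
        py = yy * dy - cy
        px = xx * dx - cx
        ct, st = np.cos(theta), np.sin(theta)
        u = px * ct + py * st
        v = -px * st + py * ct
        mask = (u / a) ** 2 + (v / b) ** 2 + (pz / c) ** 2 <= 1.0
        sub = (slice(z0, z1), slice(y0, y1), slice(x0, x1))
        if (occupied[sub] & mask).any():
            raise RenderOverlapError(
                f"nucleus {int(row.nucleus_id)} overlaps a previously rendered "
                "nucleus; scenes must satisfy the placement separation constraint"
            )
        occupied[sub] |= mask
        r = row.true_ratio
        t = row.donor_total
        dxdm[sub][mask] = t / (1.0 + r)
        dxam[sub][mask] = t * r / (1.0 + r)
        axam[sub][mask] = row.acceptor_signal

    rng = np.random.default_rng([int(config.seed), 1])
    dxdm = config.noise.apply(dxdm, rng)
    dxam = config.noise.apply(dxam, rng)
    axam = config.noise.apply(axam, rng)
    return ImageStack(dxdm, dxam, axam, voxel_size_zyx=(dz, dy, dx))


def write_scene(truth: pd.DataFrame, stack: ImageStack, config: SceneConfig, out_dir) -> dict:
    """Write stack TIFF, truth CSV and a YAML config echo; return the paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": out / f"scene_{config.condition}_seed{config.seed}.tif",
        "truth": out / f"truth_{config.condition}_seed{config.seed}.csv",
        "config": out / f"config_{config.condition}_seed{config.seed}.yaml",
    }
    stack.to_tiff(paths["stack"])
    truth.to_csv(paths["truth"], index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# 2D impression images (stomatal pores)


def generate_impression_image(
    n_pores: int,
    length_range_um: tuple[float, float] = (15.0, 25.0),
    aperture_ratio_range: tuple[float, float] = (0.2, 0.6),
    pixel_size_um: float = 0.7,
    image_shape: tuple[int, int] = (1024, 1024),
    seed: int = 0,
    background: int = 220,
    pore_value: int = 40,
    max_attempts: int = 5000,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render dark elliptical pores on a bright impression field.

    Pores are rendered with 4× supersampled partial-volume coverage, so
    boundary pixels take intermediate gray values as they do in real
    transmitted-light images of impressions. Returns the uint8 image and a
    truth table with per-pore centre (µm), length (major axis, µm), width
    (minor axis, µm) and width/length ratio. Pores are placed without
    overlap; byte-identical for a fixed seed.
    """
    if n_pores < 0:
        raise ValueError("n_pores must be >= 0")
    lo, hi = length_range_um
    rlo, rhi = aperture_ratio_range
    if not (0 < lo <= hi):
        raise ValueError("invalid length range")
    if not (0 < rlo <= rhi <= 1.0):
        raise ValueError("aperture ratio range must lie in (0, 1]")
    rng = np.random.default_rng([int(seed), 2])
    img = np.full(image_shape, background, dtype=np.uint8)
    rows = []
    centers: list[np.ndarray] = []
    radii: list[float] = []
    for i in range(n_pores):
        placed = False
        for _ in range(max_attempts):
            length = rng.uniform(lo, hi)
            ratio = rng.uniform(rlo, rhi)
            width = length * ratio
            theta = rng.uniform(0.0, np.pi)
            a_px = (length / 2.0) / pixel_size_um
            margin = a_px + 2
            cy = rng.uniform(margin, image_shape[0] - margin)
            cx = rng.uniform(margin, image_shape[1] - margin)
            center = np.array([cy, cx])
            if all(
                np.linalg.norm(center - c) >= a_px + r + 3
                for c, r in zip(centers, radii)
            ):
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place pore {i + 1}/{n_pores} without overlap"
            )
        _render_pore(img, cy, cx, a_px, width / 2.0 / pixel_size_um, theta,
                     background, pore_value)
        centers.append(center)
        radii.append(a_px)
        rows.append({
            "pore_id": i + 1,
            "x_um": cx * pixel_size_um,
            "y_um": cy * pixel_size_um,
            "length_um": length,
            "width_um": width,
            "aperture_ratio": ratio,
            "theta_rad": theta,
        })
    truth = pd.DataFrame(
        rows,
        columns=["pore_id", "x_um", "y_um", "length_um", "width_um",
                 "aperture_ratio", "theta_rad"],
    )
    return img, truth


def _render_pore(img, cy, cx, a_px, b_px, theta, background, pore_value, ss=4):
    """Draw one anti-aliased ellipse: pixel value interpolates with the
    supersampled coverage fraction."""
    h, w = img.shape
    r0 = max(int(np.floor(cy - a_px)) - 2, 0)
    r1 = min(int(np.ceil(cy + a_px)) + 3, h)
    c0 = max(int(np.floor(cx - a_px)) - 2, 0)
    c1 = min(int(np.ceil(cx + a_px)) + 3, w)
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    yy = (np.arange(r0, r1)[:, None] + offs[None, :]).ravel() - cy
    xx = (np.arange(c0, c1)[:, None] + offs[None, :]).ravel() - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = xx[None, :] * ct + yy[:, None] * st
    v = -xx[None, :] * st + yy[:, None] * ct
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    cov = inside.reshape(r1 - r0, ss, c1 - c0, ss).mean(axis=(1, 3))
    patch = img[r0:r1, c0:c1].astype(float)
    patch -= cov * (background - pore_value)
    img[r0:r1, c0:c1] = np.clip(np.round(patch), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Stained leaf disks


#: Per-stain (tissue, stain) RGB colours; background is near-white.
STAIN_COLORS = {
    "trypan_blue": {"tissue": (186, 205, 176), "stain": (60, 70, 165)},
    "dab": {"tissue": (215, 205, 180), "stain": (139, 86, 43)},
    "chlorosis": {"tissue": (95, 152, 70), "stain": (204, 188, 64)},
}
BACKGROUND_RGB = (245, 245, 245)


def generate_stained_disk(
    disk_radius_px: int = 200,
    stained_fraction: float = 0.25,
    stain: str = "trypan_blue",
    seed: int = 0,
    image_shape: tuple[int, int] | None = None,
    splash: bool = False,
    max_blobs: int = 20000,
) -> tuple[np.ndarray, dict]:
    """Render a leaf disk with stained blobs covering a known area fraction.

    The stained-pixel count is exact: blobs are accumulated until the target
    is reached, and the final blob is trimmed to land on the exact pixel
    count. Geometry is driven only by ``seed`` and the radius, so two stains
    generated with the same seed share an identical mask. ``splash=True``
    adds a stained-colour blob outside the disk (for testing mask
    conjunction). Returns (RGB uint8 image, truth dict with the exact mask).
    """
    from skimage.draw import disk as draw_disk

    if stain not in STAIN_COLORS:
        raise ValueError(f"unknown stain {stain!r}")
    if not 0.0 <= stained_fraction <= 1.0:
        raise ValueError("stained_fraction must be in [0, 1]")
    if stained_fraction > 0.9:
        raise ValueError(
            f"stained_fraction {stained_fraction} exceeds achievable blob packing (0.9)"
        )
    if image_shape is None:
        s = 2 * disk_radius_px + 60
        image_shape = (s, s)
    rng = np.random.default_rng([int(seed), 3])
    cy, cx = image_shape[0] / 2.0, image_shape[1] / 2.0
    disk_mask = np.zeros(image_shape, dtype=bool)
    rr, cc = draw_disk((cy, cx), disk_radius_px, shape=image_shape)
    disk_mask[rr, cc] = True
    disk_px = int(disk_mask.sum())
    target = int(round(stained_fraction * disk_px))

    stained = np.zeros(image_shape, dtype=bool)
    count = 0
    blobs = 0
    while count < target:
        if blobs >= max_blobs:
            raise RuntimeError("blob packing failed to reach the target fraction")
        blobs += 1
        br = rng.uniform(3.0, max(disk_radius_px / 6.0, 4.0))
        rho = rng.uniform(0.0, max(disk_radius_px - br, 1.0))
        ang = rng.uniform(0.0, 2 * np.pi)
        by, bx = cy + rho * np.sin(ang), cx + rho * np.cos(ang)
        rr, cc = draw_disk((by, bx), br, shape=image_shape)
        new = np.zeros(image_shape, dtype=bool)
        new[rr, cc] = True
        new &= disk_mask & ~stained
        n_new = int(new.sum())
        if n_new == 0:
            continue
        if count + n_new > target:
            # trim deterministic raster-order excess to hit the exact count
            excess = count + n_new - target
            idx = np.flatnonzero(new.ravel())
            new.ravel()[idx[-excess:]] = False
            n_new -= excess
        stained |= new
        count += n_new

    colors = STAIN_COLORS[stain]
    img = np.empty((*image_shape, 3), dtype=np.uint8)
    img[:] = BACKGROUND_RGB
    img[disk_mask] = colors["tissue"]
    img[stained] = colors["stain"]

    splash_mask = np.zeros(image_shape, dtype=bool)
    if splash:
        rr, cc = draw_disk((10, 10), 8, shape=image_shape)
        splash_mask[rr, cc] = True
        splash_mask &= ~disk_mask
        img[splash_mask] = colors["stain"]

    truth = {
        "stained_mask": stained,
        "disk_mask": disk_mask,
        "stained_px": count,
        "disk_px": disk_px,
        "stained_fraction": count / disk_px if disk_px else 0.0,
        "splash_mask": splash_mask,
    }
    return img, truth


def scene_config_from_yaml(path) -> SceneConfig:
    """Load a SceneConfig from a YAML file written by :func:`write_scene`
    (or hand-authored with the same keys)."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    classes = {
        k: ClassPrior(
            count=int(v["count"]),
            semi_axes_um=tuple(v["semi_axes_um"]),
            semi_axes_sd_um=float(v["semi_axes_sd_um"]),
            depth_range_um=tuple(v["depth_range_um"]),
            baseline_ratio=float(v["baseline_ratio"]),
            infested_delta_ratio=float(v["infested_delta_ratio"]),
            vein_clustered=bool(v.get("vein_clustered", False)),
        )
        for k, v in d["classes"].items()
    }
    noise = d.get("noise", {})
    cfg = SceneConfig(
        shape_zyx=tuple(d["shape_zyx"]),
        voxel_size_zyx=tuple(d["voxel_size_zyx"]),
        classes=classes,
        condition=d.get("condition", "control"),
        seed=int(d.get("seed", 0)),
        mesophyll_dropout=float(d.get("mesophyll_dropout", 0.3)),
        min_center_separation_um=float(d.get("min_center_separation_um", 8.0)),
        background_level=tuple(d.get("background_level", (2.0, 2.0, 2.0))),
        noise=NoiseModel(**noise) if isinstance(noise, dict) and noise else NoiseModel(),
        ratio_jitter_sd=float(d.get("ratio_jitter_sd", 0.05)),
        donor_total_mean=float(d.get("donor_total_mean", 300.0)),
        donor_total_sd=float(d.get("donor_total_sd", 30.0)),
        acceptor_mean=float(d.get("acceptor_mean", 500.0)),
        acceptor_sd=float(d.get("acceptor_sd", 50.0)),
    )
    cfg.validate()
    return cfg
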