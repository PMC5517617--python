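"""Synthetic two-channel pancreas volumes, stained-section images and clearing series.

No imaging data were deposited for the volumetric islet analyses this package
reimplements, so every downstream stage is validated against volumes drawn
here with known ground truth: bright solid spheroids (islets) in an endocrine
channel, partial spherical shells of nerve signal around each islet in a
neural-crest channel (emulating the peri-islet Schwann-cell sheath), Gaussian
background noise, and per-channel intensity scales. The generator records
exactly what it drew (:class:`GroundTruth`), which serves as the oracle for
detection, radius and innervation recovery.

Spheres are defined in physical μm space, so they stay round under
anisotropic voxel spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .volume_preprocess import ChannelVolume

__all__ = [
    "GroundTruth",
    "SynthConfig",
    "generate_islet_volume",
    "generate_stain_image",
    "generate_clearing_series",
]

_PLACEMENT_BUDGET = 10_000  # rejection-sampling attempts per islet before erroring


@dataclass
class GroundTruth:
    """What the generator actually drew: the oracle for the analysis pipeline."""

    islet_centers: list[tuple[float, float, float]]  # μm
    islet_radii: list[float]  # μm
    innervation_fractions: list[float]  # fraction of each shell carrying nerve signal
    sample_id: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.islet_centers)
        if len(self.islet_radii) != n or len(self.innervation_fractions) != n:
            raise ValueError("ground-truth field lengths must be equal")
        if any(r <= 0 for r in self.islet_radii):
            raise ValueError("all radii must be > 0")

    def __len__(self) -> int:
        return len(self.islet_radii)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["islet_centers"] = [tuple(c) for c in d["islet_centers"]]
        return cls(**d)


@dataclass
class SynthConfig:
    """Parameters of the synthetic pancreas volume.

    Defaults follow the imaging geometry the pipeline assumes: 5 μm voxels
    in-plane and in z, lognormal islet radii (median 40 μm, shape 0.5, the
    tens-to-~150 μm range of developing islets), a 10 μm innervation shell,
    and Gaussian background noise with sd 2% of the channel maximum —
    enough to be nonzero but not to destabilize Otsu thresholding.
    """

    volume_shape: tuple[int, int, int] = (200, 200, 60)  # voxels (x, y, z)
    voxel_size: tuple[float, float, float] = (5.0, 5.0, 5.0)  # μm
    n_islets: int = 30
    radius_distribution: dict = field(
        default_factory=lambda: {"name": "lognormal", "median": 40.0, "sigma": 0.5}
    )
    radius_bounds: tuple[float, float] = (10.0, 150.0)  # μm, draws clipped by rejection
    min_center_separation: float = 50.0  # μm, floor on center-to-center distance
    # optional extra clearance between projected xy outlines (μm); spheres far
    # apart in z can still overlap in a slab MIP, so MIP-based benchmarks that
    # assume isolated islets should set this > 0
    xy_clearance: float | None = None
    shell_thickness: float = 10.0  # μm, nerve shell around each islet
    innervation_distribution: dict = field(
        default_factory=lambda: {"name": "uniform", "low": 0.2, "high": 0.8}
    )
    background_noise: float = 0.02  # Gaussian sd as a fraction of intensity_scale
    intensity_scale: tuple[float, float] = (1000.0, 1000.0)  # (islet, nerve) channel max
    axis_ratio_jitter: float = 0.0  # 0 → spheres; >0 → per-axis scale in [1-j, 1+j]
    n_filaments: int = 0  # unassociated random-walk nerve filaments
    filament_steps: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel_size components must be > 0")
        if self.n_islets < 0:
            raise ValueError("n_islets must be >= 0")
        if self.shell_thickness < 0:
            raise ValueError("shell_thickness must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("volume_shape", "voxel_size", "radius_bounds", "intensity_scale"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _draw_radius(rng: np.random.Generator, config: SynthConfig) -> float:
    dist = config.radius_distribution
    lo, hi = config.radius_bounds
    name = dist.get("name", "lognormal")
    for _ in range(_PLACEMENT_BUDGET):
        if name == "lognormal":
            r = float(rng.lognormal(mean=np.log(dist["median"]), sigma=dist["sigma"]))
        elif name == "uniform":
            r = float(rng.uniform(dist["low"], dist["high"]))
        elif name == "fixed":
            r = float(dist["value"])
        else:
            raise ValueError(f"unknown radius distribution {name!r}")
        if lo <= r <= hi:
            return r
    raise RuntimeError(f"could not draw a radius within bounds {config.radius_bounds}")


def _draw_fraction(rng: np.random.Generator, config: SynthConfig) -> float:
    dist = config.innervation_distribution
    name = dist.get("name", "uniform")
    if name == "uniform":
        return float(rng.uniform(dist["low"], dist["high"]))
    if name == "fixed":
        return float(dist["value"])
    if name == "beta":
        return float(rng.beta(dist["a"], dist["b"]))
    raise ValueError(f"unknown innervation distribution {name!r}")


def _place_centers(
    rng: np.random.Generator, radii: Sequence[float], config: SynthConfig
) -> list[tuple[float, float, float]]:
    """Rejection-sample non-overlapping centers in μm, spheres fully inside the volume."""
    extent = np.array(config.volume_shape, dtype=float) * np.array(config.voxel_size)
    centers: list[np.ndarray] = []
    margin_pad = config.shell_thickness
    for i, r in enumerate(radii):
        margin = r + margin_pad
        lows = np.full(3, margin)
        highs = extent - margin
        if np.any(highs <= lows):
            raise ValueError(
                f"volume extent {tuple(extent)} μm too small for islet radius {r:.1f} μm "
                f"(+ {margin_pad:.1f} μm shell)"
            )
        for _ in range(_PLACEMENT_BUDGET):
            c = rng.uniform(lows, highs)
            ok = True
            for cj, rj in zip(centers, radii):
                sep = max(config.min_center_separation, r + rj)
                if np.linalg.norm(c - cj) < sep:
                    ok = False
                    break
                if config.xy_clearance is not None:
                    if np.hypot(c[0] - cj[0], c[1] - cj[1]) < r + rj + config.xy_clearance:
                        ok = False
                        break
            if ok:
                centers.append(c)
                break
        else:
            raise RuntimeError(
                f"failed to place islet {i} (radius {r:.1f} μm) after {_PLACEMENT_BUDGET} "
                f"attempts under min_center_separation={config.min_center_separation} μm "
                "and non-overlap constraints"
            )
    return [tuple(c) for c in centers]


def _sphere_masks(
    center: tuple[float, float, float],
    radius: float,
    shell: float,
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    axis_scales: np.ndarray,
) -> tuple[tuple[slice, slice, slice], np.ndarray, np.ndarray]:
    """Local bounding-box slices plus boolean (islet, shell) masks in μm space."""
    spacing = np.array(voxel_size)
    reach = (radius + shell) * axis_scales
    lo = np.maximum(np.floor((np.array(center) - reach) / spacing - 1), 0).astype(int)
    hi = np.minimum(np.ceil((np.array(center) + reach) / spacing + 1), shape).astype(int)
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    coords = [
        (np.arange(l, h) + 0.5) * s - c
        for l, h, s, c in zip(lo, hi, spacing, center)
    ]
    dx, dy, dz = np.meshgrid(*coords, indexing="ij")
    # ellipsoid metric: axis_scales stretch the sphere's principal axes
    d2 = (dx / axis_scales[0]) ** 2 + (dy / axis_scales[1]) ** 2 + (dz / axis_scales[2]) ** 2
    islet = d2 <= radius**2
    shell_mask = (d2 > radius**2) & (d2 <= (radius + shell) ** 2)
    return sl, islet, shell_mask


def generate_islet_volume(
    config: SynthConfig,
) -> tuple[ChannelVolume, ChannelVolume, GroundTruth]:
    """Draw a two-channel synthetic pancreas volume with known ground truth.

    Returns the endocrine (islet) channel, the neural-crest (nerve) channel,
    and the GroundTruth record. The islet channel holds one solid bright
    spheroid per islet; the nerve channel fills, for each islet, an exact
    ``round(f * n_shell)``-voxel subset of its shell (so the realized shell
    occupancy matches the drawn fraction ``f`` to within one voxel), plus
    optional unassociated random-walk filaments. Identical configs (including
    seed) give bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.volume_shape)

    radii = [_draw_radius(rng, config) for _ in range(config.n_islets)]
    fractions = [_draw_fraction(rng, config) for _ in range(config.n_islets)]
    centers = _place_centers(rng, radii, config)

    islet_grid = np.zeros(shape, dtype=np.float32)
    nerve_grid = np.zeros(shape, dtype=np.float32)
    islet_peak, nerve_peak = config.intensity_scale

    for center, radius, frac in zip(centers, radii, fractions):
        if config.axis_ratio_jitter > 0:
            scales = rng.uniform(
                1 - config.axis_ratio_jitter, 1 + config.axis_ratio_jitter, size=3
            )
        else:
            scales = np.ones(3)
        sl, islet_mask, shell_mask = _sphere_masks(
            center, radius, config.shell_thickness, shape, config.voxel_size, scales
        )
        islet_grid[sl][islet_mask] = islet_peak
        n_shell = int(shell_mask.sum())
        if n_shell == 0 or config.shell_thickness == 0:
            continue
        n_pos = int(round(frac * n_shell))
        flat_idx = np.flatnonzero(shell_mask)
        chosen = rng.choice(flat_idx, size=n_pos, replace=False)
        sub = nerve_grid[sl]
        flat = sub.reshape(-1)
        flat[chosen] = nerve_peak
        nerve_grid[sl] = flat.reshape(sub.shape)

    for _ in range(config.n_filaments):
        pos = rng.uniform(0, np.array(shape) - 1)
        for _ in range(config.filament_steps):
            step = rng.integers(-1, 2, size=3)
            pos = np.clip(pos + step, 0, np.array(shape) - 1)
            nerve_grid[tuple(pos.astype(int))] = nerve_peak

    if config.background_noise > 0:
        islet_grid = np.clip(
            islet_grid + rng.normal(0, config.background_noise * islet_peak, shape), 0, None
        ).astype(np.float32)
        nerve_grid = np.clip(
            nerve_grid + rng.normal(0, config.background_noise * nerve_peak, shape), 0, None
        ).astype(np.float32)

    truth = GroundTruth(
        islet_centers=centers,
        islet_radii=radii,
        innervation_fractions=fractions,
        sample_id=f"synthetic-{config.seed}",
        seed=config.seed,
    )
    islet_ch = ChannelVolume(
        islet_grid, config.voxel_size, channel_name="islet", sample_id=truth.sample_id
    )
    nerve_ch = ChannelVolume(
        nerve_grid, config.voxel_size, channel_name="nerve", sample_id=truth.sample_id
    )
    return islet_ch, nerve_ch, truth


def generate_stain_image(
    n_cells: int,
    cell_intensity: float,
    background_intensity: float,
    cell_radius_px: float,
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """A 2D stained-section fixture: bright disks (cells) on a uniform background.

    Used to validate signal-over-background quantification; the true cell
    centers are returned alongside the image.
    """
    if cell_intensity <= background_intensity or background_intensity < 0:
        raise ValueError("require cell_intensity > background_intensity >= 0")
    rng = np.random.default_rng(seed)
    img = np.full(shape, float(background_intensity))
    centers: list[np.ndarray] = []
    margin = cell_radius_px + 2
    if n_cells > 0 and (shape[0] <= 2 * margin or shape[1] <= 2 * margin):
        raise ValueError(f"image shape {shape} too small for cell radius {cell_radius_px}")
    for i in range(n_cells):
        for _ in range(_PLACEMENT_BUDGET):
            c = rng.uniform([margin, margin], [shape[0] - margin, shape[1] - margin])
            if all(np.linalg.norm(c - cj) >= 2.5 * cell_radius_px for cj in centers):
                centers.append(c)
                break
        else:
            raise RuntimeError(f"failed to place cell {i} after {_PLACEMENT_BUDGET} attempts")
    xx, yy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    for c in centers:
        disk = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 <= cell_radius_px**2
        img[disk] = cell_intensity
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0, noise_sd, shape), 0, None)
    return img, [tuple(c) for c in centers]


def generate_clearing_series(
    y_max: float,
    k: float,
    timepoints: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Absorbance time series from first-order clearing kinetics y = Ymax(1 − e^(−kt)).

    Gaussian noise of the stated sd is added; absorbance is floored at 0
    since negative optical readings are not physical.
    """
    from .assay_kinetics import ClearingSeries  # local import to avoid a cycle

    t = np.asarray(timepoints, dtype=float)
    if t.size == 0 or np.any(t < 0):
        raise ValueError("timepoints must be non-empty and non-negative")
    if y_max <= 0 or k <= 0:
        raise ValueError("y_max and k must be > 0")
    y = y_max * (1 - np.exp(-k * t))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y + rng.normal(0, noise_sd, t.shape), 0, None)
    return ClearingSeries(timepoints=t.tolist(), absorbance=y.tolist())
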