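"""Islet segmentation and morphometry on MIP sections.

The detection pipeline mirrors standard practice for volumetric endocrine
quantification: each 150 μm MIP section of the insulin channel is globally
Otsu-thresholded, cleaned by one erosion–dilation pass, and connected
components of ≥ 5 pixels (roughly one endocrine cell at 5 μm/px) become islet
candidates. Each candidate is then re-analyzed at full local resolution in a
crop padded by 20 px, where a fresh Otsu threshold, a dilation–erosion pass,
convex hull and moment-based ellipse fit yield the per-islet morphometrics.
The circle-equivalent radius is ``sqrt(hull_area / π) × pixel_size``, i.e. the
convex hull is treated as a circle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import convex_hull_image

from .volume_preprocess import ChannelVolume, ProjectionStack, project_sections

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionConfig",
    "IsletRecord",
    "IsletPopulation",
    "SectionCandidate",
    "segment_section",
    "refine_islet",
    "estimate_radius",
    "detect_islets",
    "deduplicate_adjacent_sections",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)  # default 8-connected structuring element


@dataclass
class DetectionConfig:
    """Tunables of the detection pipeline; defaults match the described method."""

    section_thickness_um: float = 150.0
    min_region_px: int = 5
    refine_margin_px: int = 20  # 100 μm at 5 μm/px
    otsu_nbins: int = 256
    # the section stage erodes-then-dilates; refinement dilates-then-erodes
    section_morph_order: tuple[str, str] = ("erode", "dilate")
    refine_morph_order: tuple[str, str] = ("dilate", "erode")
    deduplicate_adjacent: bool = False  # optional cross-section merging, off by default

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class IsletRecord:
    """One detected islet and its morphometrics.

    ``radius_um`` is the circle-equivalent radius of the refined convex hull;
    ``interaction_score`` and ``entropy_score`` are filled by the innervation
    module. Excluded records carry a non-empty reason and are flagged, never
    deleted.
    """

    islet_id: int
    sample_id: str
    section_index: int
    centroid_um: tuple[float, float]
    section_z_range: tuple[int, int]
    area_px: int
    hull_area_px: float
    radius_um: float
    ellipse_major_um: float = float("nan")
    ellipse_minor_um: float = float("nan")
    ellipse_orientation_rad: float = float("nan")
    neighborhood_px: int = 0
    neighborhood_positive_px: int = 0
    interaction_score: float = float("nan")
    entropy_score: float = float("nan")
    excluded: bool = False
    exclusion_reason: str = ""
    bbox_px: tuple[int, int, int, int] = (0, 0, 0, 0)  # (x0, y0, x1, y1) of refined mask
    mask: np.ndarray | None = None  # refined binary mask over bbox_px (not serialized)

    def __post_init__(self) -> None:
        if self.excluded and not self.exclusion_reason:
            raise ValueError("excluded records must carry a non-empty reason")

    @property
    def neighborhood_positive_fraction(self) -> float:
        """Fraction of the islet neighborhood occupied by positive nerve pixels."""
        if self.neighborhood_px == 0:
            return float("nan")
        return self.neighborhood_positive_px / self.neighborhood_px


@dataclass
class IsletPopulation:
    """All islet records from one sample — the unit of inter-group comparison."""

    records: list[IsletRecord]
    sample_id: str = ""
    stage_label: str = ""
    pixel_size_um: float = 5.0
    config_digest: str = ""

    def __post_init__(self) -> None:
        ids = [r.islet_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("islet_ids must be unique within a population")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def retained(self) -> list[IsletRecord]:
        return [r for r in self.records if not r.excluded]

    def values(self, metric: str, retained_only: bool = True) -> np.ndarray:
        recs = self.retained if retained_only else self.records
        if recs and not hasattr(recs[0], metric):
            raise AttributeError(f"metric {metric!r} not a field of IsletRecord")
        return np.array([getattr(r, metric) for r in recs], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        cols = [
            "islet_id", "sample_id", "section_index", "centroid_um", "section_z_range",
            "area_px", "hull_area_px", "radius_um", "ellipse_major_um", "ellipse_minor_um",
            "ellipse_orientation_rad", "neighborhood_px", "neighborhood_positive_px",
            "interaction_score", "entropy_score", "excluded", "exclusion_reason",
        ]
        rows = []
        for r in self.records:
            d = {c: getattr(r, c) for c in cols}
            d["centroid_x_um"], d["centroid_y_um"] = d.pop("centroid_um")
            d["z_start"], d["z_end"] = d.pop("section_z_range")
            rows.append(d)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(Path(path), index=False)


@dataclass
class SectionCandidate:
    """A candidate region from the section-level segmentation stage."""

    mask: np.ndarray  # boolean, full-section frame
    centroid_px: tuple[int, int]
    area_px: int
    section_index: int
    z_range: tuple[int, int]


def _binary_pass(mask: np.ndarray, order: tuple[str, str], selem: np.ndarray = _SQUARE3) -> np.ndarray:
    ops = {"erode": ndi.binary_erosion, "dilate": ndi.binary_dilation}
    for step in order:
        mask = ops[step](mask, structure=selem)
    return mask


def _otsu(image: np.ndarray, nbins: int) -> float | None:
    """Otsu threshold, or None when the image is (near-)constant."""
    if np.ptp(image) == 0:
        return None
    return float(threshold_otsu(image, nbins=nbins))


def segment_section(
    section: np.ndarray,
    min_region_px: int = 5,
    config: DetectionConfig | None = None,
    section_index: int = 0,
    z_range: tuple[int, int] = (0, 0),
) -> list[SectionCandidate]:
    """Segment one MIP section into candidate islet regions.

    Otsu global threshold → one erosion+dilation pass (3×3, 8-connected) for
    noise removal → 8-connected component labeling → drop components smaller
    than ``min_region_px``. Constant sections (degenerate Otsu) yield an
    empty list.
    """
    cfg = config or DetectionConfig(min_region_px=min_region_px)
    section = np.asarray(section)
    if section.size == 0:
        raise ValueError("section must be non-empty")
    thr = _otsu(section, cfg.otsu_nbins)
    if thr is None:
        logger.info("segment_section: constant section %d, no candidates", section_index)
        return []
    binary = _binary_pass(section > thr, cfg.section_morph_order)
    labeled = label(binary, connectivity=2)
    out: list[SectionCandidate] = []
    for prop in regionprops(labeled):
        if prop.area < cfg.min_region_px:
            continue
        mask = labeled == prop.label
        cx, cy = prop.centroid
        out.append(
            SectionCandidate(
                mask=mask,
                centroid_px=(int(round(cx)), int(round(cy))),
                area_px=int(prop.area),
                section_index=section_index,
                z_range=z_range,
            )
        )
    return out


def estimate_radius(hull_area_px: float, pixel_size: float) -> float:
    """Circle-equivalent radius in μm from a convex-hull area in px²."""
    if hull_area_px <= 0:
        raise ValueError(f"hull_area_px must be > 0, got {hull_area_px}")
    return math.sqrt(hull_area_px / math.pi) * pixel_size


def refine_islet(
    volume_context: ChannelVolume,
    candidate: SectionCandidate,
    islet_id: int,
    margin_px: int = 20,
    config: DetectionConfig | None = None,
) -> IsletRecord:
    """Re-analyze one candidate at full local resolution.

    The candidate's bounding box is expanded by ``margin_px`` in ±x and ±y
    (clipped at the volume bounds), max-projected over the candidate's
    section z-range, and re-thresholded with Otsu; one dilation+erosion pass
    removes noise; the connected component overlapping the original candidate
    is kept. Its convex hull defines the radius; a moments-based ellipse fit
    gives major/minor axes and orientation. If the candidate vanishes under
    the local threshold, the record is flagged ``refinement-empty``.
    """
    cfg = config or DetectionConfig(refine_margin_px=margin_px)
    px = volume_context.voxel_size[0]
    nx, ny = volume_context.shape[:2]
    coords = np.argwhere(candidate.mask)
    x0, y0 = coords.min(axis=0)
    x1, y1 = coords.max(axis=0) + 1
    cx0, cy0 = max(0, x0 - cfg.refine_margin_px), max(0, y0 - cfg.refine_margin_px)
    cx1, cy1 = min(nx, x1 + cfg.refine_margin_px), min(ny, y1 + cfg.refine_margin_px)
    z0, z1 = candidate.z_range
    crop = volume_context.intensities[cx0:cx1, cy0:cy1, z0:z1].max(axis=2)

    def _empty(reason: str) -> IsletRecord:
        cx, cy = candidate.centroid_px
        return IsletRecord(
            islet_id=islet_id,
            sample_id=volume_context.sample_id,
            section_index=candidate.section_index,
            centroid_um=((cx + 0.5) * px, (cy + 0.5) * volume_context.voxel_size[1]),
            section_z_range=candidate.z_range,
            area_px=0,
            hull_area_px=0.0,
            radius_um=0.0,
            excluded=True,
            exclusion_reason=reason,
        )

    thr = _otsu(crop, cfg.otsu_nbins)
    if thr is None:
        return _empty("refinement-empty")
    binary = _binary_pass(crop > thr, cfg.refine_morph_order)
    labeled = label(binary, connectivity=2)
    cand_crop = candidate.mask[cx0:cx1, cy0:cy1]
    overlap_labels = np.unique(labeled[cand_crop & (labeled > 0)])
    if overlap_labels.size == 0:
        return _empty("refinement-empty")
    # keep the component with the largest overlap with the original candidate
    best = max(overlap_labels, key=lambda l: int(np.sum((labeled == l) & cand_crop)))
    mask = labeled == best

    hull = convex_hull_image(mask)
    hull_area = float(hull.sum())
    prop = regionprops(mask.astype(np.uint8))[0]
    cx, cy = prop.centroid
    return IsletRecord(
        islet_id=islet_id,
        sample_id=volume_context.sample_id,
        section_index=candidate.section_index,
        centroid_um=((cx0 + cx + 0.5) * px, (cy0 + cy + 0.5) * volume_context.voxel_size[1]),
        section_z_range=candidate.z_range,
        area_px=int(prop.area),
        hull_area_px=hull_area,
        radius_um=estimate_radius(hull_area, px),
        ellipse_major_um=prop.axis_major_length / 2 * px,
        ellipse_minor_um=prop.axis_minor_length / 2 * px,
        ellipse_orientation_rad=float(prop.orientation),
        bbox_px=(int(cx0), int(cy0), int(cx1), int(cy1)),
        mask=mask,
    )


def deduplicate_adjacent_sections(pop: IsletPopulation) -> IsletPopulation:
    """Merge records of one islet detected in adjacent sections.

    Section-wise analysis counts an islet spanning a slab boundary once per
    slab. Records in adjacent sections whose centroids lie within one mean
    radius of each other are clustered; the largest-radius record (the one
    nearest the equator) is kept and the rest flagged ``duplicate-adjacent``.
    """
    recs = sorted(pop.records, key=lambda r: (-r.radius_um, r.islet_id))
    kept: list[IsletRecord] = []
    mean_r = float(np.mean([r.radius_um for r in pop.records])) if pop.records else 0.0
    for r in recs:
        dup = False
        for k in kept:
            if abs(k.section_index - r.section_index) == 1:
                d = math.hypot(
                    k.centroid_um[0] - r.centroid_um[0], k.centroid_um[1] - r.centroid_um[1]
                )
                if d <= mean_r:
                    dup = True
                    break
        if dup:
            r.excluded = True
            r.exclusion_reason = "duplicate-adjacent"
        else:
            kept.append(r)
    ordered = sorted(pop.records, key=lambda r: r.islet_id)
    return IsletPopulation(
        records=ordered,
        sample_id=pop.sample_id,
        stage_label=pop.stage_label,
        pixel_size_um=pop.pixel_size_um,
        config_digest=pop.config_digest,
    )


def detect_islets(
    islet_channel: ChannelVolume,
    config: DetectionConfig | None = None,
    stage_label: str = "",
    stack: ProjectionStack | None = None,
) -> IsletPopulation:
    """End-to-end islet detection on a (preprocessed) insulin channel.

    MIP sectioning → per-section segmentation → per-candidate refinement.
    Deterministic for fixed input and config. A pre-computed ProjectionStack
    may be supplied (e.g. for virtual thin sections); otherwise the volume is
    sectioned at ``config.section_thickness_um``.
    """
    cfg = config or DetectionConfig()
    if stack is None:
        stack = project_sections(islet_channel, cfg.section_thickness_um)
    records: list[IsletRecord] = []
    next_id = 0
    for si, (section, z_range) in enumerate(zip(stack.sections, stack.z_ranges)):
        for cand in segment_section(
            section, config=cfg, section_index=si, z_range=z_range
        ):
            rec = refine_islet(islet_channel, cand, islet_id=next_id, config=cfg)
            records.append(rec)
            next_id += 1
    pop = IsletPopulation(
        records=records,
        sample_id=islet_channel.sample_id,
        stage_label=stage_label,
        pixel_size_um=islet_channel.voxel_size[0],
        config_digest=cfg.digest(),
    )
    if cfg.deduplicate_adjacent:
        pop = deduplicate_adjacent_sections(pop)
    return pop
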