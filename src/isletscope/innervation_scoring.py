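"""Peri-islet innervation scoring and artifact exclusion.

Each islet is assigned a *neighborhood*: its filled convex hull dilated
outward by 2 px (10 μm at 5 μm/px), covering the islet interior plus the
shell where the peri-islet Schwann-cell sheath and nerve fibers sit. Nerve
pixels are called by an adaptive local-mean threshold of the nerve channel,
cleaned by a 1 px erosion, and counted inside the neighborhood; the
interaction (innervation) score is that count divided by the islet's pixel
area. Records whose neighborhood positive-pixel fraction or nerve-crop
entropy lies more than 3 SD from a reference population's mean are flagged
as artifacts (non-neural features) — flagged, never deleted — with
thresholds computed once from the reference and held constant across samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_local
from skimage.morphology import convex_hull_image

from .islet_detection import IsletPopulation, IsletRecord

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborhoodParams",
    "neighborhood_mask",
    "nerve_positive_mask",
    "score_innervation",
    "score_population",
    "histogram_entropy",
    "exclude_artifacts",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass
class NeighborhoodParams:
    offset_px: int = 2  # 10 μm at 5 μm/px
    nerve_erosion_px: int = 1  # 5 μm
    adaptive_block_px: int = 51  # local-mean window; must be odd
    adaptive_offset: float = 0.0
    exclusion_sd_multiplier: float = 3.0
    entropy_nbins: int = 256

    def __post_init__(self) -> None:
        if self.offset_px < 0:
            raise ValueError("offset_px must be >= 0")
        if self.adaptive_block_px < 3 or self.adaptive_block_px % 2 == 0:
            raise ValueError("adaptive_block_px must be odd and >= 3")


def neighborhood_mask(hull_mask: np.ndarray, offset_px: int) -> np.ndarray:
    """Islet neighborhood: the filled hull dilated outward by ``offset_px``.

    Dilation is Euclidean (every pixel within ``offset_px`` of the hull),
    clipped at the image bounds; offset 0 returns the filled hull itself.
    """
    hull_mask = np.asarray(hull_mask, dtype=bool)
    if not hull_mask.any():
        raise ValueError("hull_mask must be non-empty")
    if offset_px == 0:
        return hull_mask.copy()
    dist = ndi.distance_transform_edt(~hull_mask)
    return dist <= offset_px


def nerve_positive_mask(nerve_section: np.ndarray, params: NeighborhoodParams) -> np.ndarray:
    """Positive nerve pixels: adaptive local-mean threshold, then 1 px erosion.

    The erosion (3×3 square, ``nerve_erosion_px`` iterations) removes
    isolated supra-threshold noise pixels; with a zero erosion count the raw
    thresholded mask is returned.
    """
    nerve_section = np.asarray(nerve_section, dtype=float)
    local = threshold_local(
        nerve_section,
        block_size=params.adaptive_block_px,
        method="mean",
        offset=params.adaptive_offset,
    )
    positive = nerve_section > local
    if params.nerve_erosion_px > 0:
        positive = ndi.binary_erosion(
            positive, structure=_SQUARE3, iterations=params.nerve_erosion_px
        )
    return positive


def _record_masks(
    islet: IsletRecord, shape: tuple[int, int], params: NeighborhoodParams
) -> tuple[np.ndarray, np.ndarray]:
    """(filled hull, neighborhood) masks of a record in the full-section frame."""
    if islet.mask is None:
        raise ValueError(f"islet {islet.islet_id} carries no refined mask")
    x0, y0, x1, y1 = islet.bbox_px
    full = np.zeros(shape, dtype=bool)
    full[x0:x1, y0:y1] = convex_hull_image(islet.mask)
    return full, neighborhood_mask(full, params.offset_px)


def histogram_entropy(values: np.ndarray, nbins: int = 256) -> float:
    """Shannon entropy (bits) of the intensity histogram of ``values``."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        return 0.0
    hist, _ = np.histogram(values, bins=nbins)
    p = hist[hist > 0] / values.size
    return float(-(p * np.log2(p)).sum())


def score_innervation(
    nerve_section: np.ndarray,
    islet: IsletRecord,
    params: NeighborhoodParams | None = None,
    positive: np.ndarray | None = None,
) -> IsletRecord:
    """Score one islet's neighborhood on an aligned nerve-channel MIP section.

    Fills ``neighborhood_positive_px`` (positive nerve pixels inside the
    neighborhood, after thresholding and erosion), ``interaction_score``
    (positives / islet pixel area) and ``entropy_score`` (histogram entropy
    of the nerve intensities over the neighborhood). A precomputed
    ``positive`` mask for the whole section may be passed to avoid
    re-thresholding per islet.
    """
    params = params or NeighborhoodParams()
    if islet.area_px == 0:
        raise ValueError(f"islet {islet.islet_id} has zero area (violates detection contract)")
    if positive is None:
        positive = nerve_positive_mask(nerve_section, params)
    _, neigh = _record_masks(islet, nerve_section.shape, params)
    n_pos = int(np.sum(positive & neigh))
    entropy = histogram_entropy(np.asarray(nerve_section)[neigh], params.entropy_nbins)
    return replace(
        islet,
        neighborhood_px=int(neigh.sum()),
        neighborhood_positive_px=n_pos,
        interaction_score=n_pos / islet.area_px,
        entropy_score=entropy,
    )


def score_population(
    pop: IsletPopulation,
    nerve_stack,
    params: NeighborhoodParams | None = None,
) -> IsletPopulation:
    """Score every record of a population against its nerve-channel ProjectionStack."""
    params = params or NeighborhoodParams()
    positives = {
        i: nerve_positive_mask(sec, params) for i, sec in enumerate(nerve_stack.sections)
    }
    out = []
    for rec in pop.records:
        if rec.mask is None or rec.area_px == 0:
            out.append(rec)
            continue
        sec = nerve_stack.sections[rec.section_index]
        out.append(score_innervation(sec, rec, params, positive=positives[rec.section_index]))
    return replace_records(pop, out)


def replace_records(pop: IsletPopulation, records: list[IsletRecord]) -> IsletPopulation:
    return IsletPopulation(
        records=records,
        sample_id=pop.sample_id,
        stage_label=pop.stage_label,
        pixel_size_um=pop.pixel_size_um,
        config_digest=pop.config_digest,
    )


def exclude_artifacts(
    pop: IsletPopulation,
    reference: IsletPopulation | str = "self",
    sd_multiplier: float = 3.0,
    metrics: tuple[str, ...] = ("neighborhood_positive_fraction", "entropy_score"),
) -> IsletPopulation:
    """Flag records whose scores deviate > ``sd_multiplier`` SD from a reference mean.

    For each metric (positive-pixel score and entropy by default) the mean
    and SD are computed once from the reference population — the pooled
    current sample when ``reference="self"`` — and a record is flagged when
    ``|x − mean| > sd_multiplier × sd`` on *either* metric. With a
    zero-variance reference nothing is flagged (strict inequality). Records
    are flagged with a reason, never deleted.
    """
    ref = pop if reference == "self" else reference
    if len(ref.records) < 2:
        raise ValueError("reference population must have at least 2 records (sd undefined)")
    thresholds = {}
    for m in metrics:
        vals = np.array([getattr(r, m) for r in ref.records], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            raise ValueError(f"reference has fewer than 2 finite values for {m!r}")
        thresholds[m] = (float(vals.mean()), float(vals.std(ddof=0)))
    out = []
    for rec in pop.records:
        reasons = []
        for m in metrics:
            mean, sd = thresholds[m]
            x = getattr(rec, m)
            if np.isfinite(x) and abs(x - mean) > sd_multiplier * sd:
                reasons.append(f"{m}-outlier")
        if reasons and not rec.excluded:
            rec = replace(rec, excluded=True, exclusion_reason=";".join(reasons))
        out.append(rec)
    return replace_records(pop, out)
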