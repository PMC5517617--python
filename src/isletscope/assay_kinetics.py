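"""Clearing kinetics, staining signal-over-background, and protein-loss normalization.

Tissue clearing is modeled as a single-reactant transformation with
first-order kinetics: optical clearing progress follows
``y = Ymax · (1 − e^(−k·t))`` with ``k`` the clearing rate constant (per
hour). Rates from different tissue / hydrogel / temperature conditions are
made comparable by normalizing to a reference fit (conventionally brain
tissue in the A4B4P4 formulation cleared at 37 °C).

Staining quality on 2D sections is quantified as the mean intensity of
detected cellular regions divided by the mean extracellular background
intensity; regions are found by Otsu thresholding, a 1 px erosion,
morphological closing, and a size/roundness filter that drops non-cellular
features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

logger = logging.getLogger(__name__)

__all__ = [
    "ClearingSeries",
    "KineticsFit",
    "fit_clearing_rate",
    "normalize_rate",
    "staining_snr",
    "protein_loss_normalize",
]


@dataclass
class ClearingSeries:
    """Absorbance-vs-time measurements for one clearing condition."""

    timepoints: list[float]  # hours
    absorbance: list[float]
    tissue: str = ""
    gel_formulation: str = ""  # e.g. A4B4P0
    temperature_C: float = float("nan")

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        y = np.asarray(self.absorbance, dtype=float)
        if t.size != y.size:
            raise ValueError("timepoints and absorbance must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("absorbance must be non-negative")

    @classmethod
    def from_csv(cls, path: str | Path, **meta) -> "ClearingSeries":
        """Read a plain CSV with columns ``t`` (hours) and ``y``."""
        df = pd.read_csv(Path(path))
        if not {"t", "y"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns 't' and 'y', got {list(df.columns)}")
        return cls(timepoints=df["t"].tolist(), absorbance=df["y"].tolist(), **meta)


@dataclass
class KineticsFit:
    """Fitted first-order clearing parameters."""

    y_max: float
    k: float  # per hour
    residual_sse: float
    normalized_rate: float = float("nan")  # k / k_reference once a reference is set
    degenerate: bool = False  # flat/zero series: k is not identifiable


def _model(t: np.ndarray, y_max: float, k: float) -> np.ndarray:
    return y_max * (1 - np.exp(-k * t))


def fit_clearing_rate(series: ClearingSeries) -> KineticsFit:
    """Least-squares fit of y = Ymax(1 − e^(−kt)) to a clearing series.

    Initialization: Ymax₀ = max(y), k₀ = 1/median(t), with five multi-start
    perturbations of k₀ over two decades; the best-SSE converged fit wins.
    An all-zero (or flat-at-zero) series is returned flagged ``degenerate``
    rather than raising, since it is a valid assay outcome (no clearing).
    """
    t = np.asarray(series.timepoints, dtype=float)
    y = np.asarray(series.absorbance, dtype=float)
    if t.size < 3:
        raise ValueError("fit requires at least 3 timepoints")
    if np.all(y == 0):
        logger.warning("fit_clearing_rate: all-zero series; degenerate fit")
        return KineticsFit(y_max=0.0, k=0.0, residual_sse=0.0, degenerate=True)

    t_med = np.median(t[t > 0]) if np.any(t > 0) else 1.0
    k0 = 1.0 / t_med
    starts = [k0 * f for f in (1.0, 0.1, 0.5, 2.0, 10.0)]
    best = None
    tried = []
    for ks in starts:
        tried.append(ks)
        try:
            popt, _ = curve_fit(
                _model,
                t,
                y,
                p0=[float(y.max()), ks],
                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                maxfev=10_000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((y - _model(t, *popt)) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        raise RuntimeError(f"clearing-rate fit failed to converge; k starts tried: {tried}")
    (y_max, k), sse = best
    return KineticsFit(y_max=float(y_max), k=float(k), residual_sse=sse)


def normalize_rate(fit: KineticsFit, reference: KineticsFit) -> KineticsFit:
    """Express a fitted rate relative to a reference condition (k / k_ref)."""
    if reference.k <= 0:
        raise ValueError("reference k must be > 0")
    return KineticsFit(
        y_max=fit.y_max,
        k=fit.k,
        residual_sse=fit.residual_sse,
        normalized_rate=fit.k / reference.k,
        degenerate=fit.degenerate,
    )


def staining_snr(
    image: np.ndarray,
    min_area_px: int = 20,
    max_area_px: int = 2000,
    min_roundness: float = 0.5,
) -> tuple[float, list]:
    """Signal-over-background of a stained 2D section.

    Otsu threshold → 1 px erosion → morphological closing → region
    properties; regions outside the size bounds or with roundness
    (4π·area/perimeter²) below ``min_roundness`` are dropped as
    non-cellular. The ratio is the mean intensity over retained region
    pixels divided by the mean intensity over all other pixels. With no
    retained regions the ratio is NaN (flagged undefined), never silently 0.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("image must be non-empty")
    if np.ptp(image) == 0:
        logger.warning("staining_snr: constant image, no regions; ratio undefined")
        return float("nan"), []
    thr = threshold_otsu(image, nbins=256)
    binary = image > thr
    binary = ndi.binary_erosion(binary, structure=np.ones((3, 3)))
    binary = ndi.binary_closing(binary, structure=np.ones((3, 3)))
    labeled = label(binary, connectivity=2)
    retained = []
    for prop in regionprops(labeled):
        if not (min_area_px <= prop.area <= max_area_px):
            continue
        perim = prop.perimeter
        roundness = 4 * np.pi * prop.area / perim**2 if perim > 0 else 0.0
        if roundness < min_roundness:
            continue
        retained.append(prop)
    if not retained:
        logger.warning("staining_snr: no regions pass size/roundness filters; ratio undefined")
        return float("nan"), []
    region_mask = np.isin(labeled, [p.label for p in retained])
    signal = float(image[region_mask].mean())
    background = float(image[~region_mask].mean())
    return signal / background, retained


def protein_loss_normalize(bca_protein_ug: float, sample_weight_mg: float) -> float:
    """Protein lost to the clearing solution, normalized by starting tissue weight."""
    if sample_weight_mg <= 0:
        raise ValueError(f"sample_weight must be > 0, got {sample_weight_mg}")
    return bca_protein_ug / sample_weight_mg
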