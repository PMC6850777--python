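"""Image calibration and per-cell fluorescence statistics.

Calibration follows the two-stage scheme standard for quantitative widefield
fluorescence: (1) a per-pixel camera bias map estimated as the mean of a
dark stack; (2) a flat-field correction estimated from a dye-filled device
imaged with small stage offsets — each frame is grayscale-dilated (removing
narrow dark device features) and the per-pixel median across frames taken as
the illumination field. A raw image is corrected as
``(raw - bias) * flat_correction`` with the correction normalized to mean 1
so corrected images stay on the raw intensity scale.

The per-cell statistic is the nucleolar asymmetry score: the mean of the
brightest ``top_fraction`` (default 2%) of a cell's pixels divided by the
cell's median pixel. Normalizing by the median makes the score invariant to
global multiplicative changes such as photobleaching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.morphology import dilation, disk

from .types import DaughterSegment, TracePair

__all__ = [
    "CalibrationSet",
    "QuantParams",
    "estimate_bias",
    "estimate_flatfield",
    "correct_image",
    "nucleolar_asymmetry",
    "extract_compartment_signal",
]


@dataclass
class QuantParams:
    """Parameters of the calibration/quantification pipeline."""

    top_fraction: float = 0.02
    dilation_radius: int = 3
    min_mask_pixels: int = 50

    def validate(self) -> None:
        if not (0.0 < self.top_fraction < 1.0):
            raise ValueError(f"top_fraction={self.top_fraction} must lie in (0, 1)")
        if self.dilation_radius < 1:
            raise ValueError("dilation_radius must be >= 1")


@dataclass
class CalibrationSet:
    """Per-pixel bias offsets and multiplicative flat-field factors."""

    bias_map: np.ndarray
    flat_correction: np.ndarray

    def validate(self) -> None:
        if self.bias_map.shape != self.flat_correction.shape:
            raise ValueError(
                f"bias_map shape {self.bias_map.shape} != flat_correction shape "
                f"{self.flat_correction.shape}"
            )
        m = float(np.mean(self.flat_correction))
        if abs(m - 1.0) > 1e-6:
            raise ValueError(f"flat_correction mean {m} deviates from 1 beyond 1e-6")


def _as_stack(stack: np.ndarray, min_frames: int) -> np.ndarray:
    arr = np.asarray(stack, dtype=float)
    if arr.ndim != 3:
        raise ValueError(f"expected a (frames, h, w) stack, got shape {arr.shape}")
    if arr.shape[0] < min_frames:
        raise ValueError(f"need at least {min_frames} frames, got {arr.shape[0]}")
    return arr


def estimate_bias(dark_stack: np.ndarray) -> np.ndarray:
    """Per-pixel mean of a stack acquired with no illumination."""
    arr = _as_stack(dark_stack, min_frames=2)
    return arr.mean(axis=0)


def estimate_flatfield(
    dye_stack: np.ndarray, params: Optional[QuantParams] = None
) -> np.ndarray:
    """Flat-field correction from a bias-subtracted dye stack.

    Each frame is grayscale-dilated with a disk (suppressing narrow dark
    device features), the per-pixel median across frames is taken as the
    illumination field, and the correction is ``mean(field) / field`` so
    that it has mean 1.
    """
    params = params or QuantParams()
    params.validate()
    arr = _as_stack(dye_stack, min_frames=3)
    footprint = disk(params.dilation_radius)
    dilated = np.stack([dilation(frame, footprint) for frame in arr])
    fld = np.median(dilated, axis=0)
    if np.any(fld <= 0):
        raise ValueError(
            "illumination field has nonpositive pixels after dilation; cannot invert"
        )
    corr = 1.0 / fld
    return corr / corr.mean()  # exact mean-1 normalization


def correct_image(raw: np.ndarray, calib: CalibrationSet) -> np.ndarray:
    """Bias-subtract and flat-field a raw image, clipping at zero."""
    calib.validate()
    raw = np.asarray(raw, dtype=float)
    if raw.shape != calib.bias_map.shape:
        raise ValueError(
            f"image shape {raw.shape} does not match calibration {calib.bias_map.shape}"
        )
    return np.clip((raw - calib.bias_map) * calib.flat_correction, 0.0, None)


def nucleolar_asymmetry(pixels: np.ndarray, params: Optional[QuantParams] = None) -> float:
    """Top-``top_fraction`` mean over median score for one cell's pixels.

    The brightest ``ceil(top_fraction * n)`` pixels (at least one) are
    averaged and divided by the median of all mask pixels. Scale-invariant;
    undefined when the median is zero.
    """
    params = params or QuantParams()
    params.validate()
    pix = np.asarray(pixels, dtype=float).ravel()
    if pix.size < params.min_mask_pixels:
        raise ValueError(
            f"mask has {pix.size} pixels, below min_mask_pixels={params.min_mask_pixels}"
        )
    med = float(np.median(pix))
    if med == 0.0:
        raise ValueError("cell median is zero; asymmetry score undefined")
    k = max(1, int(np.ceil(params.top_fraction * pix.size)))
    top = np.partition(pix, pix.size - k)[pix.size - k :]
    return float(top.mean() / med)


def extract_compartment_signal(
    image_series: np.ndarray,
    mother_mask: np.ndarray,
    daughter_mask: np.ndarray,
    calib: Optional[CalibrationSet] = None,
    cell_id: str = "cell",
    start_min: float = 0.0,
    sampling_interval_min: float = 5.0,
) -> TracePair:
    """Summed per-frame intensity in the mother and daughter masks.

    Frames are calibration-corrected when ``calib`` is given. The daughter
    sums are returned as a single segment spanning the series (mask-based
    extraction has no bud-emergence annotation).
    """
    series = _as_stack(image_series, min_frames=1)
    mother_mask = np.asarray(mother_mask, dtype=bool)
    daughter_mask = np.asarray(daughter_mask, dtype=bool)
    if not mother_mask.any() or not daughter_mask.any():
        raise ValueError("compartment masks must be non-empty")
    if np.any(mother_mask & daughter_mask):
        raise ValueError("mother and daughter masks overlap")
    if calib is not None:
        series = np.stack([correct_image(f, calib) for f in series])
    mother = series[:, mother_mask].sum(axis=1)
    daughter = series[:, daughter_mask].sum(axis=1)
    return TracePair(
        cell_id=cell_id,
        start_min=start_min,
        mother_signal=mother,
        daughter_segments=[DaughterSegment(1, start_min, daughter)],
        sampling_interval_min=sampling_interval_min,
    )
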