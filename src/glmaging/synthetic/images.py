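"""Synthetic microscopy fixtures with pixel-level ground truth.

Three scenarios mirror the calibration and quantification inputs of a
timelapse microscope on a microfluidic device:

``dark``
    Frames acquired with no illumination: a fixed per-pixel camera bias
    pattern plus Gaussian read noise. Ground truth: the bias map.
``dye``
    A fluorescent dye flowed through the device: a smooth multiplicative
    vignette times the dye level, with a small random x/y stage offset per
    frame and narrow dark device features that move with the stage. Ground
    truth: the vignette (illumination field) and the feature-free field.
``cells``
    Disk-shaped cells containing a bright nuclear focus on a flat
    background. Ground truth: the label mask and, per cell, the
    top-2%/median asymmetry score of the noiseless pixels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["ImageFixture", "generate_image_fixtures"]

SCENARIOS = ("dark", "dye", "cells")


@dataclass
class ImageFixture:
    """An image stack plus the ground truth used to generate it."""

    scenario: str
    stack: np.ndarray  # (n_frames, h, w)
    bias_map: Optional[np.ndarray] = None
    vignette: Optional[np.ndarray] = None
    field: Optional[np.ndarray] = None  # vignette x dye level (feature-free)
    mask: Optional[np.ndarray] = None  # integer labels, 0 = background
    true_scores: dict[int, float] = dataclasses.field(default_factory=dict)
    noiseless: Optional[np.ndarray] = None  # single noise-free frame (cells)


def _vignette(shape: tuple[int, int], amplitude: float) -> np.ndarray:
    """Smooth radial illumination falloff, 1.0 at centre."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - (h - 1) / 2) / h) ** 2 + ((xx - (w - 1) / 2) / w) ** 2
    v = 1.0 - amplitude * r2 / r2.max()
    return v


def generate_image_fixtures(
    shape: tuple[int, int],
    n_frames: int,
    scenario: str,
    seed: int,
    read_noise_sd: float = 2.0,
    bias_level: float = 100.0,
    dye_level: float = 1000.0,
    vignette_amplitude: float = 0.3,
    n_cells: int = 12,
    cell_noise_sd: float = 0.0,
) -> ImageFixture:
    """Generate one fixture stack; identical arguments reproduce it exactly."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    h, w = shape
    if h < 64 or w < 64:
        raise ValueError("shape must be at least 64x64")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)

    if scenario == "dark":
        # Fixed-pattern bias: smooth offset plus per-pixel structure.
        bias = (
            bias_level
            + 5.0 * _vignette(shape, 1.0)
            + rng.normal(0.0, 3.0, size=shape)
        )
        stack = bias[None] + read_noise_sd * rng.standard_normal((n_frames, h, w))
        return ImageFixture("dark", stack, bias_map=bias)

    if scenario == "dye":
        vig = _vignette(shape, vignette_amplitude)
        fld = vig * dye_level
        # Device features (channel walls): narrow dark lines fixed to the
        # device, hence shifted with the stage offsets; the vignette is an
        # optical property and stays fixed in the camera frame.
        pad = 8
        trans = np.ones((h + 2 * pad, w + 2 * pad))
        for x in rng.integers(pad, w + pad, size=3):
            trans[:, x] = 0.3
        for y in rng.integers(pad, h + pad, size=2):
            trans[y, :] = 0.3
        frames = np.empty((n_frames, h, w))
        for k in range(n_frames):
            dy, dx = rng.integers(-pad, pad + 1, size=2)
            sub = trans[pad + dy : pad + dy + h, pad + dx : pad + dx + w]
            frames[k] = vig * dye_level * sub
        frames += read_noise_sd * rng.standard_normal(frames.shape)
        return ImageFixture("dye", frames, vignette=vig, field=fld)

    # cells
    background = 50.0
    img = np.full(shape, background)
    mask = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    label = 0
    attempts = 0
    centers: list[tuple[int, int, int]] = []
    while label < n_cells and attempts < 200:
        attempts += 1
        r = int(rng.integers(8, 13))
        cy = int(rng.integers(r + 1, h - r - 1))
        cx = int(rng.integers(r + 1, w - r - 1))
        if any((cy - y) ** 2 + (cx - x) ** 2 < (r + rr + 2) ** 2 for y, x, rr in centers):
            continue
        label += 1
        centers.append((cy, cx, r))
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        body = float(rng.uniform(200.0, 400.0))
        img[disk] = body
        mask[disk] = label
        # Bright nuclear focus: a small off-centre disk.
        fr = max(1, r // 4)
        fy, fx = cy + int(rng.integers(-r // 2, r // 2 + 1)), cx + int(
            rng.integers(-r // 2, r // 2 + 1)
        )
        focus = (yy - fy) ** 2 + (xx - fx) ** 2 <= fr**2
        img[focus & disk] = body * float(rng.uniform(4.0, 8.0))

    from ..imagequant import QuantParams, nucleolar_asymmetry

    params = QuantParams()
    scores = {}
    for lab in range(1, label + 1):
        pix = img[mask == lab]
        if pix.size >= params.min_mask_pixels:
            scores[lab] = nucleolar_asymmetry(pix, params)

    stack = img[None] + cell_noise_sd * rng.standard_normal((n_frames, h, w))
    return ImageFixture(
        "cells", stack, mask=mask, true_scores=scores, noiseless=img
    )
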