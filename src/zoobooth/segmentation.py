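"""Foreground segmentation for dark-field zooplankton frames.

Three stages turn a grayscale frame into a clean binary mask of the animal:

1. a focus score (variance of the Laplacian) used to drop blurred frames,
2. an adaptive per-pixel background model in the KNN family — each pixel
   keeps a store of recent intensity samples and is called background when
   enough stored samples are close to the current value,
3. binary erosion/dilation to strip drifting particles and thin appendages
   (spine, antennae) while restoring the main body to its original extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "sharpness",
    "BackgroundModel",
    "StructuringElement",
    "erode",
    "dilate",
]

_LAPLACIAN = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)


def sharpness(frame: np.ndarray) -> float:
    """Variance of the 3x3 Laplacian response — a standard focus measure.

    Borders are replicate-padded.  A constant frame scores 0; blurring a
    frame strictly lowers its score.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("sharpness expects a non-empty 2D grayscale frame")
    resp = ndimage.convolve(frame, _LAPLACIAN, mode="nearest")
    return float(resp.var())


@dataclass
class StructuringElement:
    """Rectangular structuring element for binary morphology."""

    size: tuple[int, int] = (3, 3)
    iterations: int = 1

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 1 or w < 1 or h % 2 == 0 or w % 2 == 0:
            raise ValueError("structuring element sides must be odd and >= 1")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")

    @property
    def footprint(self) -> np.ndarray:
        return np.ones(self.size, dtype=bool)


def _as_binary(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1, 255, True, False))):
        raise ValueError("mask must be binary (values 0/255)")
    return arr > 0


def erode(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary erosion; pixels beyond the image border count as background,
    so foreground touching the border is eroded away."""
    binary = _as_binary(mask)
    if se.iterations == 0:
        return (binary * np.uint8(255)).astype(np.uint8)
    out = ndimage.binary_erosion(
        binary, structure=se.footprint, iterations=se.iterations, border_value=0
    )
    return (out * np.uint8(255)).astype(np.uint8)


def dilate(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary dilation; the outside of the image stays background."""
    binary = _as_binary(mask)
    if se.iterations == 0:
        return (binary * np.uint8(255)).astype(np.uint8)
    out = ndimage.binary_dilation(
        binary, structure=se.footprint, iterations=se.iterations, border_value=0
    )
    return (out * np.uint8(255)).astype(np.uint8)


@dataclass
class BackgroundModel:
    """Sample-based adaptive background subtractor (KNN family).

    Every pixel stores ``n_samples`` recent intensities.  A pixel is
    background when at least ``k_required`` stored samples lie within
    ``match_radius`` (squared intensity difference, 8-bit units); otherwise
    it is foreground.  After classification one stored sample per pixel is
    stochastically replaced with the current value at rate 1/``history``,
    so a stationary object is absorbed into the background over a few
    multiples of ``history`` frames.

    During the first ``warmup`` frames the store is filled deterministically
    from the incoming frames and the output mask is all-background.
    Fully deterministic for a fixed ``seed``.
    """

    n_samples: int = 10
    k_required: int = 3
    match_radius: float = 400.0
    history: int = 500
    warmup: int = 10
    seed: int = 0
    _samples: np.ndarray | None = field(default=None, repr=False)
    _frames_seen: int = field(default=0, repr=False)
    _rng: np.random.Generator | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (self.n_samples >= self.k_required >= 1):
            raise ValueError("need n_samples >= k_required >= 1")
        if self.history < 1 or self.warmup < 0:
            raise ValueError("history >= 1 and warmup >= 0 required")
        self._rng = np.random.default_rng(self.seed)
        # match threshold on |diff|, precomputed from the squared radius
        self._abs_radius = int(np.floor(np.sqrt(self.match_radius)))

    def apply(self, frame: np.ndarray) -> np.ndarray:
        """Classify *frame* and update the model; returns a uint8 mask
        (255 = foreground)."""
        frame = np.asarray(frame)
        if frame.ndim != 2:
            raise ValueError("background model expects 2D grayscale frames")
        frame8 = frame.astype(np.uint8, copy=False)
        if self._samples is None:
            self._samples = np.repeat(frame8[None, :, :], self.n_samples, axis=0)
        elif self._samples.shape[1:] != frame.shape:
            raise ValueError(
                f"frame shape {frame.shape} does not match model geometry "
                f"{self._samples.shape[1:]}"
            )

        if self._frames_seen < self.warmup:
            # deterministic fill: cycle the store with the warmup frames
            self._samples[self._frames_seen % self.n_samples] = frame8
            self._frames_seen += 1
            return np.zeros(frame.shape, dtype=np.uint8)

        diff = self._samples.astype(np.int16) - frame8.astype(np.int16)
        matches = (np.abs(diff) <= self._abs_radius).sum(axis=0)
        mask = np.where(matches >= self.k_required, np.uint8(0), np.uint8(255))

        # stochastic sample replacement at rate 1/history per pixel
        update = self._rng.random(frame.shape) < (1.0 / self.history)
        if update.any():
            slots = self._rng.integers(0, self.n_samples, size=frame.shape)
            rows, cols = np.nonzero(update)
            self._samples[slots[rows, cols], rows, cols] = frame8[rows, cols]
        self._frames_seen += 1
        return mask
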