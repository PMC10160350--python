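"""Lens-calibration model: loading, barrel-distortion correction, mm scaling.

The filming rig's short-focal-length lens introduces slight barrel
distortion.  A one-off checkerboard calibration (done externally, once per
mounted set-up) produces four plain-text files that together describe a
5-coefficient Brown-Conrady camera model:

``mtx.out``
    3x3 intrinsic matrix (fx, fy, cx, cy).
``dist.out``
    distortion coefficients (k1, k2, p1, p2, k3).
``newcameramtx.out``
    3x3 rectified intrinsic matrix used for the corrected image.
``roi.out``
    valid-pixel rectangle (x, y, w, h) of the corrected image.

This module reads/writes those files, applies the inverse distortion map to
frames, and converts pixel lengths to millimetres with a fixed scale factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "CameraModel",
    "ScaleFactor",
    "load_camera_model",
    "write_camera_model",
    "undistort",
    "distort_points",
    "undistort_points",
    "px_to_mm",
]

CALIBRATION_FILES = ("dist.out", "mtx.out", "newcameramtx.out", "roi.out")


class CalibrationError(ValueError):
    """Raised when lens-calibration files are missing or malformed."""


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera with Brown-Conrady distortion.

    Parameters
    ----------
    intrinsic : (3, 3) ndarray
        Focal lengths (fx, fy) and principal point (cx, cy), in pixels.
    distortion : (5,) ndarray
        Coefficients (k1, k2, p1, p2, k3); radial k*, tangential p*.
    rectified_intrinsic : (3, 3) ndarray
        Intrinsic matrix of the corrected (undistorted) image.
    roi : tuple of int
        (x, y, width, height) valid region of the corrected image,
        0-based, half-open.
    """

    intrinsic: np.ndarray
    distortion: np.ndarray
    rectified_intrinsic: np.ndarray
    roi: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        intr = np.asarray(self.intrinsic, dtype=float)
        dist = np.asarray(self.distortion, dtype=float).ravel()
        rect = np.asarray(self.rectified_intrinsic, dtype=float)
        if intr.shape != (3, 3) or rect.shape != (3, 3):
            raise CalibrationError("intrinsic matrices must be 3x3")
        if dist.shape != (5,):
            raise CalibrationError("distortion must have 5 coefficients")
        if not (np.isfinite(intr).all() and np.isfinite(dist).all() and np.isfinite(rect).all()):
            raise CalibrationError("camera model contains non-finite values")
        if intr[0, 0] <= 0 or intr[1, 1] <= 0:
            raise CalibrationError("focal lengths must be positive")
        x, y, w, h = (int(v) for v in self.roi)
        if x < 0 or y < 0 or w <= 0 or h <= 0:
            raise CalibrationError("roi must be a positive rectangle at non-negative offset")
        object.__setattr__(self, "intrinsic", intr)
        object.__setattr__(self, "distortion", dist)
        object.__setattr__(self, "rectified_intrinsic", rect)
        object.__setattr__(self, "roi", (x, y, w, h))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CameraModel):
            return NotImplemented
        return (
            np.allclose(self.intrinsic, other.intrinsic)
            and np.allclose(self.distortion, other.distortion)
            and np.allclose(self.rectified_intrinsic, other.rectified_intrinsic)
            and self.roi == other.roi
        )

    @classmethod
    def identity(cls, width: int, height: int) -> "CameraModel":
        """Distortion-free model spanning a width x height frame."""
        m = np.eye(3)
        m[0, 2] = width / 2.0
        m[1, 2] = height / 2.0
        m[0, 0] = m[1, 1] = max(width, height)
        return cls(m, np.zeros(5), m.copy(), (0, 0, width, height))


@dataclass(frozen=True)
class ScaleFactor:
    """Pixel-to-millimetre conversion, estimated once per mounted set-up."""

    mm_per_pixel: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mm_per_pixel) and self.mm_per_pixel > 0):
            raise ValueError("mm_per_pixel must be finite and > 0")


def _read_matrix(folder: Path, name: str) -> np.ndarray:
    path = folder / name
    if not path.is_file():
        raise CalibrationError(f"missing calibration file: {name!r} (looked in {folder})")
    try:
        values = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:
        raise CalibrationError(f"could not parse {name!r}: {exc}") from exc
    return values


def load_camera_model(folder: str | Path) -> CameraModel:
    """Load the four lens-calibration text files from *folder*.

    Raises :class:`CalibrationError` naming the offending file when one is
    missing or has the wrong shape.
    """
    folder = Path(folder)
    dist = _read_matrix(folder, "dist.out").ravel()
    mtx = _read_matrix(folder, "mtx.out")
    newmtx = _read_matrix(folder, "newcameramtx.out")
    roi = _read_matrix(folder, "roi.out").ravel()
    if dist.shape != (5,):
        raise CalibrationError(f"'dist.out' must hold 5 coefficients, got {dist.size}")
    if mtx.shape != (3, 3):
        raise CalibrationError(f"'mtx.out' must be 3x3, got {mtx.shape}")
    if newmtx.shape != (3, 3):
        raise CalibrationError(f"'newcameramtx.out' must be 3x3, got {newmtx.shape}")
    if roi.shape != (4,):
        raise CalibrationError(f"'roi.out' must hold 4 integers, got {roi.size}")
    return CameraModel(mtx, dist, newmtx, tuple(int(round(v)) for v in roi))


def write_camera_model(model: CameraModel, folder: str | Path) -> None:
    """Write *model* as the four whitespace-delimited text files."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    np.savetxt(folder / "dist.out", model.distortion[None, :], fmt="%.12g")
    np.savetxt(folder / "mtx.out", model.intrinsic, fmt="%.12g")
    np.savetxt(folder / "newcameramtx.out", model.rectified_intrinsic, fmt="%.12g")
    np.savetxt(folder / "roi.out", np.asarray(model.roi, dtype=float)[None, :], fmt="%d")


def distort_points(points: np.ndarray, model: CameraModel) -> np.ndarray:
    """Map ideal (undistorted) pixel coordinates to distorted pixels.

    *points* is (N, 2) in (x, y) order, expressed in the rectified image;
    returns (N, 2) coordinates in the raw (distorted) image.
    """
    pts = np.asarray(points, dtype=float)
    rect = model.rectified_intrinsic
    x = (pts[:, 0] - rect[0, 2]) / rect[0, 0]
    y = (pts[:, 1] - rect[1, 2]) / rect[1, 1]
    k1, k2, p1, p2, k3 = model.distortion
    r2 = x * x + y * y
    radial = 1.0 + k1 * r2 + k2 * r2 * r2 + k3 * r2 * r2 * r2
    xd = x * radial + 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
    yd = y * radial + p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
    intr = model.intrinsic
    out = np.empty_like(pts)
    out[:, 0] = intr[0, 0] * xd + intr[0, 2]
    out[:, 1] = intr[1, 1] * yd + intr[1, 2]
    return out


def undistort_points(points: np.ndarray, model: CameraModel, iters: int = 20) -> np.ndarray:
    """Invert the distortion map (raw pixels -> ideal pixels) by fixed-point
    iteration; converges quickly for the mild barrel distortion of this rig
    (|k1| well below 1)."""
    pts = np.asarray(points, dtype=float)
    intr = model.intrinsic
    xd = (pts[:, 0] - intr[0, 2]) / intr[0, 0]
    yd = (pts[:, 1] - intr[1, 2]) / intr[1, 1]
    k1, k2, p1, p2, k3 = model.distortion
    x, y = xd.copy(), yd.copy()
    for _ in range(iters):
        r2 = x * x + y * y
        radial = 1.0 + k1 * r2 + k2 * r2 * r2 + k3 * r2 * r2 * r2
        dx = 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
        dy = p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
        x = (xd - dx) / radial
        y = (yd - dy) / radial
    rect = model.rectified_intrinsic
    out = np.empty_like(pts)
    out[:, 0] = rect[0, 0] * x + rect[0, 2]
    out[:, 1] = rect[1, 1] * y + rect[1, 2]
    return out


def undistort(frame: np.ndarray, model: CameraModel, crop_roi: bool = False) -> np.ndarray:
    """Correct barrel distortion of a single grayscale frame.

    For each output pixel the corresponding raw-frame position is found by
    pushing the rectified coordinate through the Brown-Conrady polynomial,
    then the raw frame is sampled bilinearly; positions falling outside the
    raw frame read as 0 (safe on a dark-field background).
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("undistort expects a 2D grayscale frame")
    h, w = frame.shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel().astype(float), yy.ravel().astype(float)])
    src = distort_points(pts, model)
    coords = np.vstack([src[:, 1], src[:, 0]]).reshape(2, h, w)
    out = ndimage.map_coordinates(
        frame.astype(float), coords, order=1, mode="constant", cval=0.0
    )
    if np.issubdtype(frame.dtype, np.integer):
        info = np.iinfo(frame.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(frame.dtype)
    else:
        out = out.astype(frame.dtype)
    if crop_roi:
        x, y, rw, rh = model.roi
        out = out[y : y + rh, x : x + rw]
    return out


def px_to_mm(length_px: float | np.ndarray, scale: ScaleFactor) -> float | np.ndarray:
    """Convert a pixel length to millimetres (strictly linear)."""
    arr = np.asarray(length_px, dtype=float)
    if np.any(arr < 0):
        raise ValueError("pixel lengths must be non-negative")
    out = arr * scale.mm_per_pixel
    return float(out) if np.isscalar(length_px) or out.ndim == 0 else out
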