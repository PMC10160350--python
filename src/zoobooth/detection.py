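"""Object detection and species-specific frame filtering.

From a cleaned binary mask and its grayscale frame: find candidate objects,
pick the largest, fit an ellipse (major axis = body length, minor = width),
measure brightness/position, and accept or reject the frame against a
species profile.  Rejections carry the first failed criterion so every
decision is auditable from the per-frame record alone.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from skimage import measure

__all__ = [
    "SpeciesProfile",
    "ObjectMeasurement",
    "Contour",
    "EllipseFitError",
    "find_contours",
    "select_largest",
    "fit_ellipse",
    "measure_object",
    "apply_species_filter",
    "load_species_profiles",
    "default_profile",
]

#: evaluation order of the acceptance criteria (reject reports the first hit)
CRITERIA = ("area", "lw_ratio", "brightness", "sharpness", "edge")


@dataclass(frozen=True)
class SpeciesProfile:
    """Frame-acceptance thresholds for one taxon.

    Areas are contour pixel areas; the length/width ratio is the fitted
    ellipse's major/minor axis ratio; brightness is the mean 8-bit grayscale
    inside the object; edge distance is from the object centre to the
    nearest cuvette-crop boundary.  ``optimal_percentile`` is the calibrated
    percentile of the per-video length distribution used as the estimate.
    """

    name: str
    min_area_px: float
    max_area_px: float
    min_lw_ratio: float
    max_lw_ratio: float
    min_brightness: float
    min_sharpness: float = 1.8
    min_edge_distance_px: float = 10.0
    optimal_percentile: int = 93

    def __post_init__(self) -> None:
        if not (self.min_area_px < self.max_area_px):
            raise ValueError("min_area_px must be < max_area_px")
        if not (1.0 <= self.min_lw_ratio <= self.max_lw_ratio):
            raise ValueError("need 1 <= min_lw_ratio <= max_lw_ratio")
        if not (50 <= self.optimal_percentile <= 100):
            raise ValueError("optimal_percentile must lie in [50, 100]")

    def replace(self, **kwargs) -> "SpeciesProfile":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


@dataclass(frozen=True)
class ObjectMeasurement:
    """Per-frame measurement of the detected object."""

    frame_index: int
    major_axis_px: float
    minor_axis_px: float
    orientation_deg: float
    area_px: float
    brightness: float
    sharpness: float
    center_x: float
    center_y: float
    edge_distance_px: float

    def __post_init__(self) -> None:
        if not (self.major_axis_px >= self.minor_axis_px > 0):
            raise ValueError("need major >= minor > 0")
        if not (0 <= self.brightness <= 255):
            raise ValueError("brightness must lie in [0, 255]")
        if self.area_px <= 0:
            raise ValueError("area must be positive")

    @property
    def lw_ratio(self) -> float:
        return self.major_axis_px / self.minor_axis_px


@dataclass(frozen=True)
class Contour:
    """One detected object: closed boundary polygon plus component pixels."""

    points: np.ndarray  # (N, 2) boundary vertices, (x, y), closed
    pixel_coords: tuple[np.ndarray, np.ndarray]  # (rows, cols) of the component

    @property
    def area_px(self) -> int:
        """Object area as component pixel count (matches px thresholds)."""
        return int(self.pixel_coords[0].size)


class EllipseFitError(ValueError):
    """Signals a frame whose object boundary cannot support an ellipse fit."""


def find_contours(mask: np.ndarray) -> list[Contour]:
    """External boundaries of all 8-connected foreground components.

    Components are returned in top-left-first scan order; holes are ignored
    (only the outer boundary is traced).  An empty mask yields ``[]``.
    """
    binary = np.asarray(mask) > 0
    labels, n = measure.label(binary, connectivity=2, return_num=True)
    contours: list[Contour] = []
    for lab in range(1, n + 1):
        component = labels == lab
        rows, cols = np.nonzero(component)
        # pad so boundary tracing closes around border-touching components
        r0, r1 = rows.min(), rows.max()
        c0, c1 = cols.min(), cols.max()
        sub = np.zeros((r1 - r0 + 3, c1 - c0 + 3), dtype=float)
        sub[1:-1, 1:-1] = component[r0 : r1 + 1, c0 : c1 + 1]
        traced = measure.find_contours(sub, 0.5, fully_connected="high")
        if not traced:
            continue
        boundary = max(traced, key=len)  # outer boundary is the longest
        pts = np.empty_like(boundary)
        pts[:, 0] = boundary[:, 1] + c0 - 1  # x
        pts[:, 1] = boundary[:, 0] + r0 - 1  # y
        contours.append(Contour(points=pts, pixel_coords=(rows, cols)))
    return contours


def select_largest(contours: list[Contour]) -> Contour | None:
    """Contour with maximal pixel area; ties go to the earliest in scan
    order.  ``None`` for an empty list."""
    best: Contour | None = None
    for c in contours:
        if best is None or c.area_px > best.area_px:
            best = c
    return best


def fit_ellipse(contour: Contour) -> tuple[float, float, float, tuple[float, float]]:
    """Direct least-squares ellipse fit to the boundary polygon.

    Returns ``(major_axis, minor_axis, orientation_deg, (cx, cy))`` with
    full axis lengths (2a >= 2b) and the major-axis orientation in degrees
    in [0, 180).  Raises :class:`EllipseFitError` on degenerate boundaries
    (fewer than 5 points or collinear).
    """
    pts = np.asarray(contour.points, dtype=float)
    if len(pts) < 5:
        raise EllipseFitError("need at least 5 boundary points")
    model = measure.EllipseModel.from_estimate(pts)
    if not model:
        raise EllipseFitError("degenerate boundary: ellipse fit failed")
    xc, yc = model.center
    a, b = model.axis_lengths  # major first
    if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
        raise EllipseFitError("degenerate ellipse axes")
    orientation = float(np.degrees(model.theta) % 180.0)
    return 2.0 * a, 2.0 * b, orientation, (float(xc), float(yc))


def measure_object(
    contour: Contour,
    gray_frame: np.ndarray,
    crop_box: tuple[int, int, int, int],
    frame_index: int = 0,
    frame_sharpness: float | None = None,
) -> ObjectMeasurement:
    """Measure the detected object on the (undistorted) grayscale frame.

    Brightness is the mean intensity over the object's own pixels (the mask
    only locates the animal; intensities come from the image itself).  Edge
    distance is from the fitted-ellipse centre to the nearest edge of the
    cuvette crop rectangle ``(x, y, w, h)``, in crop-local coordinates.
    """
    rows, cols = contour.pixel_coords
    if rows.size == 0:
        raise EllipseFitError("object has no interior pixels")
    major, minor, orientation, (cx, cy) = fit_ellipse(contour)
    brightness = float(np.asarray(gray_frame, dtype=float)[rows, cols].mean())
    _, _, w, h = crop_box
    edge_distance = float(min(cx, w - cx, cy, h - cy))
    if frame_sharpness is None:
        from .segmentation import sharpness as _sharpness

        frame_sharpness = _sharpness(gray_frame)
    return ObjectMeasurement(
        frame_index=frame_index,
        major_axis_px=major,
        minor_axis_px=minor,
        orientation_deg=orientation,
        area_px=float(contour.area_px),
        brightness=brightness,
        sharpness=float(frame_sharpness),
        center_x=cx,
        center_y=cy,
        edge_distance_px=edge_distance,
    )


def apply_species_filter(m: ObjectMeasurement, p: SpeciesProfile) -> str | None:
    """Test a measurement against the five acceptance criteria in order:
    area, length/width ratio, brightness, sharpness, edge distance.

    Returns ``None`` on acceptance, else the name of the first failed
    criterion.
    """
    if not (p.min_area_px <= m.area_px <= p.max_area_px):
        return "area"
    if not (p.min_lw_ratio <= m.lw_ratio <= p.max_lw_ratio):
        return "lw_ratio"
    if m.brightness < p.min_brightness:
        return "brightness"
    if m.sharpness < p.min_sharpness:
        return "sharpness"
    if m.edge_distance_px < p.min_edge_distance_px:
        return "edge"
    return None


def load_species_profiles(path: str | Path | None = None) -> dict[str, SpeciesProfile]:
    """Load species profiles from YAML (the packaged table by default)."""
    if path is None:
        source = importlib.resources.files("zoobooth.data").joinpath("species.yaml")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    return {name: SpeciesProfile(name=name, **params) for name, params in raw.items()}


def default_profile() -> SpeciesProfile:
    """The Daphnia profile, used when no species is chosen."""
    return load_species_profiles()["daphnia"]
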