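"""Ground-truthed synthetic scenes of a swimming zooplankter.

The generator emulates the filming geometry of the dark-field booth: a
bright, roughly ellipsoidal animal (a prolate spheroid with semi-axes
a >= b) swims and rotates freely inside a cuvette crop region against a
dark background, with drifting particle specks, optional thin appendages
(spine/antennae analogue), Gaussian optics blur and sensor noise.

The body's orientation performs a random walk on the unit sphere.  Under
orthographic projection the silhouette is an ellipse with

    projected major axis = 2 * sqrt(a^2 cos^2(theta) + b^2 sin^2(theta)),

where theta is the angle between the long axis and the image plane; the
projection can only undershoot the true length 2a, which is exactly why a
high percentile — not the mean or median — of the per-frame lengths is the
right size estimator.  Every video ships with a per-frame truth table so
the whole pipeline can be validated against known lengths.

Orthographic projection is an approximation: the cuvette is shallow
relative to the optical path, so perspective size change is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .camera import CameraModel, undistort_points

__all__ = [
    "SceneConfig",
    "GroundTruthRecord",
    "projected_axis",
    "render_frames",
    "render_video",
    "apply_lens_distortion",
    "make_calibration_cohort",
]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic clip.

    Geometry defaults follow the recording set-up: 1080x768-px frames,
    26 fps, 30-s clips.  Intensities are 8-bit; the body is bright on a
    dark background (dark-field illumination).
    """

    frame_size: tuple[int, int] = (1080, 768)  # (width, height)
    crop_box: tuple[int, int, int, int] = (190, 84, 700, 600)  # cuvette inner area
    n_frames: int = 780
    semi_major_px: float = 60.0  # a
    semi_minor_px: float = 42.0  # b
    body_intensity: float = 200.0
    body_intensity_sd: float = 8.0
    background_intensity: float = 10.0
    n_particles: int = 25
    particle_radius_px: float = 1.2
    particle_intensity: float = 80.0
    appendage: bool = False
    appendage_length_px: float = 30.0
    appendage_width_px: float = 2.0
    drift_sd_px: float = 2.5  # random acceleration sd, px/frame^2
    velocity_persistence: float = 0.9  # directed-swimming memory per frame
    angular_sd_deg: float = 8.0
    blur_sd_px: float = 0.8
    noise_sd: float = 2.5
    mm_per_pixel: float = 0.02
    distortion: CameraModel | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.semi_major_px >= self.semi_minor_px > 0):
            raise ValueError("need semi-axes a >= b > 0")
        if self.body_intensity <= self.background_intensity:
            raise ValueError("body must be brighter than the background")
        x, y, w, h = self.crop_box
        fw, fh = self.frame_size
        if x < 0 or y < 0 or x + w > fw or y + h > fh:
            raise ValueError("crop box must lie within the frame")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


@dataclass(frozen=True)
class GroundTruthRecord:
    """Per-frame truth for one synthetic frame."""

    frame_index: int
    theta_rad: float  # angle between long axis and image plane
    phi_rad: float  # in-plane orientation of the projected major axis
    projected_major_px: float
    projected_minor_px: float
    center_x: float
    center_y: float
    true_length_px: float
    true_length_mm: float


def projected_axis(a: float, b: float, theta: float) -> float:
    """Silhouette major axis of a prolate spheroid tilted by *theta* out of
    the image plane: 2*sqrt(a^2 cos^2(theta) + b^2 sin^2(theta))."""
    c, s = np.cos(theta), np.sin(theta)
    return 2.0 * float(np.sqrt(a * a * c * c + b * b * s * s))


def _rasterize_ellipse(
    canvas: np.ndarray, cx: float, cy: float, sa: float, sb: float, phi: float, value: np.ndarray | float
) -> None:
    """Paint a filled rotated ellipse (semi-axes sa, sb at angle phi) onto
    *canvas* in place, touching only its bounding box."""
    h, w = canvas.shape
    r = max(sa, sb) + 2
    x0, x1 = max(0, int(cx - r)), min(w, int(cx + r) + 1)
    y0, y1 = max(0, int(cy - r)), min(h, int(cy + r) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    c, s = np.cos(phi), np.sin(phi)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    inside = (u / sa) ** 2 + (v / sb) ** 2 <= 1.0
    region = canvas[y0:y1, x0:x1]
    region[inside] = np.broadcast_to(value, region.shape)[inside] if np.ndim(value) else value


def _rasterize_segment(
    canvas: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    half_width: float,
    value: float,
) -> None:
    """Paint a thick line segment (a thin rectangle) onto *canvas*."""
    h, w = canvas.shape
    x0 = max(0, int(min(p0[0], p1[0]) - half_width - 1))
    x1 = min(w, int(max(p0[0], p1[0]) + half_width + 2))
    y0 = max(0, int(min(p0[1], p1[1]) - half_width - 1))
    y1 = min(h, int(max(p0[1], p1[1]) + half_width + 2))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    seg_len2 = dx * dx + dy * dy
    if seg_len2 == 0:
        return
    t = np.clip(((xx - p0[0]) * dx + (yy - p0[1]) * dy) / seg_len2, 0.0, 1.0)
    dist2 = (xx - (p0[0] + t * dx)) ** 2 + (yy - (p0[1] + t * dy)) ** 2
    canvas[y0:y1, x0:x1][dist2 <= half_width**2] = value


def apply_lens_distortion(frame: np.ndarray, model: CameraModel) -> np.ndarray:
    """Warp an ideal frame into what the distorting lens would capture, so
    that :func:`zoobooth.camera.undistort` recovers the ideal frame."""
    h, w = frame.shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel().astype(float), yy.ravel().astype(float)])
    ideal = undistort_points(pts, model)
    coords = np.vstack([ideal[:, 1], ideal[:, 0]]).reshape(2, h, w)
    out = ndimage.map_coordinates(frame.astype(float), coords, order=1, mode="constant", cval=0.0)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def render_frames(cfg: SceneConfig):
    """Yield ``(frame_uint8, GroundTruthRecord)`` per frame.

    Orientation is a seeded random walk of the body's long-axis direction on
    the unit sphere; the centre drifts with reflection at the crop walls
    (inset by the body radius so the animal never clips the boundary).
    """
    rng = np.random.default_rng(cfg.seed)
    fw, fh = cfg.frame_size
    cx0, cy0, cw, ch = cfg.crop_box
    a, b = cfg.semi_major_px, cfg.semi_minor_px

    margin = a + 12.0  # keep the whole body (and edge criterion) inside
    lo_x, hi_x = cx0 + margin, cx0 + cw - margin
    lo_y, hi_y = cy0 + margin, cy0 + ch - margin
    if lo_x >= hi_x or lo_y >= hi_y:
        raise ValueError("crop box too small for the body size")
    center = np.array(
        [rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)], dtype=float
    )
    # persistent-velocity swimming (directed bursts, not pure diffusion), so
    # the animal clears its own footprint and the background model stays clean
    p = cfg.velocity_persistence
    vel_rms = cfg.drift_sd_px / max(np.sqrt(1.0 - p * p), 1e-6)
    velocity = rng.normal(scale=vel_rms, size=2)

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang_sd = np.deg2rad(cfg.angular_sd_deg)

    particles = np.column_stack(
        [rng.uniform(cx0, cx0 + cw, cfg.n_particles), rng.uniform(cy0, cy0 + ch, cfg.n_particles)]
    )

    def reflect(v: float, lo: float, hi: float) -> float:
        span = hi - lo
        if span <= 0:
            return lo
        t = (v - lo) % (2 * span)
        return lo + (t if t <= span else 2 * span - t)

    for i in range(cfg.n_frames):
        canvas = np.full((fh, fw), cfg.background_intensity, dtype=float)

        # drifting particle specks
        particles += rng.normal(scale=1.0, size=particles.shape)
        particles[:, 0] = np.clip(particles[:, 0], cx0, cx0 + cw - 1)
        particles[:, 1] = np.clip(particles[:, 1], cy0, cy0 + ch - 1)
        for px, py in particles:
            _rasterize_ellipse(
                canvas, px, py, cfg.particle_radius_px, cfg.particle_radius_px, 0.0,
                cfg.particle_intensity,
            )

        theta = float(np.arcsin(abs(axis[2])))
        phi = float(np.arctan2(axis[1], axis[0]))
        proj_major = projected_axis(a, b, theta)
        proj_minor = 2.0 * b
        body_val = cfg.body_intensity + rng.normal(scale=cfg.body_intensity_sd)
        _rasterize_ellipse(
            canvas, center[0], center[1], proj_major / 2.0, b, phi, body_val
        )
        if cfg.appendage:
            app_len = cfg.appendage_length_px * abs(np.cos(theta))
            tip = (
                center[0] + np.cos(phi) * proj_major / 2.0,
                center[1] + np.sin(phi) * proj_major / 2.0,
            )
            end = (tip[0] + np.cos(phi) * app_len, tip[1] + np.sin(phi) * app_len)
            _rasterize_segment(canvas, tip, end, cfg.appendage_width_px / 2.0, body_val)

        if cfg.blur_sd_px > 0:
            canvas = ndimage.gaussian_filter(canvas, cfg.blur_sd_px)
        if cfg.noise_sd > 0:
            canvas = canvas + rng.normal(scale=cfg.noise_sd, size=canvas.shape)
        frame = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
        if cfg.distortion is not None:
            frame = apply_lens_distortion(frame, cfg.distortion)

        yield frame, GroundTruthRecord(
            frame_index=i,
            theta_rad=theta,
            phi_rad=phi,
            projected_major_px=proj_major,
            projected_minor_px=proj_minor,
            center_x=float(center[0]),
            center_y=float(center[1]),
            true_length_px=2.0 * a,
            true_length_mm=2.0 * a * cfg.mm_per_pixel,
        )

        # advance motion state for the next frame
        velocity = p * velocity + rng.normal(scale=cfg.drift_sd_px, size=2)
        nxt = center + velocity
        for k, (lo, hi) in enumerate(((lo_x, hi_x), (lo_y, hi_y))):
            if nxt[k] < lo or nxt[k] > hi:
                velocity[k] = -velocity[k]
            nxt[k] = reflect(nxt[k], lo, hi)
        center = nxt
        axis = axis + rng.normal(scale=ang_sd, size=3)
        axis /= np.linalg.norm(axis)


def render_video(cfg: SceneConfig, out_path: str | Path) -> tuple[Path, pd.DataFrame]:
    """Render a clip to a lossless multi-page TIFF plus a truth CSV.

    Returns the video path and the truth table (also written next to the
    video as ``<stem>.truth.csv``).
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    frames: list[np.ndarray] = []
    records: list[GroundTruthRecord] = []
    for frame, rec in render_frames(cfg):
        frames.append(frame)
        records.append(rec)
    tifffile.imwrite(
        out_path, np.stack(frames), photometric="minisblack", compression="zlib"
    )
    truth = pd.DataFrame([r.__dict__ for r in records])
    truth_path = out_path.with_suffix("").with_suffix(".truth.csv")
    truth.to_csv(truth_path, index=False)
    return out_path, truth


def make_calibration_cohort(
    n_individuals: int,
    length_range_mm: tuple[float, float],
    template: SceneConfig,
    seed: int,
    out_dir: str | Path,
    manual_noise_sd_mm: float = 0.02,
    lw_ratio: float = 1.45,
) -> pd.DataFrame:
    """Render a cohort of clips with true lengths drawn uniformly in
    *length_range_mm* and emit a paired "manual" measurement table
    (truth plus Gaussian measurement noise, default sigma 0.02 mm).

    Returns a table with columns ``video_name, path, true_mm, manual_mm``;
    the same table is written to ``out_dir/manual_measurements.csv``.
    """
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_individuals):
        true_mm = float(rng.uniform(*length_range_mm))
        a = true_mm / (2.0 * template.mm_per_pixel)
        cfg = replace(
            template,
            semi_major_px=a,
            semi_minor_px=a / lw_ratio,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        name = f"sim{i:03d}_L{true_mm:.3f}mm"
        path, _ = render_video(cfg, out_dir / f"{name}.tiff")
        manual = true_mm + (
            float(rng.normal(scale=manual_noise_sd_mm)) if manual_noise_sd_mm > 0 else 0.0
        )
        rows.append(
            {"video_name": name, "path": str(path), "true_mm": true_mm, "manual_mm": manual}
        )
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "manual_measurements.csv", index=False)
    return table
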