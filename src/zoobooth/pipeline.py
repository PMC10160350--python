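"""Batch measurement pipeline.

Per frame the stages run in a fixed order: crop to the cuvette's inner area,
undistort with the stored camera model, convert to grayscale, score
sharpness, subtract the adaptive background, erode, dilate, find contours,
select the largest object, measure it, filter against the species profile,
and convert accepted lengths to millimetres.  Per video the accepted
lengths form a distribution whose calibrated percentile is the size
estimate.  Videos in a folder are processed independently in sorted order
and appended to one detailed and one summary CSV per run.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import video_io
from .camera import CameraModel, ScaleFactor, load_camera_model, undistort
from .detection import (
    EllipseFitError,
    SpeciesProfile,
    apply_species_filter,
    default_profile,
    find_contours,
    load_species_profiles,
    measure_object,
    select_largest,
)
from .segmentation import BackgroundModel, StructuringElement, dilate, erode, sharpness
from .sizing import SizeDistribution, SummarySizeRow, summarize_video
from .video_io import DetailedSizeRow

__all__ = ["RunConfig", "VideoResult", "process_video", "process_folder"]

logger = logging.getLogger("zoobooth")

#: canonical per-frame stage order (instrumented runs record and check it)
STAGE_ORDER = (
    "crop",
    "undistort",
    "grayscale",
    "sharpness",
    "background_subtraction",
    "erode",
    "dilate",
    "find_contours",
    "select_largest",
    "measure",
    "filter",
    "convert_mm",
)

VIDEO_EXTENSIONS = (".tif", ".tiff", ".npy", ".mp4", ".h264", ".avi")


@dataclass
class RunConfig:
    """Everything a batch run needs."""

    species: str = "daphnia"
    input_dir: Path | None = None
    output_dir: Path = Path(".")
    suffix: str = ""
    mm_per_pixel: float = 0.02
    crop_box: tuple[int, int, int, int] | None = None  # (x, y, w, h); None = full frame
    camera: CameraModel | None = None
    lenscalibration_dir: Path | None = None
    species_yaml: Path | None = None
    min_support: int = 10
    seed: int = 0
    save_snapshots: bool = True
    width_in_summary: bool = False
    box_level_sharpness: bool = False
    background: dict = field(default_factory=dict)  # BackgroundModel overrides
    morphology_size: tuple[int, int] = (3, 3)
    erode_iterations: int = 3
    dilate_iterations: int = 3

    def resolve_profile(self) -> SpeciesProfile:
        profiles = load_species_profiles(self.species_yaml)
        if self.species in profiles:
            return profiles[self.species]
        logger.warning("species %r not found; falling back to the Daphnia defaults", self.species)
        return default_profile()

    def resolve_camera(self) -> CameraModel | None:
        if self.camera is not None:
            return self.camera
        if self.lenscalibration_dir is not None:
            return load_camera_model(self.lenscalibration_dir)
        return None


@dataclass
class VideoResult:
    """Everything measured from one clip."""

    video_name: str
    detailed_rows: list[DetailedSizeRow]
    summary: SummarySizeRow
    snapshots: list
    reject_counts: dict[str, int]
    stage_trace: tuple[str, ...] = ()

    @property
    def distribution(self) -> SizeDistribution:
        return SizeDistribution(
            video_name=self.video_name,
            lengths_mm=tuple(r.length_mm for r in self.detailed_rows),
        )


def _is_identity_model(model: CameraModel) -> bool:
    return bool(
        np.all(model.distortion == 0)
        and np.allclose(model.intrinsic, model.rectified_intrinsic)
    )


def process_video(
    path: str | Path,
    cfg: RunConfig,
    profile: SpeciesProfile | None = None,
    camera: CameraModel | None = None,
) -> VideoResult:
    """Run the full measurement pipeline on one clip."""
    path = Path(path)
    profile = profile or cfg.resolve_profile()
    camera = camera if camera is not None else cfg.resolve_camera()
    scale = ScaleFactor(cfg.mm_per_pixel)
    meta = video_io.parse_filename(path)

    bg = BackgroundModel(seed=cfg.seed, **cfg.background)
    se = StructuringElement(size=cfg.morphology_size, iterations=1)
    se_erode = StructuringElement(size=cfg.morphology_size, iterations=cfg.erode_iterations)
    se_dilate = StructuringElement(size=cfg.morphology_size, iterations=cfg.dilate_iterations)
    del se

    skip_undistort = camera is None or _is_identity_model(camera)

    detailed: list[DetailedSizeRow] = []
    snapshots: list[tuple[np.ndarray, object]] = []
    reject_counts: dict[str, int] = {}
    stage_trace: list[str] = []
    t0 = time.perf_counter()

    for frame_index, frame in video_io.iter_frames(path, grayscale=False):
        trace = frame_index == 0  # record stage order once per video

        # crop to the cuvette inner area (raw-frame coordinates)
        if cfg.crop_box is not None:
            x, y, w, h = cfg.crop_box
            frame = frame[y : y + h, x : x + w]
            crop_box = (0, 0, w, h)
        else:
            crop_box = (0, 0, frame.shape[-1] if frame.ndim == 2 else frame.shape[1], frame.shape[0])
        if trace:
            stage_trace.append("crop")

        gray_for_undistort = frame
        if not skip_undistort:
            if frame.ndim == 3:
                frame = video_io.to_grayscale(frame)
                gray_for_undistort = frame
            frame = undistort(gray_for_undistort, camera)
        if trace:
            stage_trace.append("undistort")

        gray = video_io.to_grayscale(frame)
        if trace:
            stage_trace.append("grayscale")

        frame_sharp = sharpness(gray)
        if trace:
            stage_trace.append("sharpness")

        mask = bg.apply(gray)
        if trace:
            stage_trace.append("background_subtraction")

        mask = erode(mask, se_erode)
        if trace:
            stage_trace.append("erode")
        mask = dilate(mask, se_dilate)
        if trace:
            stage_trace.append("dilate")

        contours = find_contours(mask)
        if trace:
            stage_trace.append("find_contours")
        largest = select_largest(contours)
        if trace:
            stage_trace.extend(["select_largest", "measure", "filter", "convert_mm"])
        if largest is None:
            continue

        try:
            m = measure_object(
                largest,
                gray,
                crop_box,
                frame_index=frame_index,
                frame_sharpness=None if cfg.box_level_sharpness else frame_sharp,
            )
        except EllipseFitError as exc:
            logger.debug("%s frame %d: %s", meta.video_name, frame_index, exc)
            continue
        if cfg.box_level_sharpness:
            r0 = max(0, int(m.center_y - m.major_axis_px / 2))
            r1 = int(m.center_y + m.major_axis_px / 2) + 1
            c0 = max(0, int(m.center_x - m.major_axis_px / 2))
            c1 = int(m.center_x + m.major_axis_px / 2) + 1
            box = gray[r0:r1, c0:c1]
            if box.size:
                from dataclasses import replace as _replace

                m = _replace(m, sharpness=sharpness(box))

        reason = apply_species_filter(m, profile)
        if reason is not None:
            reject_counts[reason] = reject_counts.get(reason, 0) + 1
            logger.debug("%s frame %d rejected: %s", meta.video_name, frame_index, reason)
            continue

        detailed.append(DetailedSizeRow.from_measurement(meta.video_name, m, scale.mm_per_pixel))
        if len(snapshots) < video_io.SNAPSHOT_LIMIT:
            snapshots.append((gray.copy(), m))

    dist = SizeDistribution(
        video_name=meta.video_name, lengths_mm=tuple(r.length_mm for r in detailed)
    )
    widths = [r.width_mm for r in detailed]
    summary = summarize_video(
        dist,
        profile,
        min_support=cfg.min_support,
        include_width=cfg.width_in_summary,
        widths_mm=widths,
    )
    logger.info(
        "%s: %d accepted frames, estimate %s mm (%.1f s)",
        meta.video_name,
        dist.n_frames,
        f"{summary.length_mm:.3f}" if summary.length_mm is not None else "n/a",
        time.perf_counter() - t0,
    )
    return VideoResult(
        video_name=meta.video_name,
        detailed_rows=detailed,
        summary=summary,
        snapshots=snapshots,
        reject_counts=reject_counts,
        stage_trace=tuple(stage_trace),
    )


def process_folder(cfg: RunConfig) -> list[VideoResult]:
    """Process every video in ``cfg.input_dir`` in sorted order, appending
    to one detailed and one summary CSV (suffix honoured) and saving
    snapshot PNGs per video.  Unreadable videos are logged and skipped."""
    if cfg.input_dir is None or not Path(cfg.input_dir).is_dir():
        raise NotADirectoryError(f"input folder not found: {cfg.input_dir}")
    videos = sorted(
        p for p in Path(cfg.input_dir).iterdir() if p.suffix.lower() in VIDEO_EXTENSIONS
    )
    if not videos:
        logger.warning("no videos found in %s", cfg.input_dir)

    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = f".{cfg.suffix}" if cfg.suffix else ""
    detailed_path = out_dir / f"{tag.lstrip('.') or 'results'}.detailedsizedata.csv"
    summary_path = out_dir / f"{tag.lstrip('.') or 'results'}.sizedata.csv"

    profile = cfg.resolve_profile()
    camera = cfg.resolve_camera()
    results: list[VideoResult] = []
    for video in videos:
        try:
            res = process_video(video, cfg, profile=profile, camera=camera)
        except (IOError, ValueError) as exc:
            logger.error("skipping %s: %s", video, exc)
            continue
        video_io.write_detailed(res.detailed_rows, detailed_path)
        video_io.write_summary([res.summary], summary_path)
        if cfg.save_snapshots:
            video_io.save_snapshots(res.snapshots, out_dir / "snapshots", res.video_name)
        results.append(res)
    return results
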