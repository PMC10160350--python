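"""Video decoding, filename metadata, result CSVs and diagnostic snapshots.

Clips are one individual per video.  Identifying information (individual ID,
treatment, age, ...) is embedded in the filename as underscore-separated
tokens and travels with every output row.  Two result files are written per
run: a per-frame record (``*.detailedsizedata.csv``) and a one-row-per-video
summary (``*sizedata.csv``).  The first 19 accepted frames are additionally
saved as annotated PNGs so estimates can be validated by eye.

Supported containers: multi-page TIFF and ``.npy`` frame stacks are decoded
natively (lossless, reproducible — the formats the synthetic generator
emits); anything else (MP4/h264/AVI) is handed to :mod:`imageio`, which
requires an ffmpeg plugin for those formats.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage.draw import ellipse_perimeter

from .detection import ObjectMeasurement
from .sizing import SummarySizeRow

__all__ = [
    "VideoMeta",
    "DetailedSizeRow",
    "iter_frames",
    "count_frames",
    "to_grayscale",
    "parse_filename",
    "build_filename",
    "write_detailed",
    "write_summary",
    "read_detailed",
    "read_summary",
    "save_snapshots",
    "SNAPSHOT_LIMIT",
]

SNAPSHOT_LIMIT = 19

DETAILED_COLUMNS = [
    "video_name",
    "frame_index",
    "length_px",
    "width_px",
    "length_mm",
    "width_mm",
    "area_px",
    "brightness",
    "sharpness",
    "center_x",
    "center_y",
]

SUMMARY_COLUMNS = [
    "video_name",
    "species",
    "percentile_used",
    "length_mm",
    "n_frames",
    "width_mm",
    "low_support",
]


@dataclass(frozen=True)
class VideoMeta:
    """Identity and geometry of one clip, parsed from its filename."""

    path: Path
    tokens: tuple[str, ...]
    frame_count: int = 0
    width: int = 0
    height: int = 0

    @property
    def video_name(self) -> str:
        return self.path.stem


@dataclass(frozen=True)
class DetailedSizeRow:
    """One accepted frame's measurements, as written to the detailed CSV."""

    video_name: str
    frame_index: int
    length_px: float
    width_px: float
    length_mm: float
    width_mm: float
    area_px: float
    brightness: float
    sharpness: float
    center_x: float
    center_y: float

    def __post_init__(self) -> None:
        if not (self.length_px >= self.width_px > 0):
            raise ValueError("need length >= width > 0")
        if self.area_px <= 0:
            raise ValueError("area must be positive")

    @classmethod
    def from_measurement(
        cls, video_name: str, m: ObjectMeasurement, mm_per_pixel: float
    ) -> "DetailedSizeRow":
        return cls(
            video_name=video_name,
            frame_index=m.frame_index,
            length_px=m.major_axis_px,
            width_px=m.minor_axis_px,
            length_mm=m.major_axis_px * mm_per_pixel,
            width_mm=m.minor_axis_px * mm_per_pixel,
            area_px=m.area_px,
            brightness=m.brightness,
            sharpness=m.sharpness,
            center_x=m.center_x,
            center_y=m.center_y,
        )


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an RGB(A) frame to 8-bit grayscale by luminance weighting
    0.299 R + 0.587 G + 0.114 B, rounded to the nearest integer.  2D frames
    pass through unchanged (cast to uint8)."""
    arr = np.asarray(frame)
    if arr.ndim == 2:
        return arr.astype(np.uint8, copy=False)
    if arr.ndim == 3 and arr.shape[2] >= 3:
        lum = (
            0.299 * arr[..., 0].astype(float)
            + 0.587 * arr[..., 1].astype(float)
            + 0.114 * arr[..., 2].astype(float)
        )
        return np.clip(np.rint(lum), 0, 255).astype(np.uint8)
    raise ValueError(f"cannot convert frame of shape {arr.shape} to grayscale")


def iter_frames(path: str | Path, grayscale: bool = True) -> Iterator[tuple[int, np.ndarray]]:
    """Yield ``(frame_index, frame)`` in presentation order.

    Raises ``IOError`` for unreadable containers and ``ValueError`` for
    zero-frame videos.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"video not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        frames: Iterable[np.ndarray] = stack
    elif suffix == ".npy":
        stack = np.load(path)
        if stack.ndim == 2:
            stack = stack[None]
        frames = stack
    else:
        try:
            frames = iio.imiter(path)
        except Exception as exc:  # plugin missing or corrupt container
            raise IOError(f"cannot decode video {path}: {exc}") from exc
    n = 0
    for i, frame in enumerate(frames):
        yield i, to_grayscale(frame) if grayscale else np.asarray(frame)
        n += 1
    if n == 0:
        raise ValueError(f"video has no frames: {path}")


def count_frames(path: str | Path) -> int:
    return sum(1 for _ in iter_frames(path, grayscale=False))


def parse_filename(path: str | Path) -> VideoMeta:
    """Split the filename stem into its underscore-separated identifier
    tokens.  Degenerate stems yield a single token."""
    path = Path(path)
    tokens = tuple(t for t in path.stem.split("_") if t) or (path.stem,)
    return VideoMeta(path=path, tokens=tokens)


def build_filename(tokens: Iterable[str], suffix: str = ".h264") -> str:
    """Inverse of :func:`parse_filename`: join tokens with underscores."""
    tokens = list(tokens)
    if not tokens or any(not t or "_" in t for t in tokens):
        raise ValueError("tokens must be non-empty and underscore-free")
    return "_".join(tokens) + suffix


def _write_rows(rows, columns: list[str], out_path: str | Path) -> None:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    records = [asdict(r) if not isinstance(r, dict) else r for r in rows]
    df = pd.DataFrame.from_records(records, columns=columns)
    header = not out_path.exists()
    df.to_csv(out_path, mode="a", header=header, index=False, encoding="utf-8")
    if header and df.empty:
        # pandas skips the header for an empty frame in append mode
        out_path.write_text(",".join(columns) + "\n", encoding="utf-8")


def write_detailed(rows: Iterable[DetailedSizeRow], out_path: str | Path) -> None:
    """Append per-frame rows to the detailed CSV (header written once)."""
    _write_rows(list(rows), DETAILED_COLUMNS, out_path)


def write_summary(rows: Iterable[SummarySizeRow], out_path: str | Path) -> None:
    """Append per-video summary rows to the summary CSV."""
    _write_rows(list(rows), SUMMARY_COLUMNS, out_path)


def read_detailed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_summary(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def draw_ellipse_overlay(
    gray_frame: np.ndarray, measurement: ObjectMeasurement
) -> np.ndarray:
    """RGB copy of the frame with the fitted ellipse drawn as a 1-px
    outline."""
    rgb = np.stack([gray_frame] * 3, axis=-1).astype(np.uint8)
    rr, cc = ellipse_perimeter(
        int(round(measurement.center_y)),
        int(round(measurement.center_x)),
        max(1, int(round(measurement.minor_axis_px / 2.0))),
        max(1, int(round(measurement.major_axis_px / 2.0))),
        orientation=np.deg2rad(measurement.orientation_deg),
        shape=gray_frame.shape,
    )
    rgb[rr, cc] = (255, 64, 64)
    return rgb


def save_snapshots(
    frames_with_measurements: Iterable[tuple[np.ndarray, ObjectMeasurement]],
    out_dir: str | Path,
    video_name: str,
    limit: int = SNAPSHOT_LIMIT,
    annotate: bool = True,
) -> list[Path]:
    """Save the first *limit* accepted frames as PNGs for manual validation.

    Files are named ``<video_name>_fNNNN.png``; with ``annotate`` the fitted
    ellipse is drawn over the frame.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for frame, m in frames_with_measurements:
        if len(written) >= limit:
            break
        img = draw_ellipse_overlay(frame, m) if annotate else np.asarray(frame)
        path = out_dir / f"{video_name}_f{m.frame_index:04d}.png"
        iio.imwrite(path, img)
        written.append(path)
    return written
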