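"""Video ingestion: grayscale intensity volumes, clip segmentation, cropping.

A recording is represented as a :class:`VideoVolume` — a ``(height, width,
n_frames)`` array of intensities in ``[0, 1]`` tagged with its frame rate and
provenance (patient id, clip id).  Long recordings are segmented into clips of
at most one minute; an optional static bounding box localizes the patient in
the frame before feature extraction.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VideoVolume",
    "BoundingBox",
    "AnnotationRecord",
    "LUMA_WEIGHTS",
    "rgb_to_intensity",
    "load_video",
    "load_frames",
    "segment_clips",
    "crop_bbox",
    "read_annotations",
    "write_annotations",
    "LABEL_TO_SIGN",
]

#: ITU-R BT.601 luma weights used for color-to-intensity conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Label convention: "normal" maps to +1, "abnormal" (seizure-related) to -1.
LABEL_TO_SIGN = {"normal": 1, "abnormal": -1}


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned crop region, 0-based, top-left origin, half-open extents."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError(
                f"bounding box extents must be >= 1, got "
                f"height={self.height}, width={self.width}"
            )
        if self.top < 0 or self.left < 0:
            raise ValueError(
                f"bounding box origin must be non-negative, got "
                f"top={self.top}, left={self.left}"
            )


@dataclass(frozen=True)
class VideoVolume:
    """Grayscale intensity volume ``(height, width, n_frames)`` in ``[0, 1]``."""

    data: np.ndarray
    frame_rate: float
    patient_id: str = ""
    clip_id: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"volume must be 3-D (h, w, t), got shape {data.shape}")
        if min(data.shape) < 1:
            raise ValueError(f"all volume dimensions must be >= 1, got {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume intensities must be finite")
        if data.min() < 0.0 or data.max() > 1.0:
            raise ValueError(
                f"intensities must lie in [0, 1], got range "
                f"[{data.min():.4g}, {data.max():.4g}]"
            )
        if not (self.frame_rate > 0):
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass(frozen=True)
class AnnotationRecord:
    """One row of the annotation table: clip path/id, patient, label, box."""

    clip: str
    patient_id: str
    label: str
    bbox: Optional[BoundingBox] = None

    def __post_init__(self) -> None:
        if self.label not in LABEL_TO_SIGN:
            raise ValueError(
                f"label must be one of {sorted(LABEL_TO_SIGN)}, got {self.label!r}"
            )

    @property
    def sign(self) -> int:
        return LABEL_TO_SIGN[self.label]


def rgb_to_intensity(frame: np.ndarray) -> np.ndarray:
    """Convert an ``(h, w, 3)`` RGB frame to intensity via luma weighting.

    Uses the standard weighting ``0.299 R + 0.587 G + 0.114 B``; a gray pixel
    ``(c, c, c)`` maps to ``c`` exactly.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError(f"expected an (h, w, 3) RGB frame, got shape {frame.shape}")
    if not np.all(np.isfinite(frame)):
        raise ValueError("RGB frame contains non-finite values")
    r, g, b = LUMA_WEIGHTS
    return r * frame[..., 0] + g * frame[..., 1] + b * frame[..., 2]


def _scale_to_unit(frame: np.ndarray) -> np.ndarray:
    """Scale a frame to [0, 1] by its container's max code value."""
    if frame.dtype == np.uint8:
        return frame.astype(np.float64) / 255.0
    if frame.dtype == np.uint16:
        return frame.astype(np.float64) / 65535.0
    out = frame.astype(np.float64)
    return np.clip(out, 0.0, 1.0)


def _resize_frame(frame: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    if frame.shape == tuple(target_size):
        return frame
    from skimage.transform import resize

    # bilinear (order=1); anti-aliasing when shrinking
    return resize(
        frame,
        target_size,
        order=1,
        mode="edge",
        anti_aliasing=frame.shape[0] > target_size[0] or frame.shape[1] > target_size[1],
        preserve_range=True,
    )


_FRAME_EXTS = (".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg")


def _numeric_key(p: Path) -> tuple:
    m = re.findall(r"\d+", p.stem)
    return (int(m[-1]) if m else 0, p.name)


def _iter_frames(path: Path):
    """Yield raw frames from a frame directory or a video container file."""
    import imageio.v2 as imageio

    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTS),
            key=_numeric_key,
        )
        if not files:
            raise ValueError(f"no image frames found in directory: {path}")
        for f in files:
            yield imageio.imread(f)
        return

    try:
        reader = imageio.get_reader(str(path))
    except Exception as exc:  # decoder missing or file corrupt
        raise ValueError(f"cannot decode video file {path}: {exc}") from exc
    try:
        yield from reader
    finally:
        reader.close()


def load_video(
    path,
    target_size: tuple[int, int] = (128, 160),
    frame_rate: float = 25.0,
    patient_id: str = "",
    clip_id: str = "",
) -> VideoVolume:
    """Load a video file or frame directory into a :class:`VideoVolume`.

    Every frame is converted to grayscale, resized (bilinear) to
    ``target_size = (height, width)`` and scaled to ``[0, 1]``.

    Parameters
    ----------
    path
        A video container file (any format the installed imageio backends can
        decode) or a directory of numbered image frames (PNG/TIFF/...).
    target_size
        Working resolution ``(height, width)``; default 128 x 160.
    frame_rate
        Frames per second of the source; default 25.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"video input not found: {path}")

    frames = []
    for raw in _iter_frames(path):
        raw = np.asarray(raw)
        if raw.ndim == 3 and raw.shape[-1] == 4:  # drop alpha
            raw = raw[..., :3]
        if raw.ndim == 3:
            gray = rgb_to_intensity(_scale_to_unit(raw) * 1.0)
        else:
            gray = _scale_to_unit(raw)
        frames.append(np.clip(_resize_frame(gray, target_size), 0.0, 1.0))

    if not frames:
        raise ValueError(f"video input has zero frames: {path}")

    data = np.stack(frames, axis=-1)
    return VideoVolume(
        data=data,
        frame_rate=frame_rate,
        patient_id=patient_id,
        clip_id=clip_id or path.stem,
    )


def load_frames(
    frames: Sequence[np.ndarray],
    frame_rate: float = 25.0,
    target_size: Optional[tuple[int, int]] = None,
    patient_id: str = "",
    clip_id: str = "",
) -> VideoVolume:
    """Build a :class:`VideoVolume` from in-memory frames (gray or RGB)."""
    out = []
    for raw in frames:
        raw = np.asarray(raw)
        gray = rgb_to_intensity(_scale_to_unit(raw)) if raw.ndim == 3 else _scale_to_unit(raw)
        if target_size is not None:
            gray = _resize_frame(gray, target_size)
        out.append(np.clip(gray, 0.0, 1.0))
    if not out:
        raise ValueError("no frames given")
    return VideoVolume(np.stack(out, axis=-1), frame_rate, patient_id, clip_id)


def segment_clips(volume: VideoVolume, max_duration_s: float = 60.0) -> list[VideoVolume]:
    """Split a volume into consecutive clips no longer than ``max_duration_s``.

    Chunks are non-overlapping, in temporal order, and concatenate back to the
    input exactly; the last chunk may be shorter.  Child clip ids are the
    parent id with a zero-based index suffix (``<clip_id>_seg<k>``).  A volume
    already within the limit is returned as a single (identical) clip.
    """
    if not (max_duration_s > 0):
        raise ValueError(f"max_duration_s must be > 0, got {max_duration_s}")
    max_frames = int(math.floor(max_duration_s * volume.frame_rate + 1e-9))
    max_frames = max(max_frames, 1)
    n = volume.n_frames
    if n <= max_frames:
        return [volume]
    chunks = []
    for k, start in enumerate(range(0, n, max_frames)):
        chunks.append(
            replace(
                volume,
                data=volume.data[:, :, start : start + max_frames],
                clip_id=f"{volume.clip_id}_seg{k}",
            )
        )
    return chunks


def crop_bbox(volume: VideoVolume, box: BoundingBox) -> VideoVolume:
    """Crop every frame of ``volume`` to ``box``; frame count is unchanged."""
    h, w, _ = volume.shape
    if box.top + box.height > h:
        raise ValueError(
            f"bounding box bottom edge {box.top + box.height} exceeds frame height {h}"
        )
    if box.left + box.width > w:
        raise ValueError(
            f"bounding box right edge {box.left + box.width} exceeds frame width {w}"
        )
    data = volume.data[box.top : box.top + box.height, box.left : box.left + box.width, :]
    return replace(volume, data=data)


# ---------------------------------------------------------------------------
# annotation table (CSV: clip,patient_id,label,top,left,height,width)
# ---------------------------------------------------------------------------

_ANNOT_COLS = ["clip", "patient_id", "label", "top", "left", "height", "width"]


def read_annotations(path) -> list[AnnotationRecord]:
    """Read an annotation CSV; bounding-box columns may be empty."""
    df = pd.read_csv(path, dtype={"clip": str, "patient_id": str, "label": str})
    missing = [c for c in ("clip", "patient_id", "label") if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        bbox = None
        if all(c in df.columns and pd.notna(row[c]) for c in ("top", "left", "height", "width")):
            bbox = BoundingBox(
                top=int(row["top"]), left=int(row["left"]),
                height=int(row["height"]), width=int(row["width"]),
            )
        records.append(
            AnnotationRecord(
                clip=str(row["clip"]),
                patient_id=str(row["patient_id"]),
                label=str(row["label"]).strip().lower(),
                bbox=bbox,
            )
        )
    return records


def write_annotations(records: Sequence[AnnotationRecord], path) -> None:
    rows = []
    for r in records:
        row = {"clip": r.clip, "patient_id": r.patient_id, "label": r.label,
               "top": "", "left": "", "height": "", "width": ""}
        if r.bbox is not None:
            row.update(top=r.bbox.top, left=r.bbox.left,
                       height=r.bbox.height, width=r.bbox.width)
        rows.append(row)
    pd.DataFrame(rows, columns=_ANNOT_COLS).to_csv(path, index=False)
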