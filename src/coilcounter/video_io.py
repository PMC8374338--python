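"""Video decoding and image-stack persistence.

A recording of a dish of embryos enters the pipeline either as a video file
(AVI/MP4 when an ffmpeg-capable imageio plugin is installed, GIF always) or
as a directory of numbered PNG frames with a ``stack.json`` sidecar.  Both
roads lead to a :class:`FrameStack`: grayscale frames on a uniform time grid,
normalized to ``[0, 1]``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "FrameStack",
    "VideoDecodeError",
    "StackFormatError",
    "extract_frames",
    "to_grayscale",
    "save_stack_dir",
    "load_stack_dir",
]

STACK_META_NAME = "stack.json"
FRAME_NAME_FMT = "frame_{:06d}.png"


class VideoDecodeError(IOError):
    """The video file could not be opened or decoded."""


class StackFormatError(ValueError):
    """An image-stack directory is malformed (bad metadata or frame shapes)."""


@dataclass
class FrameStack:
    """Ordered grayscale frames on a uniform time grid.

    Attributes
    ----------
    frames : (n, h, w) float array, values in [0, 1]
    times_s : (n,) acquisition time of each frame, seconds from video start;
        frame ``i`` carries ``i * 60 / sample_rate_fpm``.
    source_id : stem of the originating video file.
    duration_s : total recorded duration of the source in seconds.
    sample_rate_fpm : frames per minute used at extraction.
    """

    frames: np.ndarray
    times_s: np.ndarray = field(repr=False)
    source_id: str
    duration_s: float
    sample_rate_fpm: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (n, h, w), got shape {self.frames.shape}")
        if len(self.times_s) != len(self.frames):
            raise ValueError("times_s and frames must have equal length")
        if len(self.times_s) > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times_s must be strictly increasing")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sample_rate_fpm <= 0:
            raise ValueError("sample_rate_fpm must be positive")
        expected = round(self.duration_s * self.sample_rate_fpm / 60.0)
        if abs(len(self.frames) - expected) > 1:
            raise ValueError(
                f"frame count {len(self.frames)} inconsistent with "
                f"duration {self.duration_s}s at {self.sample_rate_fpm} fpm "
                f"(expected ~{expected})"
            )

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]


def to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse a (h, w[, 3|4]) image to single-channel luma (Rec. 601).

    Idempotent on already-gray input.
    """
    arr = np.asarray(arr)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    raise ValueError(f"cannot interpret array of shape {arr.shape} as an image")


def _normalize_intensity(arr: np.ndarray) -> np.ndarray:
    """Scale to [0, 1] by the dtype maximum of the decoded frame."""
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def _native_fps(path: Path, n_frames: int) -> float:
    """Best-effort native frame rate from container metadata."""
    try:
        meta = iio.immeta(path, index=None)
    except Exception:
        meta = {}
    fps = meta.get("fps")
    if fps:
        return float(fps)
    dur_ms = meta.get("duration")  # GIF: per-frame delay in ms
    if dur_ms:
        return 1000.0 / float(dur_ms)
    total = meta.get("duration_s")
    if total:
        return n_frames / float(total)
    raise VideoDecodeError(f"cannot determine native frame rate of {path}")


def extract_frames(video_path: str | Path, sample_rate_fpm: float = 120.0) -> FrameStack:
    """Decode ``video_path`` into a uniformly sampled grayscale FrameStack.

    The target time grid is ``i * 60 / sample_rate_fpm``; for each target the
    nearest native frame is taken, and no native frame is used twice (which
    the precondition ``sample_rate_fpm <= native rate`` guarantees).  A
    trailing remainder of the native stream that does not fill a whole
    sampling step is truncated, never padded.
    """
    path = Path(video_path)
    if sample_rate_fpm <= 0:
        raise ValueError("sample_rate_fpm must be positive")
    if not path.is_file():
        raise VideoDecodeError(f"video file not found: {path}")
    try:
        raw = iio.imread(path, index=None)
    except Exception as exc:  # plugin-specific error zoo
        raise VideoDecodeError(f"cannot decode video {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.ndim == 2:  # single frame
        raw = raw[None]
    if len(raw) == 0:
        raise VideoDecodeError(f"video {path} contains no frames")

    fps = _native_fps(path, len(raw))
    native_fpm = fps * 60.0
    if sample_rate_fpm > native_fpm + 1e-9:
        raise ValueError(
            f"requested sample rate {sample_rate_fpm} frames/min exceeds the "
            f"native rate {native_fpm:g} frames/min of {path.name}"
        )

    duration_s = len(raw) / fps
    n_out = int(np.floor(duration_s * sample_rate_fpm / 60.0 + 1e-9))
    step_s = 60.0 / sample_rate_fpm
    times = np.arange(n_out) * step_s
    native_idx = np.clip(np.round(times * fps).astype(int), 0, len(raw) - 1)
    if len(np.unique(native_idx)) != len(native_idx):
        raise VideoDecodeError(f"non-monotone frame sampling for {path}")

    frames = np.stack(
        [to_grayscale(_normalize_intensity(np.asarray(raw[i]))) for i in native_idx]
    )
    return FrameStack(
        frames=frames,
        times_s=times,
        source_id=path.stem,
        duration_s=duration_s,
        sample_rate_fpm=float(sample_rate_fpm),
    )


def save_stack_dir(stack: FrameStack, dir_path: str | Path) -> list[Path]:
    """Persist a FrameStack as numbered 8-bit PNGs plus ``stack.json``.

    Mirrors the per-video intermediate folder of the original workflow.
    Returns the list of files written.
    """
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for i, frame in enumerate(stack.frames, start=1):
        p = out / FRAME_NAME_FMT.format(i)
        iio.imwrite(p, np.round(np.clip(frame, 0, 1) * 255).astype(np.uint8))
        written.append(p)
    meta = {
        "duration_s": stack.duration_s,
        "sample_rate_fpm": stack.sample_rate_fpm,
        "source_id": stack.source_id,
        "n_frames": len(stack),
    }
    meta_path = out / STACK_META_NAME
    meta_path.write_text(json.dumps(meta, indent=2))
    written.append(meta_path)
    return written


def load_stack_dir(dir_path: str | Path) -> FrameStack:
    """Load a stack directory written by :func:`save_stack_dir`.

    Round-trip contract: ``load(save(stack))`` reproduces frame values within
    1/255 per pixel and exact metadata.
    """
    d = Path(dir_path)
    meta_path = d / STACK_META_NAME
    if not meta_path.is_file():
        raise StackFormatError(f"missing {STACK_META_NAME} in {d}")
    try:
        meta = json.loads(meta_path.read_text())
        duration_s = float(meta["duration_s"])
        rate = float(meta["sample_rate_fpm"])
        source_id = str(meta["source_id"])
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise StackFormatError(f"malformed {meta_path}: {exc}") from exc

    frame_paths = sorted(d.glob("frame_*.png"))
    if not frame_paths:
        raise StackFormatError(f"no frame_*.png files in {d}")
    frames = []
    shape = None
    for p in frame_paths:
        img = np.asarray(iio.imread(p))
        if img.ndim != 2:
            img = to_grayscale(img)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise StackFormatError(
                f"inconsistent frame shapes in {d}: {shape} vs {img.shape} ({p.name})"
            )
        frames.append(_normalize_intensity(img))
    n = len(frames)
    if "n_frames" in meta and int(meta["n_frames"]) != n:
        warnings.warn(
            f"{d}: metadata says {meta['n_frames']} frames, found {n}", stacklevel=2
        )
    times = np.arange(n) * 60.0 / rate
    return FrameStack(
        frames=np.stack(frames),
        times_s=times,
        source_id=source_id,
        duration_s=duration_s,
        sample_rate_fpm=rate,
    )
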