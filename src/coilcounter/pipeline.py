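"""End-to-end orchestration: video (or stack) -> per-dish coiling results.

The stages run in the order of the original workflow: frame extraction,
preprocessing + global thresholding, per-frame labeling with clump
splitting, centroid tracking, frame differencing + per-embryo variance
traces, peak calling, QC flags, and result export.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import plots
from .motion_signal import variance_trace, difference_stack
from .peak_analysis import PeakConfig, count_stc
from .results_qc import DishResult, check_for_errors, compile_dish, export_results
from .segmentation import SegmentationConfig, segment_stack
from .tracking import build_tracks, tracks_to_table
from .video_io import FrameStack, extract_frames, load_stack_dir, save_stack_dir

__all__ = ["PipelineConfig", "analyze_stack", "analyze_video", "run_folder"]

logger = logging.getLogger(__name__)

VIDEO_PATTERNS = ("*.avi", "*.mp4", "*.gif")


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are the workflow defaults
    (120 frames/min, 15 px gate, peak threshold 0.003, smoothing 0.1,
    20 embryos per dish)."""

    sample_rate_fpm: float = 120.0
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    max_centroid_dist_px: float = 15.0
    diff_threshold: float = 0.02
    peaks: PeakConfig = field(default_factory=PeakConfig)
    expected_n_embryos: int = 20
    keep_intermediate_frames: bool = False

    def to_dict(self) -> dict:
        return {
            "sample_rate_fpm": self.sample_rate_fpm,
            "segmentation": vars(self.segmentation).copy(),
            "max_centroid_dist_px": self.max_centroid_dist_px,
            "diff_threshold": self.diff_threshold,
            "peaks": vars(self.peaks).copy(),
            "expected_n_embryos": self.expected_n_embryos,
            "keep_intermediate_frames": self.keep_intermediate_frames,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        seg = SegmentationConfig(**d.pop("segmentation", {}))
        peaks = PeakConfig(**d.pop("peaks", {}))
        return cls(segmentation=seg, peaks=peaks, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def apply_overrides(self, overrides: Sequence[str]) -> "PipelineConfig":
        """Apply ``section.key=value`` (or ``key=value``) strings."""
        d = self.to_dict()
        for item in overrides:
            if "=" not in item:
                raise ValueError(f"override must look like key=value, got {item!r}")
            key, _, raw = item.partition("=")
            value = yaml.safe_load(raw)
            parts = key.strip().split(".")
            node = d
            for p in parts[:-1]:
                if p not in node:
                    raise KeyError(f"unknown config section {p!r}")
                node = node[p]
            if parts[-1] not in node:
                raise KeyError(f"unknown config key {key!r}")
            node[parts[-1]] = value
        return PipelineConfig.from_dict(d)


def analyze_stack(
    stack: FrameStack,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> DishResult:
    """Run segmentation -> tracking -> variance -> peak calling on a stack.

    If ``out_dir`` is given, the workbook/CSVs, an annotated first frame and
    per-embryo peak plots are written there.
    """
    config = config or PipelineConfig()
    label_maps, threshold, pre = segment_stack(stack, config.segmentation)
    k_median = float(np.median([lm.n_labels for lm in label_maps]))
    tracks = build_tracks(label_maps, config.max_centroid_dist_px)
    logger.info(
        "%s: %d frames, median K=%g, %d tracks, threshold=%.4f",
        stack.source_id, len(stack), k_median, len(tracks), threshold,
    )
    diffs = difference_stack(pre)
    traces = variance_trace(
        diffs, tracks, label_maps, config.diff_threshold, times_s=stack.times_s
    )
    stc = []
    for eid in sorted(traces):
        if not np.any(np.isfinite(traces[eid].values)):
            logger.warning(
                "%s: embryo %d has no valid transitions; excluded from results",
                stack.source_id, eid,
            )
            continue
        stc.append(count_stc(traces[eid], config.peaks, stack.duration_s))
    flags = check_for_errors(tracks, label_maps, config.expected_n_embryos)
    for fl in flags:
        logger.warning("%s: [%s] %s", stack.source_id, fl.kind, fl.message)
    dish = compile_dish(stack.source_id, stc, threshold, flags, stack.duration_s)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        export_results(dish, out_dir)
        tracks_to_table(tracks).to_csv(out_dir / f"{stack.source_id}_tracks.csv",
                                       index=False)
        label_to_track = {
            e.label_id: tr.embryo_id
            for tr in tracks for e in tr.entries if e.frame_index == 0
        }
        plots.save_annotated_frame(
            stack.frames[0], label_maps[0],
            out_dir / f"{stack.source_id}_labels.png", label_to_track,
        )
        for r in dish.stc_results:
            plots.save_peak_plot(
                r, out_dir / f"{stack.source_id}_embryo{r.embryo_id}_peaks.png",
                times_s=traces[r.embryo_id].times_s,
            )
    return dish


def analyze_video(
    video_path: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> DishResult:
    """Extract frames from a video file (or stack directory) and analyze.

    Mirrors the original workflow's per-video frame folder: frames are
    written next to the results and removed afterwards unless
    ``keep_intermediate_frames`` is set.
    """
    config = config or PipelineConfig()
    video_path = Path(video_path)
    if video_path.is_dir():
        stack = load_stack_dir(video_path)
    else:
        stack = extract_frames(video_path, config.sample_rate_fpm)
    frames_dir = None
    if out_dir is not None:
        frames_dir = Path(out_dir) / f"{stack.source_id}_frames"
        save_stack_dir(stack, frames_dir)
    try:
        return analyze_stack(stack, config, out_dir)
    finally:
        if frames_dir is not None and not config.keep_intermediate_frames:
            shutil.rmtree(frames_dir, ignore_errors=True)


def run_folder(
    input_dir: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    pattern: str | None = None,
) -> tuple[list[DishResult], dict[str, str]]:
    """Analyze every video in a folder; isolate per-video failures.

    Returns ``(results, failures)`` where failures maps file name to the
    error message.  Raises ValueError if the folder holds no matching video.
    """
    config = config or PipelineConfig()
    input_dir = Path(input_dir)
    patterns = (pattern,) if pattern else VIDEO_PATTERNS
    videos: list[Path] = []
    for pat in patterns:
        videos.extend(sorted(input_dir.glob(pat)))
    videos = sorted(set(videos))
    if not videos:
        raise ValueError(f"no video files matching {patterns} in {input_dir}")
    results: list[DishResult] = []
    failures: dict[str, str] = {}
    for v in videos:
        try:
            results.append(analyze_video(v, config, out_dir))
        except Exception as exc:
            logger.error("analysis failed for %s: %s", v.name, exc)
            failures[v.name] = str(exc)
    if failures:
        logger.warning("%d/%d videos failed: %s",
                       len(failures), len(videos), ", ".join(failures))
    return results, failures
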