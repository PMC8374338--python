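"""Per-embryo movement signal from frame differencing.

Movement is detected as the variance of gray values of the frame-to-frame
difference image within each embryo's label region: a coiling tail changes
a sub-region of the embryo's pixels between successive frames, which shows
up as a spike of within-label variance.  An increase in variance indicates
tail coiling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .segmentation import LabelMap
from .tracking import EmbryoTrack
from .video_io import FrameStack

__all__ = ["VarianceTrace", "difference_stack", "variance_trace"]

logger = logging.getLogger(__name__)

DEFAULT_DIFF_THRESHOLD = 0.02  # ~5/255, suppresses sensor noise


@dataclass
class VarianceTrace:
    """Per-embryo motion-variance time series.

    One value per frame transition (length = n_frames - 1); transitions where
    the embryo was not observed hold NaN, not zero.  ``times_s`` is the
    midpoint time of each transition.
    """

    embryo_id: int
    values: np.ndarray
    times_s: np.ndarray = field(repr=False)
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError("variance values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


def difference_stack(stack: FrameStack | np.ndarray) -> np.ndarray:
    """Absolute frame-to-frame differences: element t is ``|f[t+1] - f[t]|``.

    Absolute (not signed): coil motion both brightens and darkens pixels.
    """
    if isinstance(stack, FrameStack):
        frames = stack.frames
    else:
        frames = np.asarray(stack, dtype=np.float64)
        if frames.ndim != 3:
            raise ValueError("expected (n, h, w) frames")
    if len(frames) < 2:
        raise ValueError("need at least two frames to form differences")
    return np.abs(np.diff(frames, axis=0))


def variance_trace(
    diffs: np.ndarray,
    tracks: Sequence[EmbryoTrack],
    label_maps: Sequence[LabelMap],
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD,
    times_s: np.ndarray | None = None,
) -> dict[int, VarianceTrace]:
    """Variance of thresholded difference pixels within each embryo label.

    For transition t the label region of the *earlier* frame (t) is used —
    embryo drift between two frames is bounded by the tracking gate, so the
    earlier region is a deterministic, adequate stand-in for both.  Pixels
    below ``diff_threshold`` are zeroed (kept in the population) and the
    population variance (ddof=0) of the region's pixel set is returned.
    Missing embryos or empty regions yield NaN.
    """
    diffs = np.asarray(diffs)
    n_trans = len(diffs)
    if len(label_maps) != n_trans + 1:
        raise ValueError(
            f"{len(diffs)} difference images require {n_trans + 1} label maps, "
            f"got {len(label_maps)}"
        )
    if times_s is None:
        times = np.arange(n_trans, dtype=float) + 0.5
    else:
        times_s = np.asarray(times_s, dtype=float)
        times = 0.5 * (times_s[:-1] + times_s[1:])

    out: dict[int, VarianceTrace] = {}
    for tr in tracks:
        values = np.full(n_trans, np.nan)
        present = {e.frame_index: e.label_id for e in tr.entries}
        for t in range(n_trans):
            lab = present.get(t)
            if lab is None:
                continue
            region = label_maps[t].labels == lab
            px = diffs[t][region]
            if px.size == 0:
                logger.warning(
                    "embryo %d: empty label region at transition %d", tr.embryo_id, t
                )
                continue
            px = np.where(px < diff_threshold, 0.0, px)
            values[t] = px.var()
        out[tr.embryo_id] = VarianceTrace(
            embryo_id=tr.embryo_id,
            values=values,
            times_s=times,
            diff_threshold=diff_threshold,
        )
    return out


def traces_to_table(traces: dict[int, VarianceTrace]):
    """Long-format export of all traces (embryo, transition, time, variance)."""
    import pandas as pd

    rows = []
    for eid in sorted(traces):
        tr = traces[eid]
        for t, (v, ts) in enumerate(zip(tr.values, tr.times_s)):
            rows.append((eid, t, ts, v))
    return pd.DataFrame(
        rows, columns=["embryo_id", "transition_index", "time_s", "variance"]
    )
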