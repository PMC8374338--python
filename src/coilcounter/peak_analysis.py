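"""Peak detection on variance traces and STC frequency computation.

Each trace is smoothed with a Gaussian-weighted moving average whose window
is a fraction of the trace length, then scanned for local maxima whose drop
to the next point exceeds a threshold — the semantics of quantmod's
``findPeaks`` (which flags the bar *after* the turn; we report the maximum
index itself, an off-by-one presentation difference that leaves counts
unchanged).  Counts are converted to a spontaneous tail-coiling frequency
per minute using the recording duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motion_signal import VarianceTrace

__all__ = ["PeakConfig", "StcResult", "smooth_trace", "find_peaks", "count_stc"]


@dataclass
class PeakConfig:
    """Peak-calling parameters.

    ``peak_threshold`` is the minimum drop after a local maximum for it to
    count as a coil (applied to the smoothed trace); ``smoothing_span`` is
    the fraction of the trace length used as the smoothing window.
    Defaults are the workflow defaults (0.003 and 0.1).
    """

    peak_threshold: float = 0.003
    smoothing_span: float = 0.1
    min_separation: int = 2  # maxima closer than this are merged (keep higher)

    def __post_init__(self) -> None:
        if self.peak_threshold < 0:
            raise ValueError("peak_threshold must be >= 0")
        if not 0 < self.smoothing_span <= 1:
            raise ValueError("smoothing_span must be in (0, 1]")


@dataclass
class StcResult:
    """Per-embryo coiling result; raw and smoothed traces are kept for QC."""

    embryo_id: int
    peak_indices: np.ndarray
    peak_count: int
    frequency_per_min: float
    raw_trace: np.ndarray = field(repr=False)
    smoothed_trace: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if len(self.peak_indices) > 1 and not np.all(np.diff(self.peak_indices) > 0):
            raise ValueError("peak_indices must be strictly increasing")


def smoothing_window(span: float, n: int) -> int:
    """Window length: max(3, round(span * n)), forced odd."""
    w = max(3, int(round(span * n)))
    if w % 2 == 0:
        w += 1
    return min(w, n if n % 2 == 1 else n - 1) if n >= 3 else 3


def _gaussian_kernel(window: int) -> np.ndarray:
    """Truncated Gaussian weights over the window, sigma = (window - 1) / 8.

    The window spans +-4 sigma, concentrating weight near the center: coils
    a few seconds apart stay resolvable and the post-peak drop stays sharp
    enough for the drop-threshold peak criterion, while single-transition
    noise blips are still flattened below it.
    """
    half = window // 2
    sigma = max((window - 1) / 8.0, 1e-9)
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth_trace(
    trace: VarianceTrace | np.ndarray,
    smoothing_span: float = 0.1,
    embryo_id: int | None = None,
) -> np.ndarray:
    """Gaussian-weighted running mean of a trace; same length as the input.

    Missing (NaN) values are linearly interpolated first, with the ends held
    at the nearest observed value.  Edges are handled by edge replication,
    so a constant trace is preserved exactly.
    """
    if isinstance(trace, VarianceTrace):
        embryo_id = trace.embryo_id
        values = trace.values
    else:
        values = np.asarray(trace, dtype=np.float64)
    n = len(values)
    if n < 3:
        raise ValueError("trace must have length >= 3")
    finite = np.isfinite(values)
    if not finite.any():
        who = f"embryo {embryo_id}" if embryo_id is not None else "trace"
        raise ValueError(f"all values missing for {who}")
    if not finite.all():
        idx = np.arange(n)
        values = np.interp(idx, idx[finite], values[finite])

    w = smoothing_window(smoothing_span, n)
    kernel = _gaussian_kernel(w)
    half = w // 2
    padded = np.pad(values, half, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def find_peaks(
    values: np.ndarray, peak_threshold: float = 0.003, min_separation: int = 2
) -> np.ndarray:
    """Indices i with values[i] > both neighbors and a post-peak drop
    ``values[i] - values[i+1]`` strictly above ``peak_threshold``.

    Plateaus (equal neighbors) are not peaks and endpoints are never peaks.
    Surviving maxima closer than ``min_separation`` are merged, keeping the
    higher one (guards against double-counting fast multiple coils).
    """
    v = np.asarray(values, dtype=np.float64)
    if len(v) < 3:
        raise ValueError("need at least 3 values")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    i = np.arange(1, len(v) - 1)
    is_peak = (v[i] > v[i - 1]) & (v[i] > v[i + 1]) & (v[i] - v[i + 1] > peak_threshold)
    cand = i[is_peak]
    if min_separation > 1 and len(cand) > 1:
        kept: list[int] = [int(cand[0])]
        for c in cand[1:]:
            if c - kept[-1] < min_separation:
                if v[c] > v[kept[-1]]:
                    kept[-1] = int(c)
            else:
                kept.append(int(c))
        cand = np.array(kept)
    return cand.astype(int)


def count_stc(
    trace: VarianceTrace, config: PeakConfig, duration_s: float
) -> StcResult:
    """Smooth, detect peaks, and report the STC frequency per minute.

    ``frequency_per_min = peak_count * 60 / duration_s`` exactly.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    smoothed = smooth_trace(trace, config.smoothing_span)
    peaks = find_peaks(smoothed, config.peak_threshold, config.min_separation)
    count = int(len(peaks))
    return StcResult(
        embryo_id=trace.embryo_id,
        peak_indices=peaks,
        peak_count=count,
        frequency_per_min=count * 60.0 / duration_s,
        raw_trace=np.asarray(trace.values, dtype=float),
        smoothed_trace=smoothed,
    )
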