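"""QC figure exports: annotated label overlays and peak plots.

These are the inspection artifacts for the manual correction protocol:
an annotated frame locates each embryo by its (1-based) image label, and a
peak plot shows the smoothed and unsmoothed variance traces with dashed
vertical lines at the detected coils, so suspect peaks (wide, weak, or
irregular) can be verified against the original video.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .peak_analysis import StcResult
from .segmentation import LabelMap

__all__ = ["save_annotated_frame", "save_peak_plot"]


def save_annotated_frame(
    frame: np.ndarray,
    label_map: LabelMap,
    out_path: str | Path,
    embryo_ids: dict[int, int] | None = None,
) -> Path:
    """Save ``frame`` with embryo numbers drawn at label centroids.

    Numbers are 1-based (image-annotation convention; the tables are
    0-based).  ``embryo_ids`` optionally maps frame label -> track id.
    """
    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.imshow(frame, cmap="gray", vmin=0, vmax=1)
    for region in label_map.regions:
        eid = embryo_ids.get(region.label) if embryo_ids else region.label - 1
        if eid is None:
            continue
        r, c = region.centroid
        ax.text(c, r, str(eid + 1), color="yellow", fontsize=9,
                ha="center", va="center")
    ax.set_axis_off()
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path


def save_peak_plot(
    result: StcResult,
    out_path: str | Path,
    times_s: Sequence[float] | None = None,
) -> Path:
    """Save smoothed + raw variance traces with dashed lines at peaks."""
    out_path = Path(out_path)
    x = np.asarray(times_s) if times_s is not None else np.arange(len(result.raw_trace))
    xlabel = "time (s)" if times_s is not None else "transition index"
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(x, result.raw_trace, lw=0.7, color="0.6", label="unsmoothed")
    ax.plot(x, result.smoothed_trace, lw=1.4, color="C0", label="smoothed")
    for p in result.peak_indices:
        ax.axvline(x[p], ls="--", color="C3", lw=0.8)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("variance")
    ax.set_title(
        f"embryo {result.embryo_id}: {result.peak_count} coils "
        f"({result.frequency_per_min:g}/min)"
    )
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
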