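"""Centroid-based tracking: chain per-frame labels into embryo identities.

Embryos barely move between frames, so identity is maintained by greedy
nearest-neighbor matching of label centroids with a hard distance gate
(default 15 px, inclusive).  A track that loses its label for one frame may
re-join through the same gate; after that a new identity is opened.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .segmentation import LabelMap

__all__ = [
    "TrackEntry",
    "EmbryoTrack",
    "associate_frames",
    "build_tracks",
    "tracks_to_table",
]

DEFAULT_GATE_PX = 15.0
REJOIN_MAX_GAP_FRAMES = 1  # a track may be missing for at most this many frames


@dataclass(frozen=True)
class TrackEntry:
    frame_index: int
    label_id: int
    centroid: tuple[float, float]


@dataclass
class EmbryoTrack:
    """A persistent embryo identity across frames.

    ``embryo_id`` is 0-based (tabular convention; image annotations add 1).
    Entries exist only for frames where the embryo was matched; a frame
    without an entry is a missing observation.
    """

    embryo_id: int
    entries: list[TrackEntry] = field(default_factory=list)

    def frames(self) -> list[int]:
        return [e.frame_index for e in self.entries]

    def label_at(self, frame_index: int) -> int | None:
        for e in self.entries:
            if e.frame_index == frame_index:
                return e.label_id
        return None

    def coverage(self, n_frames: int) -> float:
        return len(self.entries) / n_frames if n_frames else 0.0

    @property
    def first_frame(self) -> int:
        return self.entries[0].frame_index

    @property
    def last_entry(self) -> TrackEntry:
        return self.entries[-1]


def _greedy_match(
    prev_items: Sequence[tuple[int, tuple[float, float]]],
    curr_items: Sequence[tuple[int, tuple[float, float]]],
    gate_px: float,
) -> dict[int, int]:
    """Greedy minimum-distance matching with an inclusive gate.

    Candidate pairs are sorted by (distance, prev key, curr key) and accepted
    while both sides are unmatched — deterministic, and identical to the
    optimal assignment for well-separated embryos.
    """
    pairs = []
    for pk, pc in prev_items:
        for ck, cc in curr_items:
            d = float(np.hypot(pc[0] - cc[0], pc[1] - cc[1]))
            if d <= gate_px:
                pairs.append((d, pk, ck))
    pairs.sort()
    matched: dict[int, int] = {}
    used_curr: set[int] = set()
    for _, pk, ck in pairs:
        if pk in matched or ck in used_curr:
            continue
        matched[pk] = ck
        used_curr.add(ck)
    return matched


def associate_frames(
    prev: LabelMap, curr: LabelMap, max_centroid_dist_px: float = DEFAULT_GATE_PX
) -> dict[int, int]:
    """Map previous-frame labels to current-frame labels by centroid proximity.

    A pair is matched only if the Euclidean centroid distance is at most the
    gate (inclusive: 15 px matches, 16 px does not, at the default).
    Unmatched current labels signal new tracks; unmatched previous labels are
    missing in the current frame.
    """
    if prev.labels.shape != curr.labels.shape:
        raise ValueError("label maps must share image geometry")
    return _greedy_match(
        [(r.label, r.centroid) for r in prev.regions],
        [(r.label, r.centroid) for r in curr.regions],
        max_centroid_dist_px,
    )


def build_tracks(
    label_maps: Sequence[LabelMap], max_centroid_dist_px: float = DEFAULT_GATE_PX
) -> list[EmbryoTrack]:
    """Chain label maps into tracks; every label of every frame is covered
    exactly once.

    New identities are numbered by order of first appearance (frame, then
    row-major centroid).  A track unseen in the immediately previous frame
    may still re-join within the gate for one more frame, matched against
    its last known centroid.
    """
    if len(label_maps) == 0:
        raise ValueError("need at least one label map")
    tracks: list[EmbryoTrack] = []

    def _open_tracks(frame_index: int, regions: Iterable) -> None:
        for r in sorted(regions, key=lambda r: r.centroid):
            t = EmbryoTrack(embryo_id=len(tracks))
            t.entries.append(TrackEntry(frame_index, r.label, r.centroid))
            tracks.append(t)

    _open_tracks(0, label_maps[0].regions)
    for t_idx in range(1, len(label_maps)):
        lm = label_maps[t_idx]
        candidates = [
            tr for tr in tracks
            if t_idx - tr.last_entry.frame_index <= REJOIN_MAX_GAP_FRAMES + 1
        ]
        matched = _greedy_match(
            [(tr.embryo_id, tr.last_entry.centroid) for tr in candidates],
            [(r.label, r.centroid) for r in lm.regions],
            max_centroid_dist_px,
        )
        by_id = {tr.embryo_id: tr for tr in candidates}
        taken = set(matched.values())
        for eid, lab in matched.items():
            centroid = next(r.centroid for r in lm.regions if r.label == lab)
            by_id[eid].entries.append(TrackEntry(t_idx, lab, centroid))
        _open_tracks(t_idx, [r for r in lm.regions if r.label not in taken])
    return tracks


def tracks_to_table(tracks: Sequence[EmbryoTrack]) -> pd.DataFrame:
    """Flat per-observation table: embryo_id, frame_index, label_id, centroid."""
    rows = [
        (tr.embryo_id, e.frame_index, e.label_id, e.centroid[0], e.centroid[1])
        for tr in tracks
        for e in tr.entries
    ]
    return pd.DataFrame(
        rows,
        columns=["embryo_id", "frame_index", "label_id", "centroid_row", "centroid_col"],
    )
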