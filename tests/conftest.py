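"""Shared fixtures: small synthetic dishes sized for fast unit tests.

The full acquisition conditions (20 embryos, 400x300 px, 60 s) are exercised
in the acceptance tests; unit tests use smaller dishes for speed.
"""

import numpy as np
import pytest

import coilcounter as cc


@pytest.fixture(scope="session")
def small_dish():
    """A 5-embryo, 30 s dish at the analysis rate with known coil counts."""
    counts = [0, 2, 4, 3, 1]
    stack, schedule = cc.generate_dish_video(
        n_embryos=5,
        duration_s=30.0,
        fps_native=2.0,
        counts=counts,
        seed=11,
        frame_shape=(200, 260),
    )
    return stack, schedule


@pytest.fixture(scope="session")
def small_dish_analysis(small_dish):
    """Segmentation + tracking of the small dish, shared across tests."""
    stack, schedule = small_dish
    label_maps, threshold, pre = cc.segment_stack(stack, cc.SegmentationConfig())
    tracks = cc.build_tracks(label_maps)
    return stack, schedule, label_maps, threshold, pre, tracks


def run_pipeline_with_truth(stack, schedule, config=None):
    """Run the analysis once and pair each track with its true coil count.

    Returns a list of (true_count, detected_count) per matched embryo.
    """
    config = config or cc.PipelineConfig(expected_n_embryos=schedule.n_embryos)
    label_maps, threshold, pre = cc.segment_stack(stack, config.segmentation)
    tracks = cc.build_tracks(label_maps, config.max_centroid_dist_px)
    diffs = cc.difference_stack(pre)
    traces = cc.variance_trace(
        diffs, tracks, label_maps, config.diff_threshold, times_s=stack.times_s
    )
    mapping = match_tracks_to_schedule(tracks, schedule)
    pairs = []
    for tr in tracks:
        res = cc.count_stc(traces[tr.embryo_id], config.peaks, stack.duration_s)
        pairs.append((len(schedule.events[mapping[tr.embryo_id]]), res.peak_count))
    return pairs


def match_tracks_to_schedule(tracks, schedule):
    """Map track id -> schedule embryo index by nearest first-frame centroid."""
    out = {}
    for tr in tracks:
        c = tr.entries[0].centroid
        out[tr.embryo_id] = min(
            range(len(schedule.geometries)),
            key=lambda k: (schedule.geometries[k].center[0] - c[0]) ** 2
            + (schedule.geometries[k].center[1] - c[1]) ** 2,
        )
    return out
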