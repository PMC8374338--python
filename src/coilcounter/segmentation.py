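"""Embryo segmentation: preprocessing, thresholding and clump splitting.

Each frame is median-filtered and background-subtracted (rolling-ball style:
a grey opening with a disc larger than an embryo, subtracted), binarized at a
global threshold derived from the mean pixel intensity of the whole stack,
hole-filled so embryos appear completely filled, and labeled.  Touching
embryos are separated by a seeded watershed on the distance transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import block_reduce
from skimage.morphology import disk, erosion, opening
from skimage.segmentation import watershed

from .video_io import FrameStack

__all__ = [
    "SegmentationConfig",
    "LabelMap",
    "Region",
    "preprocess",
    "compute_global_threshold",
    "binarize",
    "label_embryos",
    "segment_stack",
]


@dataclass
class SegmentationConfig:
    """Tunable parameters of the segmentation stage.

    All lengths are in pixels.  ``background_radius_px`` should exceed an
    embryo diameter so the opening removes embryos from the background
    estimate; ``split_min_distance_px`` is the minimum separation of
    watershed seeds and controls how aggressively clumps are split.
    """

    median_radius_px: int = 2
    background_radius_px: int = 50
    threshold_offset: float = 0.0
    min_area_px: int = 100
    erosion_radius_px: int = 1
    split_min_distance_px: int = 10

    def __post_init__(self) -> None:
        for name in ("median_radius_px", "background_radius_px", "erosion_radius_px",
                     "split_min_distance_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")


@dataclass(frozen=True)
class Region:
    label: int
    area: int
    centroid: tuple[float, float]  # (row, col), 0-based


@dataclass
class LabelMap:
    """Integer-labeled segmentation of one frame (0 = background)."""

    labels: np.ndarray
    regions: list[Region] = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")

    @property
    def n_labels(self) -> int:
        return len(self.regions)

    def centroids(self) -> dict[int, tuple[float, float]]:
        return {r.label: r.centroid for r in self.regions}

    def mask_of(self, label: int) -> np.ndarray:
        return self.labels == label


def _rolling_background(frame: np.ndarray, radius: int) -> np.ndarray:
    """Background estimate by grey opening with a disc of ``radius``.

    For large radii the image is shrunk first (block-min), opened at the
    reduced radius, and rescaled — the classic rolling-ball speedup.  The
    returned background never exceeds the image, so subtraction is >= 0.
    """
    if radius < 16:
        bg = opening(frame, disk(max(radius, 1), decomposition="sequence"))
        return np.minimum(bg, frame)
    shrink = 4 if radius < 100 else 8
    h, w = frame.shape
    pad_h = (-h) % shrink
    pad_w = (-w) % shrink
    padded = np.pad(frame, ((0, pad_h), (0, pad_w)), mode="edge")
    small = block_reduce(padded, (shrink, shrink), np.min)
    r_small = max(1, round(radius / shrink))
    bg_small = opening(small, disk(r_small, decomposition="sequence"))
    bg = ndi.zoom(bg_small, shrink, order=1, mode="nearest")[:h, :w]
    return np.minimum(bg, frame)


def preprocess(frame: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    """Median-filter then background-subtract one frame; output in [0, 1].

    A spatially constant frame maps to (approximately) all zeros, so uniform
    illumination changes never masquerade as movement downstream.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError(f"expected a 2-D frame, got shape {frame.shape}")
    out = frame
    if config.median_radius_px > 0:
        out = ndi.median_filter(out, footprint=disk(config.median_radius_px))
    if config.background_radius_px > 0:
        out = out - _rolling_background(out, config.background_radius_px)
    return np.clip(out, 0.0, 1.0)


def compute_global_threshold(
    stack: FrameStack | np.ndarray, config: SegmentationConfig
) -> float:
    """Mean pixel intensity over all pixels of all (preprocessed) frames,
    plus ``threshold_offset``, clipped to [0, 1]."""
    frames = stack.frames if isinstance(stack, FrameStack) else np.asarray(stack)
    if frames.size == 0 or len(frames) == 0:
        raise ValueError("cannot compute a threshold from an empty stack")
    return float(np.clip(frames.mean() + config.threshold_offset, 0.0, 1.0))


def binarize(frame: np.ndarray, threshold: float) -> np.ndarray:
    """Foreground mask: intensity strictly above threshold, holes filled."""
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError(f"expected a 2-D frame, got shape {frame.shape}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    mask = frame > threshold
    return ndi.binary_fill_holes(mask)


def label_embryos(mask: np.ndarray, config: SegmentationConfig) -> LabelMap:
    """Label embryos in a binary mask, splitting touching ones.

    Clump splitting is a seeded watershed on the Euclidean distance
    transform; seeds are distance maxima separated by at least
    ``split_min_distance_px`` (shape-based splitting of roundish objects).
    Final labels are eroded by ``erosion_radius_px``, filtered by
    ``min_area_px`` and renumbered consecutively 1..K.  Deterministic.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        return LabelMap(labels=np.zeros(mask.shape, dtype=np.int32), regions=[])

    dist = ndi.distance_transform_edt(mask)
    cc, _ = ndi.label(mask)
    seed_coords = peak_local_max(
        dist,
        min_distance=max(1, config.split_min_distance_px),
        labels=cc,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(seed_coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:  # degenerate: no maxima found, keep components
        labels = cc.astype(np.int32)
    else:
        labels = watershed(-dist, markers, mask=mask).astype(np.int32)

    if config.erosion_radius_px > 0:
        eroded = erosion(mask, disk(config.erosion_radius_px))
        labels = np.where(eroded, labels, 0)

    # area filter + consecutive renumbering (ascending original label order)
    counts = np.bincount(labels.ravel())
    keep = [lab for lab in range(1, len(counts)) if counts[lab] >= config.min_area_px]
    remap = np.zeros(len(counts), dtype=np.int32)
    for new, old in enumerate(keep, start=1):
        remap[old] = new
    labels = remap[labels]

    regions: list[Region] = []
    if keep:
        centroids = ndi.center_of_mass(np.ones_like(labels), labels, range(1, len(keep) + 1))
        areas = np.bincount(labels.ravel(), minlength=len(keep) + 1)
        for new in range(1, len(keep) + 1):
            regions.append(
                Region(label=new, area=int(areas[new]),
                       centroid=(float(centroids[new - 1][0]), float(centroids[new - 1][1])))
            )
    return LabelMap(labels=labels, regions=regions)


def segment_stack(
    stack: FrameStack, config: SegmentationConfig | None = None
) -> tuple[list[LabelMap], float, np.ndarray]:
    """Preprocess and segment every frame of a stack.

    Returns ``(label_maps, threshold, preprocessed_frames)``; the threshold
    is the stack-global mean-intensity threshold actually applied.
    """
    config = config or SegmentationConfig()
    pre = np.stack([preprocess(f, config) for f in stack.frames])
    threshold = compute_global_threshold(pre, config)
    label_maps = [label_embryos(binarize(f, threshold), config) for f in pre]
    return label_maps, threshold, pre
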