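"""Synthetic dish videos with known coiling ground truth.

Emulates the acquisition scene: ~20 bright, roughly elliptical embryos
placed side by side (not superimposed) on a dark background in a 400x300 px
field, recorded for one minute.  A coil is rendered as a transient crescent
perturbation: for about a second the tail end of the ellipse (the ~25% of
its pixels beyond 0.4 of the semi-major axis) drops to background intensity,
alternating between the two ends as the tail swings — exactly the kind of
localized intensity change the variance signal responds to.  Gaussian pixel
noise and slow per-embryo drift are added.  Everything is deterministic
given the seed.

Also provides a dose-response dataset generator: per-embryo Poisson coil
counts whose rate follows a four-parameter log-logistic curve of
concentration, for parameter-recovery testing of the EC50 fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .video_io import FrameStack

__all__ = [
    "EmbryoGeometry",
    "CoilSchedule",
    "PlacementError",
    "make_schedule",
    "generate_dish_stack",
    "generate_dish_video",
    "write_video",
    "generate_dose_response_dataset",
]

FRAME_SHAPE = (300, 400)  # (rows, cols): the acquisition image size
BACKGROUND_INTENSITY = 0.04
NOISE_SIGMA = 0.01
COIL_CRESCENT_CUT = 0.4       # crescent = pixels with |u| beyond this fraction of a
COIL_DURATION_S = 1.0         # a coiling burst lasts on the order of a second
MIN_CENTER_SPACING_PX = 42.0  # embryos side by side, never superimposed
CONTROL_RATE_PER_MIN = 3.3    # untreated-control coiling rate


class PlacementError(RuntimeError):
    """The requested number of embryos cannot be packed into the frame."""


@dataclass(frozen=True)
class EmbryoGeometry:
    center: tuple[float, float]          # (row, col)
    semi_axes: tuple[float, float]       # (major, minor), px
    orientation_rad: float
    intensity: float


@dataclass
class CoilSchedule:
    """Ground truth for one synthetic dish video."""

    events: list[list[tuple[float, int]]]   # per embryo: (time_s, duration_frames)
    geometries: list[EmbryoGeometry]
    drift_px_per_frame: np.ndarray          # (n, 2) velocity per embryo
    noise_sigma: float
    seed: int
    duration_s: float
    fps: float

    def __post_init__(self) -> None:
        for evs in self.events:
            for t, dur in evs:
                if not 0 <= t <= self.duration_s:
                    raise ValueError(f"coil time {t} outside [0, {self.duration_s}]")
                if dur < 1:
                    raise ValueError("coil duration must be >= 1 frame")

    @property
    def n_embryos(self) -> int:
        return len(self.geometries)

    def counts(self) -> np.ndarray:
        """True coil count per embryo."""
        return np.array([len(e) for e in self.events])

    def to_dict(self) -> dict:
        return {
            "events": [[[t, d] for t, d in evs] for evs in self.events],
            "geometries": [asdict(g) for g in self.geometries],
            "drift_px_per_frame": self.drift_px_per_frame.tolist(),
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "duration_s": self.duration_s,
            "fps": self.fps,
        }


def _place_embryos(
    n: int, rng: np.random.Generator, frame_shape: tuple[int, int]
) -> list[EmbryoGeometry]:
    """Cluster embryos toward the dish center on a jittered grid."""
    h, w = frame_shape
    margin = 25
    sp = MIN_CENTER_SPACING_PX
    rows = max(1, int((h - 2 * margin) // sp))
    cols = max(1, int((w - 2 * margin) // sp))
    if rows * cols < n:
        raise PlacementError(
            f"cannot place {n} embryos with {sp:.0f} px spacing in a "
            f"{h}x{w} frame (capacity {rows * cols})"
        )
    r0 = (h - (rows - 1) * sp) / 2
    c0 = (w - (cols - 1) * sp) / 2
    cells = [(r0 + i * sp, c0 + j * sp) for i in range(rows) for j in range(cols)]
    # prefer central cells so the dish looks "clustered to the center"
    cr, cc = h / 2, w / 2
    cells.sort(key=lambda p: (p[0] - cr) ** 2 + (p[1] - cc) ** 2)
    chosen = cells[:n]
    geoms = []
    for (r, c) in chosen:
        jitter = rng.uniform(-4, 4, size=2)
        geoms.append(
            EmbryoGeometry(
                center=(float(r + jitter[0]), float(c + jitter[1])),
                semi_axes=(float(rng.uniform(14, 17)), float(rng.uniform(10, 12.5))),
                orientation_rad=float(rng.uniform(0, np.pi)),
                intensity=float(rng.uniform(0.70, 0.85)),
            )
        )
    return geoms


def _sample_event_times(
    count: int, duration_s: float, min_gap_s: float, rng: np.random.Generator,
) -> list[float]:
    """Event times uniform conditional on a minimum pairwise gap.

    Constructive spacing sampler: draw the slack uniformly, then re-insert
    the mandatory gaps — exact and never rejects a feasible request.
    An edge margin keeps events away from the first/last frames.
    """
    lo, hi = 1.0, duration_s - 1.5
    if count == 0:
        return []
    slack = (hi - lo) - (count - 1) * min_gap_s
    if slack < 0:
        raise ValueError(
            f"cannot fit {count} events with {min_gap_s}s gaps into {duration_s}s"
        )
    t = lo + np.sort(rng.uniform(0, slack, size=count)) + min_gap_s * np.arange(count)
    return [float(x) for x in t]


def make_schedule(
    n_embryos: int = 20,
    duration_s: float = 60.0,
    fps: float = 10.0,
    rate_per_min: float | None = None,
    counts: np.ndarray | list[int] | None = None,
    event_times: list[list[float]] | None = None,
    min_gap_s: float = 3.0,
    noise_sigma: float = NOISE_SIGMA,
    drift_speed_px_per_s: float = 0.05,
    seed: int = 0,
    frame_shape: tuple[int, int] = FRAME_SHAPE,
) -> CoilSchedule:
    """Build a ground-truth schedule.

    Coil counts come either from ``counts`` (one per embryo) or are drawn
    Poisson(``rate_per_min`` x duration/60) per embryo; event times keep a
    minimum gap of ``min_gap_s`` so individual coils stay resolvable.
    """
    rng = np.random.default_rng(seed)
    geoms = _place_embryos(n_embryos, rng, frame_shape)
    dur_frames = max(1, int(round(COIL_DURATION_S * fps)))
    if event_times is not None:
        if len(event_times) != n_embryos:
            raise ValueError("event_times must have one list per embryo")
        events = [[(float(t), dur_frames) for t in sorted(ts)] for ts in event_times]
        angles = rng.uniform(0, 2 * np.pi, size=n_embryos)
        drift = (drift_speed_px_per_s / fps) * np.column_stack(
            [np.sin(angles), np.cos(angles)]
        )
        return CoilSchedule(
            events=events, geometries=geoms, drift_px_per_frame=drift,
            noise_sigma=noise_sigma, seed=seed, duration_s=duration_s, fps=fps,
        )
    if counts is None:
        lam = 0.0 if rate_per_min is None else rate_per_min * duration_s / 60.0
        counts_arr = rng.poisson(lam, size=n_embryos)
        # physically resolvable ceiling given the minimum inter-coil gap
        max_events = int((duration_s - 2.5) // min_gap_s) + 1
        counts_arr = np.minimum(counts_arr, max(max_events, 0))
    else:
        counts_arr = np.asarray(counts, dtype=int)
        if len(counts_arr) != n_embryos:
            raise ValueError("counts must have one entry per embryo")
    events = [
        [(t, dur_frames) for t in _sample_event_times(int(c), duration_s, min_gap_s, rng)]
        for c in counts_arr
    ]
    angles = rng.uniform(0, 2 * np.pi, size=n_embryos)
    drift = (drift_speed_px_per_s / fps) * np.column_stack([np.sin(angles), np.cos(angles)])
    return CoilSchedule(
        events=events,
        geometries=geoms,
        drift_px_per_frame=drift,
        noise_sigma=noise_sigma,
        seed=seed,
        duration_s=duration_s,
        fps=fps,
    )


def _ellipse_masks(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    theta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean ellipse mask and the major-axis coordinate u of each pixel.

    Evaluated on a local window around the embryo for speed.
    """
    h, w = shape
    a, b = semi_axes
    r0, c0 = center
    half = int(np.ceil(max(a, b))) + 2
    rlo, rhi = max(0, int(r0) - half), min(h, int(r0) + half + 1)
    clo, chi = max(0, int(c0) - half), min(w, int(c0) + half + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr, dc = rr - r0, cc - c0
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    local = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask = np.zeros(shape, dtype=bool)
    mask[rlo:rhi, clo:chi] = local
    u_full = np.zeros(shape)
    u_full[rlo:rhi, clo:chi] = u
    return mask, u_full


def render_frame(
    schedule: CoilSchedule, frame_index: int, frame_shape: tuple[int, int],
    noise: np.ndarray | None = None,
) -> np.ndarray:
    """Render one frame of the dish (without noise unless provided)."""
    img = np.full(frame_shape, BACKGROUND_INTENSITY)
    for k, g in enumerate(schedule.geometries):
        dr, dc = schedule.drift_px_per_frame[k] * frame_index
        coil_side = None
        for ev_t, ev_dur in schedule.events[k]:
            offset = frame_index - int(round(ev_t * schedule.fps))
            if 0 <= offset < ev_dur:
                coil_side = offset % 2  # tail swings between the two ends
                break
        mask, u = _ellipse_masks(
            frame_shape, (g.center[0] + dr, g.center[1] + dc), g.semi_axes,
            g.orientation_rad,
        )
        img[mask] = g.intensity
        if coil_side is not None:
            a = g.semi_axes[0]
            cut = COIL_CRESCENT_CUT * a
            crescent = mask & ((u > cut) if coil_side == 0 else (u < -cut))
            img[crescent] = BACKGROUND_INTENSITY
    if noise is not None:
        img = img + noise
    return np.clip(img, 0.0, 1.0)


def generate_dish_stack(
    schedule: CoilSchedule, frame_shape: tuple[int, int] = FRAME_SHAPE
) -> FrameStack:
    """Render the full schedule into a FrameStack at the schedule's fps."""
    n_frames = int(round(schedule.duration_s * schedule.fps))
    rng = np.random.default_rng(schedule.seed + 1)  # noise stream, decoupled
    frames = np.empty((n_frames, *frame_shape))
    for i in range(n_frames):
        noise = (
            rng.normal(0.0, schedule.noise_sigma, size=frame_shape)
            if schedule.noise_sigma > 0
            else None
        )
        frames[i] = render_frame(schedule, i, frame_shape, noise)
    return FrameStack(
        frames=frames,
        times_s=np.arange(n_frames) / schedule.fps,
        source_id=f"synthetic_seed{schedule.seed}",
        duration_s=schedule.duration_s,
        sample_rate_fpm=schedule.fps * 60.0,
    )


def generate_dish_video(
    n_embryos: int = 20,
    duration_s: float = 60.0,
    fps_native: float = 10.0,
    schedule: CoilSchedule | None = None,
    rate_per_min: float | None = None,
    counts=None,
    seed: int = 0,
    frame_shape: tuple[int, int] = FRAME_SHAPE,
    **schedule_kwargs,
) -> tuple[FrameStack, CoilSchedule]:
    """Generate a dish recording and return (stack, ground-truth schedule)."""
    if schedule is None:
        schedule = make_schedule(
            n_embryos=n_embryos,
            duration_s=duration_s,
            fps=fps_native,
            rate_per_min=rate_per_min,
            counts=counts,
            seed=seed,
            frame_shape=frame_shape,
            **schedule_kwargs,
        )
    return generate_dish_stack(schedule, frame_shape), schedule


def write_video(stack: FrameStack, path) -> None:
    """Write a stack as a video file.

    GIF is always available; AVI/MP4 require an ffmpeg-capable imageio
    plugin.  GIF stores 8-bit grayscale losslessly, so the analysis chain is
    unaffected by the container.
    """
    import imageio.v3 as iio
    from pathlib import Path

    path = Path(path)
    frames8 = np.round(np.clip(stack.frames, 0, 1) * 255).astype(np.uint8)
    fps = stack.sample_rate_fpm / 60.0
    if path.suffix.lower() == ".gif":
        iio.imwrite(path, frames8, duration=1000.0 / fps, loop=0)
    else:
        iio.imwrite(path, frames8, fps=fps)


def four_pl_fraction(conc: np.ndarray, ec50: float, slope: float,
                     max_effect_frac: float = 0.0) -> np.ndarray:
    """Response fraction of the control rate under a 4PL curve.

    1 at zero concentration, ``max_effect_frac`` at saturation, inflection at
    ``ec50``.  ``slope == 0`` is the no-effect limit (fraction 1 everywhere).
    """
    conc = np.asarray(conc, dtype=float)
    if slope == 0:
        return np.ones_like(conc)
    frac = np.ones_like(conc)
    pos = conc > 0
    frac[pos] = 1 + (max_effect_frac - 1) / (1 + (ec50 / conc[pos]) ** slope)
    return frac


def generate_dose_response_dataset(
    ec50: float,
    slope: float,
    concentrations,
    control_rate: float = CONTROL_RATE_PER_MIN,
    n_embryos: int = 20,
    n_replicates: int = 2,
    max_effect_frac: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-embryo Poisson coil counts across concentrations plus the truth.

    Concentration 0 rows are the untreated controls.  The design default
    (7 concentrations x 2 replicates x 20 embryos, control rate 3.3/min)
    mirrors a typical coiling concentration-response experiment.
    """
    concentrations = np.asarray(sorted(concentrations), dtype=float)
    if np.any(concentrations < 0):
        raise ValueError("concentrations must be non-negative")
    if 0.0 not in concentrations:
        concentrations = np.concatenate([[0.0], concentrations])
    rng = np.random.default_rng(seed)
    rows = []
    for conc in concentrations:
        frac = float(four_pl_fraction(np.array([conc]), ec50, slope, max_effect_frac)[0])
        lam = max(control_rate * frac, 0.0)
        for rep in range(n_replicates):
            freqs = rng.poisson(lam, size=n_embryos)
            for emb, f in enumerate(freqs):
                rows.append((conc, rep, emb, float(f)))
    table = pd.DataFrame(
        rows, columns=["concentration", "replicate", "embryo_id", "frequency_per_min"]
    )
    truth = {
        "ec50": ec50,
        "slope": slope,
        "control_rate": control_rate,
        "max_effect_frac": max_effect_frac,
    }
    return table, truth
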