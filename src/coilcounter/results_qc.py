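"""Dish-level results, QC, correction artifacts, and dose-response fitting.

This stage compiles per-embryo coiling results into a dish summary, raises
internal-control flags when the image analysis looks wrong (so the user can
re-run with an adjusted threshold or tracking gate), exports the two-sheet
workbook and CSV mirrors used for the manual correction protocol, and fits a
four-parameter log-logistic (4PL) concentration-response curve to
control-normalized coiling frequencies to estimate EC50 and EC10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .peak_analysis import StcResult
from .segmentation import LabelMap
from .tracking import EmbryoTrack

__all__ = [
    "QcFlag",
    "DishResult",
    "DoseResponseFit",
    "check_for_errors",
    "compile_dish",
    "export_results",
    "read_results_csv",
    "compare_auto_vs_corrected",
    "normalize_to_control",
    "fit_concentration_response",
    "shapiro_test",
    "bartlett_test",
    "kruskal_test",
]

ID_OFFSET_NOTE = (
    "Embryo ids are 0-based in tables; annotated images use 1-based labels "
    "(table id 0 == image label 1)."
)


@dataclass(frozen=True)
class QcFlag:
    kind: str
    message: str
    frames: tuple[int, ...] = ()
    suggestion: str = ""


@dataclass
class DishResult:
    """Compiled per-dish analysis output."""

    source_id: str
    stc_results: list[StcResult]
    threshold_used: float
    flags: list[QcFlag] = field(default_factory=list)
    duration_s: float = 60.0

    @property
    def n_embryos_analyzed(self) -> int:
        return len(self.stc_results)

    @property
    def mean_frequency_per_min(self) -> float:
        if not self.stc_results:
            return float("nan")
        return float(np.mean([r.frequency_per_min for r in self.stc_results]))

    def frequencies(self) -> np.ndarray:
        return np.array([r.frequency_per_min for r in self.stc_results])


def compile_dish(
    source_id: str,
    stc_results: Sequence[StcResult],
    threshold_used: float,
    flags: Sequence[QcFlag] = (),
    duration_s: float = 60.0,
) -> DishResult:
    return DishResult(
        source_id=source_id,
        stc_results=list(stc_results),
        threshold_used=threshold_used,
        flags=list(flags),
        duration_s=duration_s,
    )


def check_for_errors(
    tracks: Sequence[EmbryoTrack],
    label_maps: Sequence[LabelMap],
    expected_n: int = 20,
) -> list[QcFlag]:
    """Internal control: diagnostics that the image analysis went wrong.

    Flags (never errors): per-frame label counts deviating > 10% from their
    median, tracks covering < 90% of frames, and a track count different
    from the expected dish occupancy.  Each flag carries a suggested remedy
    (adjust the global threshold offset or the centroid gate).
    """
    flags: list[QcFlag] = []
    n_frames = len(label_maps)
    counts = np.array([lm.n_labels for lm in label_maps])
    med = float(np.median(counts)) if n_frames else 0.0
    if med > 0:
        bad = np.nonzero(np.abs(counts - med) > 0.1 * med)[0]
        if bad.size:
            flags.append(
                QcFlag(
                    kind="label_count",
                    message=(
                        f"label count deviates >10% from the median ({med:g}) "
                        f"in {bad.size} frame(s)"
                    ),
                    frames=tuple(int(b) for b in bad[:50]),
                    suggestion="adjust SegmentationConfig.threshold_offset and re-run",
                )
            )
    for tr in tracks:
        cov = tr.coverage(n_frames)
        if cov < 0.9:
            flags.append(
                QcFlag(
                    kind="track_coverage",
                    message=(
                        f"embryo {tr.embryo_id} observed in only {cov:.0%} of frames"
                    ),
                    frames=(tr.first_frame, tr.last_entry.frame_index),
                    suggestion=(
                        "adjust threshold_offset or max_centroid_dist_px and re-run"
                    ),
                )
            )
    if len(tracks) != expected_n:
        flags.append(
            QcFlag(
                kind="track_count",
                message=f"found {len(tracks)} tracks, expected {expected_n}",
                suggestion="check segmentation threshold; embryos may be merged or lost",
            )
        )
    return flags


def _raw_data_frame(dish: DishResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "embryo_id": [r.embryo_id for r in dish.stc_results],
            "peak_count": [r.peak_count for r in dish.stc_results],
            "frequency_per_min": [r.frequency_per_min for r in dish.stc_results],
            "peak_indices": [
                ";".join(str(int(i)) for i in r.peak_indices) for r in dish.stc_results
            ],
        }
    )


def export_results(dish: DishResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the workbook and CSV mirrors for one dish.

    The workbook (named after the video stem) has the two sheets of the
    reference layout: sheet "default" with the embryo labels, the number of
    embryos analyzed and the threshold used; sheet "Raw data" with per-embryo
    peak indices, counts and frequencies.  CSV mirrors round-trip exactly.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc
    stem = dish.source_id
    raw = _raw_data_frame(dish)
    default_sheet = pd.DataFrame(
        {
            "embryo_id": [r.embryo_id for r in dish.stc_results],
            "n_embryos_analyzed": dish.n_embryos_analyzed,
            "threshold": dish.threshold_used,
        }
    )

    xlsx = out_dir / f"{stem}.xlsx"
    with pd.ExcelWriter(xlsx, engine="openpyxl") as writer:
        default_sheet.to_excel(writer, sheet_name="default", index=False, startrow=1)
        raw.to_excel(writer, sheet_name="Raw data", index=False, startrow=1)
        for name in ("default", "Raw data"):
            writer.sheets[name].cell(row=1, column=1, value=ID_OFFSET_NOTE)

    results_csv = out_dir / f"{stem}_results.csv"
    raw.to_csv(results_csv, index=False)
    traces_csv = out_dir / f"{stem}_traces.csv"
    trace_rows = []
    for r in dish.stc_results:
        for t, (v, s) in enumerate(zip(r.raw_trace, r.smoothed_trace)):
            trace_rows.append((r.embryo_id, t, v, s))
    pd.DataFrame(
        trace_rows, columns=["embryo_id", "transition_index", "variance", "smoothed"]
    ).to_csv(traces_csv, index=False)
    return {"xlsx": xlsx, "results_csv": results_csv, "traces_csv": traces_csv}


def read_results_csv(path: str | Path) -> pd.DataFrame:
    """Read back a ``*_results.csv``; frequencies reproduce exactly."""
    df = pd.read_csv(path)
    df["peak_indices"] = df["peak_indices"].fillna("")
    return df


def compare_auto_vs_corrected(
    auto: Sequence[float], corrected: Sequence[float]
) -> dict:
    """Paired comparison of automated vs manually corrected per-dish means.

    Returns per-dish differences (auto - corrected), agreement counts, and a
    Wilcoxon signed-rank p-value (the paired nonparametric choice).  With a
    single pair the test is skipped with a warning; identical vectors give
    p = 1 by convention.
    """
    auto = np.asarray(auto, dtype=float)
    corrected = np.asarray(corrected, dtype=float)
    if auto.shape != corrected.shape:
        raise ValueError("auto and corrected must have equal length")
    diff = auto - corrected
    out = {
        "differences": diff,
        "n_agree": int(np.sum(diff == 0)),
        "n_auto_higher": int(np.sum(diff > 0)),
        "n_corrected_higher": int(np.sum(diff < 0)),
        "p_value": np.nan,
    }
    if len(diff) < 2:
        warnings.warn("need at least 2 pairs for a signed-rank test; skipped",
                      stacklevel=2)
        return out
    if np.all(diff == 0):
        out["p_value"] = 1.0
        return out
    nz = diff[diff != 0]
    method = "exact" if len(nz) <= 25 else "auto"
    res = stats.wilcoxon(nz, method=method)
    out["p_value"] = float(res.pvalue)
    return out


def normalize_to_control(
    treatment_means: Sequence[float], control_mean: float
) -> np.ndarray:
    """Express coiling frequencies as a percentage of the untreated control."""
    if control_mean <= 0:
        raise ValueError("control_mean must be positive")
    return np.asarray(treatment_means, dtype=float) * 100.0 / control_mean


def _four_pl(logc: np.ndarray, bottom: float, top: float, log_ec50: float,
             hill: float) -> np.ndarray:
    """4PL response at log-concentration; top is the low-dose asymptote for
    hill > 0."""
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (logc - log_ec50)))


@dataclass
class DoseResponseFit:
    """Fitted 4PL concentration-response curve on %-of-control responses."""

    concentrations: np.ndarray
    responses_pct: np.ndarray
    bottom: float
    top: float
    hill: float
    ec50: float
    ec10: float | None
    direction: str  # "hyperactivity" | "hypoactivity" | "no_effect"
    flags: list[str] = field(default_factory=list)

    def predict(self, conc) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return _four_pl(np.log(conc), self.bottom, self.top,
                        np.log(self.ec50), self.hill)

    @property
    def anchor(self) -> float:
        """Control-side (low-dose) asymptote."""
        return self.top if self.hill > 0 else self.bottom

    @property
    def far_asymptote(self) -> float:
        return self.bottom if self.hill > 0 else self.top


class FitError(RuntimeError):
    """4PL optimization failed to converge."""


def fit_concentration_response(
    concentrations: Sequence[float],
    normalized_pct: Sequence[float],
    no_effect_span_pct: float = 5.0,
) -> DoseResponseFit:
    """Least-squares 4PL fit of %-of-control responses vs concentration.

    Points at concentration 0 (controls) anchor the low-dose asymptote
    initialization but only strictly positive concentrations enter the
    log-concentration fit.  EC50 is the fitted inflection; EC10 is found by
    root-finding where the curve crosses 90% (hypoactivity) or 110%
    (hyperactivity) of the control-side asymptote.  A fitted span smaller
    than ``no_effect_span_pct`` points is reported as no effect.
    """
    conc = np.asarray(concentrations, dtype=float)
    pct = np.asarray(normalized_pct, dtype=float)
    if conc.shape != pct.shape:
        raise ValueError("concentrations and responses must have equal length")
    pos = conc > 0
    if np.unique(conc[pos]).size < 3:
        raise ValueError("need at least 3 distinct positive concentrations")
    anchor0 = float(pct[~pos].mean()) if (~pos).any() else 100.0
    logc = np.log(conc[pos])
    y = pct[pos]

    flags: list[str] = []
    span0 = float(y.max() - y.min())
    if span0 < no_effect_span_pct and abs(anchor0 - y.mean()) < no_effect_span_pct:
        return DoseResponseFit(
            concentrations=conc, responses_pct=pct,
            bottom=float(y.mean()), top=float(y.mean()), hill=0.0,
            ec50=float("nan"), ec10=None, direction="no_effect",
            flags=["no_effect: response span below threshold"],
        )

    def residuals(params):
        bottom, top, log_ec50, hill = params
        return _four_pl(logc, bottom, top, log_ec50, hill) - y

    # try both directions; keep the better least-squares solution
    lo_y, hi_y = float(np.min(y)), float(np.max(y))
    best = None
    for hill0 in (2.0, -2.0):
        p0 = [lo_y if hill0 > 0 else anchor0,
              anchor0 if hill0 > 0 else hi_y,
              float(np.median(logc)), hill0]
        try:
            sol = optimize.least_squares(
                residuals, p0,
                bounds=([-50, -50, logc.min() - 14, -50],
                        [500, 500, logc.max() + 14, 50]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError(
            f"4PL fit did not converge on {np.unique(conc[pos]).size} concentrations; "
            f"response span {span0:.1f}%"
        )
    bottom, top, log_ec50, hill = best.x
    ec50 = float(np.exp(log_ec50))
    anchor = top if hill > 0 else bottom
    far = bottom if hill > 0 else top

    if abs(far - anchor) < no_effect_span_pct:
        direction = "no_effect"
        flags.append("no_effect: fitted span below threshold")
        ec50 = float("nan")
    else:
        direction = "hyperactivity" if far > anchor else "hypoactivity"

    if np.isfinite(ec50) and not (conc[pos].min() <= ec50 <= conc[pos].max()):
        flags.append("ec50_extrapolated: EC50 outside the tested range")

    # monotonicity check on group means (diagnostic only)
    order = np.argsort(conc[pos])
    grp = pd.Series(y[order]).groupby(conc[pos][order]).mean().to_numpy()
    d = np.diff(grp)
    if len(d) and not (np.all(d <= 0) or np.all(d >= 0)):
        flags.append("nonmonotone: group means are not monotone in concentration")

    ec10 = None
    if direction != "no_effect":
        level = 0.9 * anchor if direction == "hypoactivity" else 1.1 * anchor
        f = lambda lc: _four_pl(np.array([lc]), bottom, top, log_ec50, hill)[0] - level
        lo, hi = log_ec50 - 20, log_ec50 + 20
        try:
            if f(lo) * f(hi) < 0:
                ec10 = float(np.exp(optimize.brentq(f, lo, hi, xtol=1e-12)))
            else:
                flags.append("ec10_undefined: curve never crosses the 10% level")
        except Exception:
            flags.append("ec10_undefined: root finding failed")
        if ec10 is not None and not (conc[pos].min() <= ec10 <= conc[pos].max()):
            flags.append("ec10_extrapolated: EC10 outside the tested range")

    return DoseResponseFit(
        concentrations=conc, responses_pct=pct,
        bottom=float(bottom), top=float(top), hill=float(hill),
        ec50=ec50, ec10=ec10, direction=direction, flags=flags,
    )


# ---------------------------------------------------------------------------
# Thin hypothesis-test wrappers (standard tests, alpha = 0.05 convention)

def shapiro_test(values) -> tuple[float, float]:
    res = stats.shapiro(np.asarray(values, dtype=float))
    return float(res.statistic), float(res.pvalue)


def bartlett_test(*groups) -> tuple[float, float]:
    res = stats.bartlett(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)


def kruskal_test(*groups) -> tuple[float, float]:
    res = stats.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)
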