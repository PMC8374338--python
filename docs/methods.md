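# Methods

`coilcounter` quantifies spontaneous tail coiling (STC) — the earliest motor
behavior of zebrafish embryos, ~17–25 hours post fertilization — from fixed-
camera video of a dish of embryos. The endpoint is the per-embryo coiling
frequency per minute, the dish mean, and, across chemical concentrations,
a four-parameter log-logistic (4PL) concentration-response fit yielding EC50
and EC10. This note documents the model behind each stage, the parameters
that matter, what the synthetic fixtures do and do not emulate, and the
numerical choices made where the design was open.

## Pipeline model

**Frame extraction.** Videos are resampled to a uniform grid of
`sample_rate_fpm` frames per minute (default 120, i.e. 2 Hz). Frame *i*
carries time `i·60/sample_rate_fpm` s; for each target time the nearest
native frame is taken, no native frame is used twice (requires the requested
rate not to exceed the native rate), and a trailing remainder that does not
fill a whole sampling step is truncated rather than padded. Intensities are
normalized by the dtype maximum of the decoded frames so thresholds are
comparable across 8-bit and 16-bit sources; color input is collapsed to
Rec. 601 luma. Decoding goes through imageio: animated GIF always works
(8-bit grayscale round-trips losslessly), AVI/MP4 work wherever an
ffmpeg-capable imageio plugin is installed. Pre-extracted PNG stack
directories with a `stack.json` sidecar are an equivalent input.

**Segmentation.** Each frame is median-filtered (disc radius
`median_radius_px`, default 2 px) and background-subtracted by a rolling-ball
estimate: a grey opening with a disc of `background_radius_px` (default
50 px, chosen to exceed an embryo diameter so embryos cannot leak into the
background estimate). For large radii the opening runs on a block-minimum
shrunken image and is rescaled — the classic rolling-ball speedup; the
background is clamped below the image so the subtraction is non-negative.
A known limitation of any morphological background estimate is a border band
up to one disc radius wide where an intensity ramp is not fully removed;
embryos are clustered to the dish center, so this does not affect the
analysis region. The global binarization threshold is the mean pixel
intensity over all pixels of all preprocessed frames plus a user
`threshold_offset` (default 0), clipped to [0, 1]. This stack-mean threshold
presumes a typical dish occupancy (~20 embryos ≈ 9% foreground); for very
sparse scenes (one embryo) the mean sits near the noise floor and
`threshold_offset` must be raised — this is the adjustment knob the method
itself exposes. Foreground holes are filled so embryos are completely
filled, touching embryos are split by a seeded watershed on the Euclidean
distance transform (seeds are distance maxima at least
`split_min_distance_px` = 10 px apart), each label is eroded by
`erosion_radius_px` = 1 px, labels under `min_area_px` = 100 px (debris
guard) are dropped, and labels are renumbered 1..K. Segmentation is fully
deterministic.

**Tracking.** Embryo identity is maintained by greedy minimum-distance
matching of label centroids between consecutive frames with a hard inclusive
gate of `max_centroid_dist_px` = 15 px: 15 px still matches, 16 px opens a
new identity. Greedy matching (candidate pairs sorted by distance, ties by
label ids) coincides with the optimal assignment for well-separated embryos
and is deterministic. A track that loses its label may re-join through the
same gate for one missing frame; after that a new identity is opened. Track
ids are 0-based in all tables and 1-based in annotated images.

**Motion signal.** Movement is the variance of gray values of the
frame-to-frame difference image within each embryo's label. Differences are
absolute (a coiling tail both brightens and darkens pixels). Pixels below
`diff_threshold` (default 0.02 ≈ 5/255) are zeroed but kept in the pixel
population, and the population variance (ddof = 0) is reported — a coil
changes a sub-region of the label, producing a Bernoulli-mixture variance
f(1−f)Δ² for a fraction f of pixels changing by Δ. The label region of the
earlier frame of each transition is used (drift between two frames is
bounded by the tracking gate). Missing observations yield NaN, never zero.
A spatially uniform illumination step is removed by background subtraction
and, being constant within a label, contributes no variance either way.

**Peak analysis.** Traces (length n_frames − 1) are smoothed with a
weighted running mean: window `max(3, round(smoothing_span · length))`
forced odd (span default 0.1 → window 13 on a one-minute trace), Gaussian
weights with σ = (window − 1)/8 truncated to the window, edges handled by
replication so constants are preserved exactly; NaNs are linearly
interpolated first with ends held. The Gaussian weighting is a deliberate
choice over a flat boxcar: a flat 13-wide window provably merges any two
coils closer than ~6.5 s into a single plateau (the sum of two offset
boxcars has one maximal plateau), whereas the σ = 1.5 kernel resolves
events 3 s apart while still flattening single-transition noise blips below
the peak threshold. Peaks are then found with the drop criterion of
quantmod's `findPeaks`: index *i* is a peak iff
`v[i] > v[i−1]`, `v[i] > v[i+1]`, and the post-peak drop
`v[i] − v[i+1]` strictly exceeds `peak_threshold` (default 0.003). Plateaus
are not peaks and endpoints are never peaks. We report the local-maximum
index itself rather than quantmod's bar-after-the-turn index; counts are
unchanged. Surviving maxima closer than 2 transitions are merged keeping
the higher (a guard against double-counting fast multiple coils; for strict
maxima this is almost always a no-op). Finally
`frequency_per_min = peak_count · 60 / duration_s` exactly.

**QC and correction artifacts.** The internal-control check flags (a)
frames whose label count deviates more than 10% from the per-video median,
(b) tracks observed in under 90% of frames, and (c) a track count different
from the expected dish occupancy (default 20); each flag suggests the
remedy the method prescribes (adjust `threshold_offset` or the centroid
gate and re-run). Exports per video: a workbook named after the video stem
with sheet `default` (labels, number analyzed, threshold) and sheet
`Raw data` (per-embryo peak indices, counts, frequencies), CSV mirrors that
round-trip exactly, an annotated first frame (1-based labels at centroids),
and per-embryo peak plots showing smoothed and unsmoothed traces with
dashed lines at peaks — the artifacts the manual correction protocol needs.
Automated-vs-corrected dish means are compared with a paired Wilcoxon
signed-rank test (exact for ≤25 non-zero differences; identical vectors
report p = 1; a single pair is skipped with a warning).

**Concentration-response.** Group frequencies are normalized to the
untreated control (×100/control mean). The 4PL curve
`y = bottom + (top − bottom) / (1 + exp(hill·(log c − log EC50)))`
is fitted by bounded least squares on log-concentration over the treated
groups, initialized from the control-side level and tried with both slope
signs; EC50 is the fitted inflection (flagged when outside the tested
range). Direction is hyperactivity when the far asymptote exceeds the
control-side asymptote, hypoactivity otherwise; a fitted span under 5
percentage points is reported as no effect with EC50 undefined. EC10 is
found by root-finding where the curve crosses 90% (hypoactivity) or 110%
(hyperactivity) of the control-side asymptote — a curve-relative
definition, stated explicitly because several conventions exist.
Shapiro/Bartlett/Kruskal-Wallis are exposed only as thin scipy wrappers
(α = 0.05 convention).

## Synthetic fixtures

The generator emulates the acquisition scene: a 400×300 px field, ~20
bright ellipses (semi-axes ~14–17 × 10–12.5 px, intensity 0.70–0.85) on a
dark background (0.04), clustered toward the center on a jittered grid with
≥42 px center spacing so embryos sit side by side without touching, slow
per-embryo drift (0.05 px/s), and Gaussian pixel noise (σ = 0.01). A coil
is rendered as a transient crescent perturbation: for about one second the
~25% of the embryo's pixels beyond 0.4 of the semi-major axis drop to
background intensity, alternating between the two ends as the tail swings.
This produces exactly the asymmetric two-transition variance signature a
real coil produces in the intensity-based signal. Event times are sampled
uniformly conditional on a minimum gap (default 3 s, the resolvability
limit of the default smoothing) by the exact spacing construction, and
rate-driven schedules draw Poisson counts capped at the resolvable ceiling.
Everything is a deterministic function of the seed.

What the fixtures do **not** emulate: chorion optics, photorealistic embryo
texture, kinematic tail articulation, burst substructure, debris, uneven
illumination beyond what background subtraction removes, and embryo-embryo
contact. Passing the recovery tests therefore demonstrates that the
algorithmic chain is correct under the stated scene model, not that real
recordings will segment equally cleanly; on real data the threshold offset
and gate may need the adjustments the QC flags suggest.

The dose-response generator draws per-embryo Poisson coil counts at rate
`3.3/min × 4PL(c)` (control rate 3.3/min; response fraction 1 at c = 0,
`max_effect_frac` at saturation, inflection at the true EC50; zero slope is
treated as the no-effect limit, fraction ≡ 1).

## Problem sizes and numerical choices

Test and acceptance runs use: one-minute dishes of 20 embryos for the
full-condition checks; 10 seeded dishes (200 embryos) for count recovery;
1,000 random length-120 traces for the peak-detection oracle; 100 simulated
experiments at the 7-concentration × 2-replicate × 20-embryo design for
EC50 recovery. Smaller 4–8 embryo dishes back the unit tests. End-to-end
recovery dishes are rendered directly at the 2 Hz analysis grid; the
extraction path (native 10 fps video → 120 frames/min sampling) is
exercised separately by the video-container tests and the worked example.

Numerical conventions worth knowing: coordinates are (row, col), 0-based,
pixel units; population variance throughout; the tracking gate is
inclusive; thresholds compare strictly (`>`); watershed seed order and
greedy-match tie-breaks are fixed so identical input yields identical
output; the stack-mean threshold is clipped to [0, 1]; the 4PL fit uses
log-EC50 internally with wide bounds and tight (1e-12) tolerances, which
recovers noiseless parameters to ≤1e-6 relative error.

## Known limitations

- The variance signal counts events; it does not measure burst duration,
  amplitude, or kinematics, and cannot separate a genuine double coil from
  two closely spaced single coils closer than the smoothing resolution.
- Whole-embryo displacement (not just tail motion) also raises variance;
  the QC artifacts surface such peaks for manual correction, the pipeline
  does not adjudicate them.
- The stack-mean threshold assumes the usual dish occupancy; single-embryo
  or near-empty scenes need a positive `threshold_offset`.
- EC10 is defined relative to the control-side asymptote of the fitted
  curve; other software may define it relative to the fitted span, which
  gives different values for partial-effect curves.
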