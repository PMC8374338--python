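# coilcounter

Automated quantification of **spontaneous tail coiling (STC)** in zebrafish
embryos from video. STC — brief tail flips of the embryo inside its chorion
at ~17–25 hours post fertilization — is the earliest motor behavior of the
zebrafish and a sensitive behavioral endpoint for developmental
neurotoxicity screening: chemicals that excite the nervous system raise the
coiling frequency (hyperactivity), inhibitors lower it (hypoactivity).

Counting coils by eye is slow and subjective. `coilcounter` turns a
one-minute fixed-camera recording of a dish of ~20 embryos into per-embryo
coiling frequencies automatically:

1. **Frame extraction** — the video is resampled to 120 frames/min and
   converted to normalized grayscale.
2. **Segmentation** — median filter, rolling-ball background subtraction,
   a global threshold from the stack-mean intensity, hole filling, and
   watershed clump splitting label each embryo `1..K` per frame.
3. **Tracking** — label centroids are chained across frames by greedy
   nearest-neighbor matching with a 15 px gate.
4. **Motion signal** — for each embryo, the variance of the thresholded
   frame-difference pixels inside its label, one value per transition; a
   coil appears as a spike of within-label variance.
5. **Peak analysis** — the trace is smoothed (window = 0.1 of the trace
   length, Gaussian-weighted) and peaks are called with a drop threshold of
   0.003 (quantmod `findPeaks` semantics):
   `frequency/min = peaks × 60 / duration`.
6. **Results & QC** — per-dish workbook and CSVs, annotated label images
   and peak plots for the manual correction protocol, internal-control
   flags, normalization to untreated controls, and a four-parameter
   log-logistic (4PL) concentration-response fit

   `y(c) = bottom + (top − bottom) / (1 + exp(hill·(log c − log EC50)))`

   giving EC50 and EC10 relative to the control asymptote.

A fully deterministic synthetic-dish generator (bright ellipses, scheduled
crescent "coils", noise, drift) provides ground truth for every stage, so
the whole chain is testable without laboratory recordings.

## Worked example

```bash
# render a synthetic one-minute dish of 20 embryos coiling at 3.3/min
coilcounter simulate --out demo/dish.gif --n-embryos 20 --duration 60 \
    --fps 10 --rate 3.3 --seed 1

# analyze every video in the folder
coilcounter analyze demo --out demo/results
```

The analysis prints one line per video:

```
dish: 20 embryos, mean STC 3.85/min, 0 flag(s)
```

meaning all 20 embryos were segmented and tracked, their mean coiling
frequency was 3.85 per minute (the dish was simulated at a control-like
3.3/min; the realized Poisson schedule for this seed contains 77 coils =
a true mean of 3.85/min, so the pipeline recovered every one), and no
internal-control flag was raised. `demo/results/` then contains `dish.xlsx` (sheet
`default`: labels, n analyzed, threshold; sheet `Raw data`: per-embryo
peak indices, counts, frequencies), CSV mirrors, `dish_labels.png`
(annotated embryos, 1-based in images, 0-based in tables) and per-embryo
peak plots.

The same pipeline is available as a library:

```python
import coilcounter as cc

stack, truth = cc.generate_dish_video(n_embryos=20, duration_s=60,
                                      rate_per_min=3.3, seed=1)
dish = cc.analyze_stack(stack, cc.PipelineConfig())
print(dish.mean_frequency_per_min, truth.counts())
```

For concentration-response data (`concentration,frequency_per_min` CSV with
concentration 0 = controls):

```bash
coilcounter doseresponse freqs.csv --out results
```

which reports the fitted direction (hyper-/hypoactivity), EC50, EC10, and
the fitted 4PL parameters.

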