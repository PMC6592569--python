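# pixflow

Per-pixel trace-matching ("pixel intensity cross-correlation") velocimetry
for capillary-scale flow in registered high-frame-rate video, with its full
pre/post-processing pipeline, simplified PIV and spatiotemporal-kymograph
baselines, network flow statistics, and a synthetic flow-phantom generator
with ground truth.

## How it works

For each pixel of a 100 ms analysis epoch, the temporal intensity trace is
compared (RMS difference) against the one-frame forward- and
backward-shifted traces of every other candidate pixel. The best match marks
the destination/source of the flowing material; its displacement divided by
the inter-frame period is the speed. Static background structure is removed
by subtracting the standardized temporal-standard-deviation map from the
standardized RMS map; winners are gated by a physiological speed cap
(4.5 mm/s) and a Bonferroni-corrected one-tailed significance threshold
(p = 0.025 over the candidate pixels). Forward and backward estimates are
averaged (or the stronger one kept).

## Layout

| module | role |
| --- | --- |
| `pixflow.phantom` | synthetic vessels, pulsatile plug-flow cell trains, rendering, ground truth |
| `pixflow.preprocess` | frame-mean normalisation, rolling-mean subtraction, detrend + Fourier filter, motion contrast, epoch splitting |
| `pixflow.vesselmask` | single-scale Frangi vesselness, Otsu mask, skeleton segments, disjoint labels |
| `pixflow.pix_core` | the velocimetry algorithm (similarity maps, normalisation, gating, speed maps) |
| `pixflow.baselines` | simplified PIV (tiered block correlation) and STK (kymograph slope sweep) |
| `pixflow.metrics` | segment filling, per-segment traces, pulsatility index, goodness of fit, field-average correlation, CTT/CTTH |
| `pixflow.cli` | `pixflow` command-line interface |

## CLI

```sh
# generate a pulsatile single-vessel phantom with ground truth
pixflow phantom --out out/phantom --duration 1.0 --mean-velocity 1.0 \
    --pulsatility-depth 0.25 --seed 1

# velocimetry on a sequence (TIFF/AVI + fps/pixel size via sidecar or flags)
pixflow run --input out/phantom/sequence.tif --out out/vel \
    --mask out/phantom/mask.tif --epoch-ms 100 --step-ms 50 --vmax 4.5 --p 0.025

# baselines and metrics
pixflow piv --input out/phantom/sequence.tif --out out/piv
pixflow stk --input out/phantom/sequence.tif --out out/stk
pixflow metrics --velocity-dir out/vel --labels out/msk/labels.tif \
    --segments out/msk/segments.csv --out out/stats

# end-to-end phantom demo
pixflow demo --out out/demo --seed 1
```

Defaults follow the standard parameter set: 1 μm pixels, 100 ms epochs
stepped by 50 ms, 5 μm vesselness scale and segment dilation, 25 μm minimum
segment length, 4.5 mm/s speed cap, p = 0.025; PIV uses 12 μm templates with
18/30/36 μm search tiers capped at 2.25/3.75/4.5 mm/s and a 0.3 mm/s floor.

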