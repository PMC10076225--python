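# axotrace

Detection, tracking, separation and fluorescence extraction of axonal
regions of interest (ROIs) in two-photon recordings — for experiments that
image a bundle of axons in cross-section (for example ascending neurons
passing through the fly cervical connective) with a green activity indicator
(GCaMP) and a red anatomical marker (tdTomato).

Movement of the behaving animal translates and deforms the imaged tissue
from frame to frame, and several axons may touch and segment as one region.
`axotrace` turns a raw two-channel image stack into per-axon ΔF/F and ΔR/R
time series by running four stages:

1. **Detection** — each frame is segmented into putative axons with a
   classical pipeline: non-local-means denoising over a 5-frame temporal
   window, per-pixel channel maximum, Gaussian smoothing (σ = 2 px), Otsu
   thresholding, one erosion, and removal of components under 11 pixels.
2. **Tracking** — a *tracker template* (one model per axon with running-mean
   area and centroid) is matched to every frame's ROIs by a nested Hungarian
   assignment.  The cost of pairing ROI *i* with axon *k* is

   cost(i, k) = w_area·|area_i − area_k| + (1/(N_ROI−1)) Σ cost′(i′, k′\*)

   where the inner cost compares displacement vectors relative to the
   assumed pair (length, angle) and areas, attenuated down the scan
   direction; w_dist = 1.0, w_θ = 0.1, w_area = 0.1, α_θ = 0.1.  "Dummy"
   axons priced at max(0.3, 1.1·min cost) let spurious ROIs stay unmatched.
   Tracking runs twice: a sequential pass that updates the template by
   running averages, then a re-match of every frame against the frozen
   template.
3. **Separation** — on the average of a self-similar frame cluster (found
   by OPTICS on negative cross-correlation), merged ROIs are split by a
   watershed seeded at intensity maxima ≥ 0.05; each division is stored as
   a straight cut line *normalized to the ROI's least-squares ellipse*, so
   it can be re-fitted to the same axon's ellipse in every other frame.
4. **Fluorescence** — per axon and frame, F_t is the mean of non-zero green
   ROI pixels, R_t = F_t / tdTom_t, and ΔF/F = (F_t − F)/F with the baseline
   F the minimal mean over sliding 10-s windows.  Frames where an axon went
   unmatched are explicit missing values.

A fully ground-truthed synthetic-recording generator
(`axotrace.synthetic`) — elliptical-Gaussian axons, Poisson spikes convolved
with a calcium kernel, per-frame affine movement artifacts, shot + read
noise — makes every stage testable end to end without any microscopy data.

## Worked example

```python
from axotrace import generate_experiment, run_variant, evaluate_against_truth, PipelineConfig

stack, truth = generate_experiment(n_axons=3, n_frames=60, seed=1, artifact_magnitude=0.0)
result = run_variant(stack, PipelineConfig(), "raw")
report = evaluate_against_truth(result, truth)
print(f"identity accuracy {100 * report['identity_accuracy']:.1f} %, "
      f"mean Dice {report['mean_dice']:.3f}")
```

or, from the shell:

```
$ axotrace benchmark --n-axons 3 --n-frames 60 --seed 1 --artifact 0.0
raw: identity accuracy 100.0 %, mean Dice 0.867, trace r [0.980, 0.986, 0.992]
```

Every identity the tracker assigned is correct (100 %); the per-frame Dice
overlap between the detected foreground and the true axon masks is 0.867;
and the extracted fluorescence traces correlate with the true calcium
traces at r ≥ 0.98 (the residual comes from the generator's shot and read
noise — with `--no-noise` the correlation is exactly 1).

The full workflow on real data reads a two-channel TIFF stack and writes
all three variants (raw, cross-correlation-registered, optic-flow if a
registrar is plugged in) side by side:

```
axotrace run --data my_recording/ --variants raw,cc --out results/
```

Each variant directory contains `masks.tif`, `rois.csv`, `identities.csv`,
`template.json`, `cuts.json` and `fluorescence.csv` (missing values as
empty fields, baselines in the JSON sidecar).

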