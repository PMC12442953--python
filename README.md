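# intradental

Analysis toolkit for stimulus-locked in vivo ganglion calcium imaging of
tooth-innervating sensory neurons, with the companion quantification
pipelines used around such recordings:

- **motion** — inter-frame movie registration: translation rough pass then
  affine fine-tune, mean-squares similarity, regular-step gradient descent.
- **fluor** — ROI management, neuropil-corrected dF trace extraction
  (soma mean minus local-annulus mean per frame), total trapezoidal AUC over
  a stimulation window (default frames 40–120), Feret-diameter morphometry.
- **classify** — pulse-triggered-average detection of electrical-round
  entrainment, the "responds in ≥ 2 of 3 rounds" cell rule, persistence-rule
  detection for single stimulation epochs, pooled responder proportions, and
  marker-positivity scoring on aligned images.
- **ishreg** — post hoc ISH-to-in-vivo alignment: 0.1–99.9 percentile
  normalization, control-point second-order polynomial initialization,
  classic multiresolution Demons refinement (four levels, iterations
  [5,1,1,1] coarse→fine), warp application to channel stacks, ROI transfer,
  and labeling efficiency/specificity.
- **quantfluor** — region-level immune-cell fluorescence: nuclear-channel
  thresholding with morphological cleanup, two-stage background subtraction,
  area-normalized brightness.
- **reflex** — EMG reflex quantification (zero-phase 100–3000 Hz band-pass,
  rectification + 0.1 s leaky integration, per-stimulus latency / duration /
  peak-to-peak) and jaw-opening kinematics from two-keypoint incisor tracks
  aligned to a high-rate trigger.
- **synthgen** — deterministic synthetic data generators (movies with
  GCaMP-like transients, neuropil and motion; warped guidepost image pairs;
  EMG bursts; jaw tracks; immune images) with exported ground truth, so the
  whole pipeline is testable without external recordings.
- **pipeline** — config-driven end-to-end runs and demo fixtures with
  byte-reproducible JSON reports.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(proportion arithmetic, motion-recovery error bounds, neuropil cancellation,
responder-rule equivalence, alignment landmark error, brightness recovery,
reflex metric tolerances, pipeline reproducibility).

## CLI

One entry point, `idn`, with a sub-group per module:

```bash
idn synth movie --spec spec.json --seed 1 --out data/
idn motion register --in movie.tif --out reg.tif --transforms t.json --reference mean
idn fluor extract --movie reg.tif --rois rois.tif --out traces.csv
idn classify run --traces traces.csv --stim stim.json --out responders.csv
idn ishreg align --fixed invivo.tif --moving ish.tif --points pts.json --out aligned.tif
idn quantfluor run --image img.tif --out brightness.csv
idn reflex emg --trace emg.csv --out metrics.csv
idn reflex jaw --track track.csv --out defl.csv
idn pipeline demo --out demo/ --seed 1
idn pipeline run --config run.yaml --out out/
```

Formats: movies and images as TIFF (16-bit with a JSON scaling sidecar, or
float32), ROIs as label TIFF or polygon JSON, traces/EMG/tracks as CSV with
JSON sidecars, stimulus trains / control points / transforms / warp models as
JSON (+ a two-plane float TIFF for dense displacement fields).

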