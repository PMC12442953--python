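"""End-to-end orchestration: synthetic demo fixtures and reproducible runs.

A run is described by a single config document (YAML/JSON-compatible dict)
with per-stage blocks; every paper-gap default lives in the config so it can
be overridden without code changes.  Identical (config, seed) pairs produce
byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np

from . import io
from .classify import (ResponderTable, ResponseCriterion,
                       classify_intradental, detect_round_response,
                       pool_proportions, score_expression)
from .fluor import (AUCConfig, NeuropilConfig, compute_auc, extract_traces,
                    feret_diameter, pulse_peak_amplitude)
from .ishreg import (ControlPoints, apply_warp_stack, demons_refine,
                     fit_polynomial_warp, transfer_rois)
from .motion import register_stack
from .quantfluor import quantify
from .reflex import jaw_deflection, reflex_metrics
from .synthgen import (SynthMovieSpec, generate_emg, generate_immune_image,
                       generate_ish_pair, generate_jaw_track, generate_movie,
                       make_electrical_train)

DEFAULT_CONFIG = {
    "seed": 0,
    "movie": {"height_px": 128, "width_px": 128, "n_frames": 200,
              "n_cells": 12, "responder_fraction": 0.5,
              "transient_amplitude": 20.0, "neuropil_amplitude": 10.0,
              "motion_model": "translation", "noise_sd": 1.0},
    "stim": {"n_rounds": 3, "pulses_per_round": 3, "start_s": 8.0,
             "rate_hz": 0.625, "inter_round_gap_s": 5.0},
    "motion": {"reference": "first_frame"},
    "fluor": {"inner_margin_px": 2, "outer_margin_px": 8,
              "auc_start_frame": 40, "auc_end_frame": 120,
              "auc_normalization": "none"},
    "classify": {"threshold_sd": 3.0, "response_window_s": 1.0,
                 "baseline_end_frame": 35},
    "ishreg": {"warp_magnitude_px": 3.0, "n_guideposts": 10, "n_channels": 3},
    "quantfluor": {"roi_intensity": 100.0, "background_intensity": 10.0},
    "reflex": {"latency_s": 0.008, "peak_to_peak_mv": 1.0,
               "deflection_um": 305.0},
}


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_demo_fixtures(out_dir, seed: int = 0) -> dict:
    """Write a small synthetic fixture set with ground truth; returns a
    manifest with per-file checksums."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stim = make_electrical_train(n_rounds=3, pulses_per_round=3, start_s=8.0)
    spec = SynthMovieSpec(height_px=256, width_px=256, n_frames=300,
                          n_cells=20, responder_fraction=0.5,
                          neuropil_amplitude=10.0, motion_model="translation",
                          noise_sd=1.0, seed=seed)
    movie, truth = generate_movie(spec, stim)
    io.write_movie_tiff(out / "movie.tif", movie)
    io.write_label_tiff(out / "rois.tif", truth.true_rois)
    io.write_stimulus_json(out / "stim.json", stim)
    (out / "movie_truth.json").write_text(json.dumps({
        "responder": truth.extras["responder"].tolist(),
        "diameter_um": truth.extras["diameter_um"].tolist(),
        "true_shifts": [t.offset.tolist() for t in truth.true_motion],
    }))

    fixed, moving_stack, ish_truth = generate_ish_pair(seed=seed + 1)
    io.write_image_tiff(out / "ish_fixed.tif", fixed)
    io.write_image_tiff(out / "ish_moving.tif", moving_stack)
    cps = ControlPoints(ish_truth.true_control_points[:, 0],
                        ish_truth.true_control_points[:, 1])
    io.write_control_points_json(out / "ish_points.json", cps)

    emg, emg_truth = generate_emg(stim_onsets_s=[0.5, 1.5, 2.5],
                                  seed=seed + 2)
    io.write_emg_csv(out / "emg.csv", emg)

    track, track_truth = generate_jaw_track(pulse_onsets_s=[1.0, 3.0],
                                            seed=seed + 3)
    io.write_track_csv(out / "jaw.csv", track)

    immune, imm_truth = generate_immune_image(seed=seed + 4)
    io.write_image_tiff(out / "immune.tif", immune)

    files = sorted(p for p in out.iterdir() if p.is_file()
                   and p.name != "manifest.json")
    manifest = {"seed": seed,
                "files": {p.name: _file_checksum(p) for p in files}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def validate_config(cfg: dict) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, block in (cfg or {}).items():
        if key not in merged:
            raise ValueError(f"unknown config block {key!r}")
        if isinstance(block, dict):
            unknown = set(block) - set(merged[key])
            if unknown:
                raise ValueError(f"unknown keys in {key!r}: {sorted(unknown)}")
            merged[key].update(block)
        else:
            merged[key] = block
    return merged


def run_pipeline(cfg: dict | None = None, out_dir=None) -> dict:
    """Run the full synthetic pipeline and return a reproducible report.

    Stages: generate movie -> motion correction -> trace extraction ->
    responder classification + AUC + diameters -> ISH pair alignment +
    positivity scoring -> immune quantification -> EMG/jaw reflex metrics.
    Each stage's recovered-vs-true summary goes into the report; a stage
    failure is recorded and halts downstream stages of the same branch.
    """
    cfg = validate_config(cfg)
    seed = int(cfg["seed"])
    report: dict = {"config": cfg, "seed": seed, "stages": {}, "warnings": []}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- movie branch -------------------------------------------------
        mc = cfg["movie"]
        stim = make_electrical_train(**cfg["stim"])
        spec = SynthMovieSpec(seed=seed, **mc)
        movie, truth = generate_movie(spec, stim)
        reg, transforms = register_stack(
            movie, reference=cfg["motion"]["reference"])
        true_shift = np.array([t.offset for t in truth.true_motion])
        est_shift = np.array([t.offset for t in transforms])
        resid = est_shift + true_shift
        resid = resid - resid.mean(axis=0)
        report["stages"]["motion"] = {
            "n_frames": movie.n_frames,
            "shift_residual_rms_px": float(np.sqrt((resid**2).mean())),
        }

        fl = cfg["fluor"]
        npil = NeuropilConfig(fl["inner_margin_px"], fl["outer_margin_px"])
        traces = extract_traces(reg, truth.true_rois, npil)
        base_end = cfg["classify"]["baseline_end_frame"]
        amp_est = np.array([
            pulse_peak_amplitude(tr, stim.pulse_onsets_s,
                                 movie.frame_rate_hz,
                                 baseline_frames=(0, base_end))
            for tr in traces.values])
        responder = truth.extras["responder"]
        rel_err = np.abs(amp_est[responder] - spec.transient_amplitude) \
            / spec.transient_amplitude if responder.any() else np.array([])
        report["stages"]["fluor"] = {
            "n_cells": traces.n_cells,
            "amplitude_recovery_within_10pct":
                float((rel_err <= 0.10).mean()) if rel_err.size else None,
        }

        crit = ResponseCriterion(baseline_window_frames=(0, base_end),
                                 threshold_sd=cfg["classify"]["threshold_sd"],
                                 response_window_s=cfg["classify"]["response_window_s"])
        n_rounds = len(stim.rounds)
        round_resp = np.zeros((traces.n_cells, n_rounds), dtype=bool)
        for i in range(traces.n_cells):
            for j, r in enumerate(stim.rounds):
                round_resp[i, j] = detect_round_response(
                    traces.values[i], stim.restrict_to_round(r),
                    movie.frame_rate_hz, crit)
        is_intr = np.array([classify_intradental(r) for r in round_resp])
        auc_cfg = AUCConfig(fl["auc_start_frame"], fl["auc_end_frame"],
                            fl["auc_normalization"])
        aucs = np.array([compute_auc(tr, auc_cfg) for tr in traces.values])
        diam = np.array([feret_diameter(r.mask, movie.pixel_size_um)
                         for r in truth.true_rois])
        table = ResponderTable(traces.cell_ids, round_resp,
                               {"electrical": is_intr}, {"electrical": aucs},
                               diam)
        tp = int((is_intr & responder).sum())
        tn = int((~is_intr & ~responder).sum())
        report["stages"]["classify"] = {
            "sensitivity": tp / max(1, int(responder.sum())),
            "specificity": tn / max(1, int((~responder).sum())),
            "proportion": pool_proportions([table], "electrical"),
            "mean_diameter_um": float(diam.mean()),
        }

        # --- ISH branch ---------------------------------------------------
        ic = cfg["ishreg"]
        fixed, moving_stack, ish_truth = generate_ish_pair(
            n_guideposts=ic["n_guideposts"], n_channels=ic["n_channels"],
            warp_magnitude_px=ic["warp_magnitude_px"], seed=seed + 1)
        cps = ControlPoints(ish_truth.true_control_points[:, 0],
                            ish_truth.true_control_points[:, 1])
        poly = fit_polynomial_warp(cps)
        wm = demons_refine(fixed, moving_stack[0], poly)
        aligned = apply_warp_stack(moving_stack, wm)
        g = ish_truth.true_control_points[:, 0]
        lm_err = np.linalg.norm(wm.map_points(g)
                                - ish_truth.true_warp.map_points(g), axis=1)
        rois_fixed = transfer_rois(ish_truth.true_rois, wm, target="fixed")
        calls = score_expression(aligned[1:], rois_fixed)
        agreement = float((calls == ish_truth.true_positivity).mean())
        report["stages"]["ishreg"] = {
            "landmark_rms_px": float(np.sqrt((lm_err**2).mean())),
            "ms_init": wm.metadata["ms_init"],
            "ms_final": wm.metadata["ms_final"],
            "positivity_agreement": agreement,
        }

        # --- immune branch --------------------------------------------
        qc = cfg["quantfluor"]
        image, imm_truth = generate_immune_image(
            roi_intensity=qc["roi_intensity"],
            background_intensity=qc["background_intensity"], seed=seed + 4)
        quant = quantify(image)
        report["stages"]["quantfluor"] = {
            "mean_brightness": quant["mean_brightness"],
            "expected": qc["roi_intensity"] - qc["background_intensity"],
            "roi_area_px": quant["roi_area_px"],
        }

        # --- reflex branch --------------------------------------------
        rc = cfg["reflex"]
        emg, emg_truth = generate_emg(stim_onsets_s=[0.5],
                                      latency_s=rc["latency_s"],
                                      peak_to_peak_mv=rc["peak_to_peak_mv"],
                                      seed=seed + 2)
        metrics = reflex_metrics(emg, (0.0, 0.4))[0]
        track, _ = generate_jaw_track(pulse_onsets_s=[1.0],
                                      deflection_um=rc["deflection_um"],
                                      seed=seed + 3)
        defl = jaw_deflection(track)
        report["stages"]["reflex"] = {
            "latency_s": metrics.latency_s,
            "true_latency_s": rc["latency_s"],
            "peak_to_peak_mv": metrics.peak_to_peak_mv,
            "true_peak_to_peak_mv": rc["peak_to_peak_mv"],
            "deflection_um": float(defl["deflection_um"][0]),
            "true_deflection_um": rc["deflection_um"],
        }

    report["warnings"] = sorted({str(w.message) for w in caught})
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1,
                                                    sort_keys=True))
    return report
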