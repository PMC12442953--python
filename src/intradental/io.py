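"""File I/O: multi-page TIFF movies, label masks, JSON sidecars, CSV traces."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .classify import StimulusTrain
from .fluor import ROI, ROISet, TraceMatrix, polygon_to_mask
from .ishreg import ControlPoints, PolynomialWarp2, WarpModel
from .motion import AffineTransform2D, MovieStack
from .reflex import EMGTrace, KeypointTrack, TriggerTrace


def write_movie_tiff(path, movie: MovieStack, scale_to_uint16: bool = True
                     ) -> None:
    """Write a movie as multi-page TIFF (16-bit by default).

    The float-to-uint16 scaling (offset/scale) is stored in a JSON sidecar
    so that reading round-trips the intensities.
    """
    path = Path(path)
    frames = movie.frames
    meta = {"frame_rate_hz": movie.frame_rate_hz,
            "pixel_size_um": movie.pixel_size_um}
    if scale_to_uint16:
        lo, hi = float(frames.min()), float(frames.max())
        scale = (65535.0 / (hi - lo)) if hi > lo else 1.0
        data = np.round((frames - lo) * scale).astype(np.uint16)
        meta.update({"offset": lo, "scale": scale})
        tifffile.imwrite(path, data)
    else:
        tifffile.imwrite(path, frames.astype(np.float32))
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_movie_tiff(path) -> MovieStack:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None]
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if "scale" in meta:
        data = data / meta["scale"] + meta.get("offset", 0.0)
    return MovieStack(data, meta.get("frame_rate_hz", 5.0),
                      meta.get("pixel_size_um", 1.0))


def write_image_tiff(path, image: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32),
                     photometric="minisblack")


def read_image_tiff(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(float)


def write_label_tiff(path, rois: ROISet) -> None:
    tifffile.imwrite(Path(path), rois.to_labels().astype(np.int32))
    ids_path = Path(path).with_suffix(".ids.json")
    ids_path.write_text(json.dumps(rois.ids))


def read_label_tiff(path) -> ROISet:
    labels = tifffile.imread(Path(path))
    ids_path = Path(path).with_suffix(".ids.json")
    ids = json.loads(ids_path.read_text()) if ids_path.exists() else None
    return ROISet.from_labels(labels, ids)


def write_rois_json(path, rois_polygons: dict, image_shape) -> None:
    """Polygon ROI JSON: {"image_shape": [H, W], "rois": [{"id", "polygon"}]}"""
    doc = {"image_shape": list(image_shape),
           "rois": [{"id": k, "polygon": np.asarray(v).tolist()}
                    for k, v in rois_polygons.items()]}
    Path(path).write_text(json.dumps(doc))


def read_rois_json(path) -> ROISet:
    doc = json.loads(Path(path).read_text())
    shape = tuple(doc["image_shape"])
    rois = [ROI(r["id"], polygon_to_mask(r["polygon"], shape))
            for r in doc["rois"]]
    return ROISet(rois, shape)


def write_traces_csv(path, traces: TraceMatrix) -> None:
    """Traces as CSV (rows = cells, columns = frames) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(traces.values, index=traces.cell_ids)
    df.index.name = "cell_id"
    df.to_csv(path)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(
        {"frame_rate_hz": traces.frame_rate_hz, "units": "dF"}))


def read_traces_csv(path) -> TraceMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col="cell_id")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return TraceMatrix(df.to_numpy(), [str(i) for i in df.index],
                       meta.get("frame_rate_hz", 5.0))


def write_stimulus_json(path, stim: StimulusTrain) -> None:
    Path(path).write_text(json.dumps(stim.to_dict()))


def read_stimulus_json(path) -> StimulusTrain:
    return StimulusTrain.from_dict(json.loads(Path(path).read_text()))


def write_transforms_json(path, transforms) -> None:
    Path(path).write_text(json.dumps([t.to_dict() for t in transforms]))


def read_transforms_json(path) -> list:
    return [AffineTransform2D.from_dict(d)
            for d in json.loads(Path(path).read_text())]


def write_control_points_json(path, points: ControlPoints) -> None:
    Path(path).write_text(json.dumps({"pairs": points.to_pairs()}))


def read_control_points_json(path) -> ControlPoints:
    return ControlPoints.from_pairs(json.loads(Path(path).read_text())["pairs"])


def write_warp_model(path_json, path_tiff, w: WarpModel) -> None:
    """Warp model: polynomial coefficients as JSON, displacement field as a
    two-plane float TIFF."""
    Path(path_json).write_text(json.dumps({
        "coeffs_row": w.polynomial.coeffs_row.tolist(),
        "coeffs_col": w.polynomial.coeffs_col.tolist(),
        "fixed_shape": list(w.fixed_shape),
        "displacement_tiff": str(path_tiff),
    }))
    tifffile.imwrite(Path(path_tiff),
                     np.moveaxis(w.displacement, -1, 0).astype(np.float32))


def read_warp_model(path_json) -> WarpModel:
    doc = json.loads(Path(path_json).read_text())
    disp = tifffile.imread(doc["displacement_tiff"]).astype(float)
    return WarpModel(PolynomialWarp2(doc["coeffs_row"], doc["coeffs_col"]),
                     np.moveaxis(disp, 0, -1), tuple(doc["fixed_shape"]))


def write_emg_csv(path, trace: EMGTrace) -> None:
    pd.DataFrame({"time_s": trace.times_s, "mv": trace.samples}).to_csv(
        path, index=False)
    Path(path).with_suffix(".meta.json").write_text(json.dumps(
        {"sample_rate_hz": trace.sample_rate_hz,
         "stim_onsets_s": trace.stim_onsets_s.tolist(),
         "channel": trace.channel}))


def read_emg_csv(path, sample_rate_hz=None, stim_onsets_s=None) -> EMGTrace:
    df = pd.read_csv(path)
    meta_path = Path(path).with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    if sample_rate_hz is None:
        sample_rate_hz = meta.get("sample_rate_hz")
    if sample_rate_hz is None:
        dt = np.diff(df["time_s"].to_numpy()).mean()
        sample_rate_hz = 1.0 / dt
    if stim_onsets_s is None:
        stim_onsets_s = meta.get("stim_onsets_s", [])
    return EMGTrace(df["mv"].to_numpy(), float(sample_rate_hz),
                    np.asarray(stim_onsets_s, dtype=float),
                    meta.get("channel", "digastric"))


def write_track_csv(path, track: KeypointTrack) -> None:
    pd.DataFrame({
        "frame": np.arange(track.n_frames),
        "x_top": track.top_xy[:, 0], "y_top": track.top_xy[:, 1],
        "x_bottom": track.bottom_xy[:, 0], "y_bottom": track.bottom_xy[:, 1],
    }).to_csv(path, index=False)
    meta = {"video_rate_hz": track.video_rate_hz,
            "px_per_um": track.px_per_um}
    if track.trigger is not None:
        meta["trigger_rate_hz"] = track.trigger.rate_hz
        meta["pulse_onsets_s"] = track.trigger.pulse_onsets_s.tolist()
    Path(path).with_suffix(".meta.json").write_text(json.dumps(meta))


def read_track_csv(path, video_rate_hz=None, px_per_um=None) -> KeypointTrack:
    df = pd.read_csv(path)
    meta_path = Path(path).with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    trigger = None
    if "trigger_rate_hz" in meta:
        trigger = TriggerTrace(meta["trigger_rate_hz"],
                               np.asarray(meta.get("pulse_onsets_s", [])))
    return KeypointTrack(
        df[["x_top", "y_top"]].to_numpy(),
        df[["x_bottom", "y_bottom"]].to_numpy(),
        video_rate_hz or meta.get("video_rate_hz", 170.0),
        px_per_um or meta.get("px_per_um", 1.0),
        trigger)
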