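"""Stimulus-locked responder detection and positivity scoring.

Two detection contexts: electrical pulse trains are tested with a
pulse-triggered average (robust at 0.6 Hz entrainment), single stimulation
epochs with a persistence rule (threshold exceeded for a minimum run of
consecutive frames).  The intradental rule is ">= k of R electrical rounds"
with k defaulting to 2 of 3.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .fluor import ROISet

MODALITIES = ("electrical", "force", "cold", "cutting", "friction", "vibration")


@dataclass
class StimulusTrain:
    modality: str
    pulse_onsets_s: np.ndarray
    pulse_duration_s: float = 0.2
    round_ids: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        self.pulse_onsets_s = np.asarray(self.pulse_onsets_s, dtype=float)
        if np.any(np.diff(self.pulse_onsets_s) <= 0):
            raise ValueError("pulse onsets must be strictly increasing")
        if self.pulse_duration_s <= 0:
            raise ValueError("pulse duration must be positive")
        if self.round_ids is None:
            self.round_ids = np.zeros(len(self.pulse_onsets_s), dtype=int)
        else:
            self.round_ids = np.asarray(self.round_ids, dtype=int)
        if len(self.round_ids) != len(self.pulse_onsets_s):
            raise ValueError("every pulse needs a round id")

    @property
    def rounds(self) -> list:
        return sorted(set(int(r) for r in self.round_ids))

    def restrict_to_round(self, round_id: int) -> "StimulusTrain":
        sel = self.round_ids == round_id
        if not sel.any():
            raise ValueError(f"no pulses in round {round_id}")
        return StimulusTrain(self.modality, self.pulse_onsets_s[sel],
                             self.pulse_duration_s,
                             self.round_ids[sel], dict(self.params))

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "pulse_onsets_s": self.pulse_onsets_s.tolist(),
            "pulse_duration_s": self.pulse_duration_s,
            "round_ids": self.round_ids.tolist(),
            "params": self.params,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusTrain":
        return cls(d["modality"], d["pulse_onsets_s"],
                   d.get("pulse_duration_s", 0.2), d.get("round_ids"),
                   d.get("params", {}))


@dataclass
class ResponseCriterion:
    baseline_window_frames: tuple = (0, 39)
    threshold_sd: float = 3.0
    response_window_s: float = 1.0
    min_consecutive_frames: int = 2

    def __post_init__(self) -> None:
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be positive")
        if self.min_consecutive_frames < 1:
            raise ValueError("min_consecutive_frames must be >= 1")


def _baseline_stats(trace: np.ndarray, crit: ResponseCriterion):
    b0, b1 = crit.baseline_window_frames
    base = trace[b0:b1 + 1]
    if base.size == 0:
        raise ValueError("baseline window outside trace")
    mu = float(base.mean())
    sd = float(base.std())
    if sd == 0.0:
        warnings.warn("flat baseline: using machine epsilon for sd",
                      stacklevel=3)
        sd = float(np.finfo(float).eps)
    return mu, sd


def detect_round_response(trace: np.ndarray, stim: StimulusTrain,
                          frame_rate_hz: float,
                          crit: ResponseCriterion | None = None) -> bool:
    """Pulse-triggered-average detection for one electrical round.

    True iff the peak of the average response over [0, response_window_s]
    after pulse onset exceeds baseline mean + threshold_sd * baseline sd.
    """
    crit = crit or ResponseCriterion()
    trace = np.asarray(trace, dtype=float).ravel()
    mu, sd = _baseline_stats(trace, crit)
    win = max(1, int(round(crit.response_window_s * frame_rate_hz)))
    segments = []
    for onset in stim.pulse_onsets_s:
        f0 = int(round(onset * frame_rate_hz))
        if f0 < 0 or f0 + win > trace.size:
            continue
        segments.append(trace[f0:f0 + win])
    if not segments:
        raise ValueError("no stimulus pulse lies within the trace")
    pta = np.mean(segments, axis=0)
    return bool(pta.max() > mu + crit.threshold_sd * sd)


def classify_intradental(round_responses, k_required: int = 2) -> bool:
    """True iff the cell responded in at least ``k_required`` rounds."""
    responses = [bool(r) for r in round_responses]
    if len(responses) < 1:
        raise ValueError("need at least one round")
    return sum(responses) >= k_required


def detect_stimulus_response(trace: np.ndarray, window: tuple,
                             frame_rate_hz: float,
                             crit: ResponseCriterion | None = None) -> bool:
    """Persistence-rule detection for a single stimulation epoch.

    True iff the trace exceeds baseline mean + threshold_sd * sd for at
    least ``min_consecutive_frames`` consecutive frames inside
    ``window = (start_s, end_s)``.
    """
    crit = crit or ResponseCriterion()
    trace = np.asarray(trace, dtype=float).ravel()
    mu, sd = _baseline_stats(trace, crit)
    f0 = int(round(window[0] * frame_rate_hz))
    f1 = int(round(window[1] * frame_rate_hz))
    if f0 < 0 or f1 > trace.size or f0 >= f1:
        raise ValueError("response window outside the recording")
    above = trace[f0:f1] > mu + crit.threshold_sd * sd
    run = best = 0
    for a in above:
        run = run + 1 if a else 0
        best = max(best, run)
    return best >= crit.min_consecutive_frames


@dataclass
class ResponderTable:
    """Per-cell classification results for one imaging field."""

    cell_ids: list
    round_responses: np.ndarray  # n_cells x n_rounds booleans
    stimulus_responses: dict = field(default_factory=dict)  # modality -> bool array
    auc: dict = field(default_factory=dict)  # modality -> real array
    diameter_um: np.ndarray | None = None
    k_required: int = 2

    def __post_init__(self) -> None:
        self.round_responses = np.atleast_2d(
            np.asarray(self.round_responses, dtype=bool))
        if self.round_responses.shape[0] != len(self.cell_ids):
            raise ValueError("round_responses rows must match cell_ids")
        for mod, flags in self.stimulus_responses.items():
            self.stimulus_responses[mod] = np.asarray(flags, dtype=bool)
            if len(self.stimulus_responses[mod]) != len(self.cell_ids):
                raise ValueError(f"{mod}: flags must match cell count")

    @property
    def is_intradental(self) -> np.ndarray:
        return self.round_responses.sum(axis=1) >= self.k_required

    def to_dataframe(self):
        import pandas as pd

        data = {"cell_id": self.cell_ids}
        for j in range(self.round_responses.shape[1]):
            data[f"round_{j + 1}"] = self.round_responses[:, j]
        data["is_intradental"] = self.is_intradental
        for mod, flags in self.stimulus_responses.items():
            data[f"responds_{mod}"] = flags
        for mod, vals in self.auc.items():
            data[f"auc_{mod}"] = vals
        if self.diameter_um is not None:
            data["diameter_um"] = self.diameter_um
        return pd.DataFrame(data)


def round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def pool_proportions(tables, modality: str, decimals: int = 0) -> dict:
    """Pool responder counts across imaging fields.

    Denominator: intradental cells across all tables.  Numerator: those
    flagged responsive to ``modality``.  ``decimals=0`` rounds the percent
    to the nearest integer (half away from zero); ``decimals=1`` truncates
    at the first decimal, matching the convention of printed one-decimal
    proportions.
    """
    num = den = 0
    for t in tables:
        intr = t.is_intradental
        den += int(intr.sum())
        flags = t.stimulus_responses.get(modality)
        if flags is not None:
            num += int((intr & flags).sum())
    return proportion_percent(num, den, decimals)


def proportion_percent(numerator: int, denominator: int, decimals: int = 0) -> dict:
    if numerator < 0 or denominator < 0 or numerator > denominator:
        raise ValueError("require 0 <= numerator <= denominator")
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    pct = 100.0 * numerator / denominator
    if decimals == 0:
        percent: float = float(round_half_away(pct))
    elif decimals == 1:
        percent = math.floor(pct * 10.0) / 10.0  # truncate toward zero
    else:
        raise ValueError("decimals must be 0 or 1")
    return {"numerator": numerator, "denominator": denominator,
            "percent": percent}


def score_expression(aligned_channels: np.ndarray, rois: ROISet,
                     k_sd: float = 2.0) -> np.ndarray:
    """Per-cell per-channel positivity calls on aligned images.

    A cell is positive in a channel iff its ROI mean exceeds the background
    mean + k_sd * background sd, background statistics taken over pixels
    outside all ROIs.  ``aligned_channels`` is C x H x W (or H x W for a
    single channel); returns an (n_cells, C) boolean array.
    """
    channels = np.asarray(aligned_channels, dtype=float)
    if channels.ndim == 2:
        channels = channels[None]
    if channels.shape[1:] != rois.image_shape:
        raise ValueError("channels not on the ROI grid")
    bg = ~rois.union_mask()
    if not bg.any():
        raise ValueError("no background pixels outside ROIs")
    calls = np.zeros((len(rois), channels.shape[0]), dtype=bool)
    for c, img in enumerate(channels):
        mu = float(img[bg].mean())
        sd = float(img[bg].std())
        thr = mu + k_sd * sd
        for i, r in enumerate(rois):
            if not r.mask.any():
                raise ValueError(f"ROI {r.id!r} empty after alignment")
            calls[i, c] = float(img[r.mask].mean()) > thr
    return calls
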