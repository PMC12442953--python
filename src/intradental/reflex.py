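"""EMG reflex quantification and jaw-opening kinematics.

EMG processing: zero-phase 4th-order Butterworth band-pass (100-3000 Hz by
default), full-wave rectification, leaky integration (0.1 s time constant),
and per-stimulus latency / duration / peak-to-peak metrics.  Kinematics:
per-frame Euclidean distance between two incisor keypoints aligned to a
high-rate trigger, with per-pulse baseline-referenced deflection in um.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps


@dataclass
class EMGTrace:
    samples: np.ndarray  # mV
    sample_rate_hz: float
    stim_onsets_s: np.ndarray = field(default_factory=lambda: np.array([]))
    channel: str = "digastric"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        self.stim_onsets_s = np.asarray(self.stim_onsets_s, dtype=float).ravel()
        if self.sample_rate_hz < 6000:
            raise ValueError("sample_rate_hz must be >= 6000 (Nyquist for "
                             "the 100-3000 Hz band)")
        dur = self.samples.size / self.sample_rate_hz
        if self.stim_onsets_s.size and (self.stim_onsets_s.min() < 0
                                        or self.stim_onsets_s.max() > dur):
            raise ValueError("stimulus onsets must lie within the trace")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate_hz


@dataclass
class ReflexMetrics:
    stimulus_index: int
    detected: bool
    latency_s: float = float("nan")
    duration_s: float = float("nan")
    peak_to_peak_mv: float = float("nan")


def bandpass_emg(trace: EMGTrace, low_hz: float = 100.0,
                 high_hz: float = 3000.0) -> EMGTrace:
    """Zero-phase (forward-backward) Butterworth band-pass; removes DC."""
    if not (0 < low_hz < high_hz < trace.sample_rate_hz / 2):
        raise ValueError("band corners invalid for the sampling rate")
    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass",
                     fs=trace.sample_rate_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, trace.samples)
    return EMGTrace(filtered, trace.sample_rate_hz, trace.stim_onsets_s,
                    trace.channel)


def integrate_emg(trace: EMGTrace, tau_s: float = 0.1) -> np.ndarray:
    """Full-wave rectification followed by a single-pole leaky integrator."""
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    rect = np.abs(trace.samples)
    a = float(np.exp(-1.0 / (tau_s * trace.sample_rate_hz)))
    # y[n] = a*y[n-1] + (1-a)*x[n]  via an IIR filter
    return sps.lfilter([1.0 - a], [1.0, -a], rect)


def reflex_metrics(trace: EMGTrace, baseline_window_s: tuple,
                   k_sd: float = 3.0, end_gap_s: float = 0.005,
                   search_window_s: float = 0.1,
                   onset_floor_frac: float = 0.1,
                   min_duration_s: float = 0.001,
                   prefiltered: bool = False) -> list:
    """Per-stimulus reflex latency, duration, and peak-to-peak amplitude.

    Onset is the first post-stimulus sample where the rectified filtered
    trace exceeds ``baseline mean + k_sd * sd`` (with a floor at
    ``onset_floor_frac`` of the in-window peak, which keeps noiseless traces
    from triggering on filter edge transients); the burst ends at the last
    supra-threshold sample before a sub-threshold run of at least
    ``end_gap_s``.  Peak-to-peak is measured on the filtered, unrectified
    trace over [onset, end].  ``detected`` is False when no crossing occurs
    within ``search_window_s`` of the stimulus.
    """
    if trace.stim_onsets_s.size == 0:
        raise ValueError("trace carries no stimulus onsets")
    filt = trace if prefiltered else bandpass_emg(trace)
    fs = trace.sample_rate_hz
    rect = np.abs(filt.samples)
    b0 = int(round(baseline_window_s[0] * fs))
    b1 = int(round(baseline_window_s[1] * fs))
    if not (0 <= b0 < b1 <= rect.size):
        raise ValueError("baseline window outside the trace")
    if baseline_window_s[1] > trace.stim_onsets_s.min():
        raise ValueError("baseline window must precede the first stimulus")
    mu = float(rect[b0:b1].mean())
    sd = float(rect[b0:b1].std())
    if sd == 0.0:
        warnings.warn("flat baseline: using machine epsilon for sd",
                      stacklevel=2)
        sd = float(np.finfo(float).eps)
    gap = max(1, int(round(end_gap_s * fs)))
    out = []
    for k, onset_s in enumerate(trace.stim_onsets_s):
        s0 = int(round(onset_s * fs))
        s1 = min(rect.size, s0 + int(round(search_window_s * fs)))
        window = rect[s0:s1]
        if window.size == 0:
            out.append(ReflexMetrics(k, False))
            continue
        thr = max(mu + k_sd * sd, onset_floor_frac * float(window.max()))
        next_stim = (int(round(trace.stim_onsets_s[k + 1] * fs))
                     if k + 1 < trace.stim_onsets_s.size else rect.size)
        min_run = max(1, int(round(min_duration_s * fs)))
        found = None
        search_from = s0
        while found is None:
            above = np.flatnonzero(rect[search_from:s1] > thr)
            if above.size == 0:
                break
            onset_i = search_from + int(above[0])
            # end: last supra-threshold sample before a sub-threshold run
            # of at least end_gap_s
            end_i = onset_i
            i = onset_i
            while i < next_stim:
                if rect[i] > thr:
                    end_i = i
                    i += 1
                else:
                    run_end = min(next_stim, i + gap)
                    if not np.any(rect[i:run_end] > thr):
                        break
                    i += 1
            n_supra = int(np.count_nonzero(rect[onset_i:end_i + 1] > thr))
            if n_supra >= min_run:
                found = (onset_i, end_i)
            else:
                search_from = end_i + 1  # isolated noise crossing: keep looking
        if found is None:
            out.append(ReflexMetrics(k, False))
            continue
        onset_i, end_i = found
        seg = filt.samples[onset_i:end_i + 1]
        out.append(ReflexMetrics(
            k, True,
            latency_s=(onset_i - s0) / fs,
            duration_s=(end_i - onset_i) / fs,
            peak_to_peak_mv=float(seg.max() - seg.min())))
    return out


@dataclass
class TriggerTrace:
    rate_hz: float
    pulse_onsets_s: np.ndarray

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("trigger rate must be positive")
        self.pulse_onsets_s = np.asarray(self.pulse_onsets_s,
                                         dtype=float).ravel()


@dataclass
class KeypointTrack:
    """Two-keypoint (top/bottom incisor) track with trigger alignment."""

    top_xy: np.ndarray     # n_frames x 2 px
    bottom_xy: np.ndarray  # n_frames x 2 px
    video_rate_hz: float
    px_per_um: float
    trigger: TriggerTrace | None = None

    def __post_init__(self) -> None:
        self.top_xy = np.atleast_2d(np.asarray(self.top_xy, dtype=float))
        self.bottom_xy = np.atleast_2d(np.asarray(self.bottom_xy, dtype=float))
        if self.top_xy.shape != self.bottom_xy.shape or self.top_xy.shape[1] != 2:
            raise ValueError("keypoint arrays must both be (n_frames, 2)")
        if self.video_rate_hz <= 0 or self.px_per_um <= 0:
            raise ValueError("rates and scale must be positive")

    @property
    def n_frames(self) -> int:
        return self.top_xy.shape[0]

    def distances_px(self) -> np.ndarray:
        return np.linalg.norm(self.top_xy - self.bottom_xy, axis=1)

    def frame_times_s(self) -> np.ndarray:
        """Frame times snapped to the nearest trigger sample."""
        t = np.arange(self.n_frames) / self.video_rate_hz
        if self.trigger is None:
            return t
        return np.round(t * self.trigger.rate_hz) / self.trigger.rate_hz


def jaw_deflection(track: KeypointTrack, pulse_window_s: float = 1.0,
                   baseline_window_s: float = 0.5) -> dict:
    """Per-pulse jaw deflection in micrometres.

    For each trigger pulse: baseline = mean inter-incisor distance over
    ``baseline_window_s`` before onset; deflection = max(distance -
    baseline) within ``pulse_window_s`` after onset, converted to um.
    Pulses whose windows contain missing (NaN) keypoints are marked invalid.
    """
    if track.trigger is None or track.trigger.pulse_onsets_s.size == 0:
        raise ValueError("track carries no trigger pulses")
    d = track.distances_px()
    t = track.frame_times_s()
    deflections, valid = [], []
    for onset in track.trigger.pulse_onsets_s:
        base_sel = (t >= onset - baseline_window_s) & (t < onset)
        resp_sel = (t >= onset) & (t <= onset + pulse_window_s)
        if not base_sel.any() or not resp_sel.any():
            raise ValueError(f"pulse at {onset} s outside the recording")
        if np.isnan(d[base_sel]).any() or np.isnan(d[resp_sel]).any():
            deflections.append(float("nan"))
            valid.append(False)
            continue
        baseline = float(d[base_sel].mean())
        defl_px = float((d[resp_sel] - baseline).max())
        deflections.append(defl_px / track.px_per_um)
        valid.append(True)
    return {"deflection_um": np.array(deflections),
            "valid": np.array(valid, dtype=bool),
            "distance_px": d, "frame_times_s": t}
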