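"""ECG preprocessing, peak detection, pacing-window beat classification,
interval measurement, and aligned averaging.

The analysis follows the protocol of intravital optical-pacing experiments:
the ECG is lowpass filtered (100 Hz passband) and normalized to median 0 /
maximum amplitude 1; R peaks are detected as thresholded local maxima and
P waves as the local maximum in a ~100 ms window before each R peak.  Beats
are classified against the laser pulse train — a beat is *stimulated* when
its R peak falls 10–38 ms after a pulse rising edge (ventricular pacing) or
its P peak 38–52 ms after a pulse falling edge (sinoatrial-node pacing),
*unstimulated* when it precedes the first pulse, and *excluded* otherwise.
R-wave duration is the span between the zero crossings flanking the R peak;
the PR interval runs from the P peak to the first zero crossing of the QRS
complex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .exceptions import DegenerateSignalError, ValidationError
from .stats import mann_whitney_u  # noqa: F401  (re-exported: part of this stage's surface)
from .trace import PulseTrain, TimeTrace

#: inclusive stimulated-beat latency windows, ms, keyed by pacing mode.
#: ventricular: R peak relative to the pulse *rising* edge;
#: nodal: P peak relative to the pulse *falling* edge.
CLASSIFICATION_WINDOWS_MS = {
    "ventricular": (10.0, 38.0),
    "nodal": (38.0, 52.0),
}

BEAT_COLUMNS = [
    "r_peak_time_s",
    "p_peak_time_s",
    "label",
    "r_duration_ms",
    "pr_interval_ms",
    "matched_pulse_index",
]

_WINDOW_EPS_MS = 1e-9  # absorb float rounding at the inclusive window edges


def preprocess_ecg(
    raw: TimeTrace,
    target_rate: float | None = None,
    passband: float = 100.0,
    invert: bool = False,
    filter_order: int = 4,
) -> TimeTrace:
    """Resample, lowpass filter, and normalize an ECG trace.

    The output is uniformly sampled at ``target_rate`` (default: the input
    rate), filtered with a zero-phase Butterworth lowpass of the given
    ``passband``, optionally inverted, then shifted to median 0 and scaled
    to maximum absolute amplitude 1.
    """
    fs = raw.sampling_rate if target_rate is None else float(target_rate)
    if fs <= 0:
        raise ValidationError("target_rate must be positive")
    if passband >= fs / 2:
        raise ValidationError("passband must be below the Nyquist frequency")
    x = raw.samples
    if np.max(x) - np.min(x) == 0:
        raise DegenerateSignalError("flat signal cannot be normalized")
    if fs != raw.sampling_rate:
        t_new = np.arange(int(np.floor(raw.duration * fs)) + 1) / fs
        x = np.interp(t_new, raw.times - raw.start_time, x)
    sos = spsig.butter(filter_order, passband, btype="low", fs=fs, output="sos")
    x = spsig.sosfiltfilt(sos, x)
    if invert:
        x = -x
    x = x - np.median(x)
    peak = np.max(np.abs(x))
    if peak == 0:
        raise DegenerateSignalError("signal is flat after filtering")
    return TimeTrace(fs, x / peak, raw.start_time)


def binarize_pulses(ttl: TimeTrace, threshold_fraction: float = 0.5) -> PulseTrain:
    """Edge times where the TTL crosses ``min + f * (max - min)``.

    Crossing times are linearly interpolated between the bracketing samples.
    A trace that starts (ends) above threshold gets a rising (falling) edge
    at its first (last) sample so that edges always alternate.
    """
    if not 0 < threshold_fraction < 1:
        raise ValidationError("threshold_fraction must lie in (0, 1)")
    x = ttl.samples
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo == 0:
        return PulseTrain()
    thr = lo + threshold_fraction * (hi - lo)
    above = x >= thr
    t = ttl.times
    rising: list[float] = []
    falling: list[float] = []
    if above[0]:
        rising.append(t[0])
    idx = np.flatnonzero(np.diff(above.astype(int)))
    for i in idx:
        frac = (thr - x[i]) / (x[i + 1] - x[i])
        tc = t[i] + frac / ttl.sampling_rate
        if above[i + 1]:
            rising.append(tc)
        else:
            falling.append(tc)
    if above[-1]:
        falling.append(t[-1])
    if not rising:
        return PulseTrain()
    return PulseTrain(np.asarray(rising), np.asarray(falling))


def detect_r_peaks(
    ecg: TimeTrace, min_height: float = 0.4, min_separation_ms: float = 50.0
) -> np.ndarray:
    """R-peak times: local maxima above ``min_height`` normalized units,
    at least ``min_separation_ms`` apart (nearest-sample resolution)."""
    distance = max(int(round(min_separation_ms / 1000.0 * ecg.sampling_rate)), 1)
    idx, _ = spsig.find_peaks(ecg.samples, height=min_height, distance=distance)
    return ecg.start_time + idx / ecg.sampling_rate


def detect_p_waves(
    ecg: TimeTrace,
    r_peaks: np.ndarray,
    search_window_ms: float = 100.0,
    guard_ms: float = 10.0,
    min_prominence: float = 0.1,
) -> np.ndarray:
    """Per-beat P-peak times: the maximum in ``[r - window, r - guard]``.

    NaN when the window extends before the trace or its intensity range is
    below ``min_prominence`` (no discernible P deflection).
    """
    if search_window_ms <= guard_ms:
        raise ValidationError("search window must exceed the guard interval")
    fs = ecg.sampling_rate
    x = ecg.samples
    out = np.full(len(r_peaks), np.nan)
    for k, r in enumerate(np.asarray(r_peaks, dtype=float)):
        i0 = int(round((r - ecg.start_time - search_window_ms / 1000.0) * fs))
        i1 = int(round((r - ecg.start_time - guard_ms / 1000.0) * fs))
        if i0 < 0 or i1 >= ecg.n or i1 <= i0:
            continue
        seg = x[i0 : i1 + 1]
        if np.max(seg) - np.min(seg) < min_prominence:
            continue
        out[k] = ecg.start_time + (i0 + int(np.argmax(seg))) / fs
    return out


def make_beat_table(r_peaks: np.ndarray, p_peaks: np.ndarray | None = None) -> pd.DataFrame:
    """Assemble a beat table from detected peaks (all labels 'unstimulated')."""
    r = np.asarray(r_peaks, dtype=float)
    if r.size and np.any(np.diff(r) <= 0):
        raise ValidationError("r_peak times must be strictly increasing")
    df = pd.DataFrame({
        "r_peak_time_s": r,
        "p_peak_time_s": np.asarray(p_peaks, dtype=float) if p_peaks is not None else np.nan,
        "label": "unstimulated",
        "r_duration_ms": np.nan,
        "pr_interval_ms": np.nan,
        "matched_pulse_index": np.nan,
    })
    return df[BEAT_COLUMNS]


def classify_beats(
    beats: pd.DataFrame,
    pulses: PulseTrain,
    mode: str,
    window_ms: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Label each beat unstimulated / stimulated / excluded.

    A beat is *unstimulated* if its R peak precedes the first pulse rising
    edge (or there are no pulses).  It is *stimulated* if the mode's
    reference peak (R for ventricular, P for nodal) falls inside the
    inclusive latency window after the nearest preceding reference edge
    (rising for ventricular, falling for nodal) and that pulse has not
    already captured an earlier beat.  Everything else is *excluded*.
    """
    if mode not in CLASSIFICATION_WINDOWS_MS:
        raise ValidationError(f"unknown mode {mode!r}")
    lo, hi = window_ms if window_ms is not None else CLASSIFICATION_WINDOWS_MS[mode]
    out = beats.copy()
    out["label"] = "excluded"
    out["matched_pulse_index"] = np.nan

    if pulses.n_pulses == 0:
        out["label"] = "unstimulated"
        return out
    first_rising = pulses.rising_edges[0]
    edges = pulses.rising_edges if mode == "ventricular" else pulses.falling_edges

    claimed: set[int] = set()
    for i in out.index:
        r = out.at[i, "r_peak_time_s"]
        if r < first_rising:
            out.at[i, "label"] = "unstimulated"
            continue
        ref = r if mode == "ventricular" else out.at[i, "p_peak_time_s"]
        if not np.isfinite(ref):
            continue  # nodal beat with no detectable P wave: excluded
        j = int(np.searchsorted(edges, ref, side="right")) - 1
        if j < 0:
            continue
        latency_ms = (ref - edges[j]) * 1000.0
        if lo - _WINDOW_EPS_MS <= latency_ms <= hi + _WINDOW_EPS_MS and j not in claimed:
            out.at[i, "label"] = "stimulated"
            out.at[i, "matched_pulse_index"] = j
            claimed.add(j)
    return out


def _zero_cross_left(x: np.ndarray, t0: float, fs: float, peak_idx: int, span: int) -> float:
    """Last negative-to-positive crossing at or before ``peak_idx`` within
    ``span`` samples; linear interpolation between bracketing samples."""
    for j in range(peak_idx - 1, max(peak_idx - span, 0) - 1, -1):
        if x[j] <= 0:  # first non-positive sample walking left; x[j+1] > 0
            if x[j] == 0:
                return t0 + j / fs
            frac = -x[j] / (x[j + 1] - x[j])
            return t0 + (j + frac) / fs
    return np.nan


def _zero_cross_right(x: np.ndarray, t0: float, fs: float, peak_idx: int, span: int) -> float:
    for j in range(peak_idx + 1, min(peak_idx + span, x.size - 1) + 1):
        if x[j] <= 0:
            if x[j] == 0:
                return t0 + j / fs
            frac = x[j - 1] / (x[j - 1] - x[j])
            return t0 + (j - 1 + frac) / fs
    return np.nan


def measure_intervals(
    ecg: TimeTrace, beats: pd.DataFrame, search_span_ms: float = 60.0
) -> pd.DataFrame:
    """Fill R-wave durations and PR intervals into a beat table.

    R duration = interval between the linearly interpolated zero crossings on
    either side of the R peak; PR = P peak to the first zero crossing of the
    QRS complex (the crossing immediately preceding the R upstroke).  NaN
    with no crossing within ``search_span_ms``.
    """
    x = ecg.samples
    fs = ecg.sampling_rate
    span = max(int(round(search_span_ms / 1000.0 * fs)), 2)
    out = beats.copy()
    r_dur = np.full(len(out), np.nan)
    pr = np.full(len(out), np.nan)
    for k, i in enumerate(out.index):
        pk = ecg.index_of(out.at[i, "r_peak_time_s"])
        left = _zero_cross_left(x, ecg.start_time, fs, pk, span)
        right = _zero_cross_right(x, ecg.start_time, fs, pk, span)
        if np.isfinite(left) and np.isfinite(right):
            r_dur[k] = (right - left) * 1000.0
        p = out.at[i, "p_peak_time_s"]
        if np.isfinite(left) and np.isfinite(p):
            pr[k] = (left - p) * 1000.0
    out["r_duration_ms"] = r_dur
    out["pr_interval_ms"] = pr
    return out


@dataclass
class AlignedAverage:
    """Mean ± SD waveform on a lag axis around alignment points, with the
    per-segment nearest laser onset/offset lags summarized."""

    lags_s: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_beats: int
    laser_onset_mean_s: float = np.nan
    laser_onset_sd_s: float = np.nan
    laser_offset_mean_s: float = np.nan
    laser_offset_sd_s: float = np.nan


def aligned_average(
    ecg: TimeTrace,
    align_times: np.ndarray,
    window_ms: tuple[float, float] = (50.0, 50.0),
    pulses: PulseTrain | None = None,
) -> AlignedAverage:
    """Average ECG segments aligned on the given times (e.g. R or P peaks).

    Segments whose window extends outside the trace are dropped; at least one
    usable segment is required.  When a pulse train is given, the lag of the
    nearest rising (falling) edge to each alignment point is summarized as
    the laser onset (offset) mean and SD.
    """
    fs = ecg.sampling_rate
    npre = int(round(window_ms[0] / 1000.0 * fs))
    npost = int(round(window_ms[1] / 1000.0 * fs))
    segs = []
    used_times = []
    for a in np.asarray(align_times, dtype=float):
        c = ecg.index_of(a)
        if c - npre < 0 or c + npost >= ecg.n:
            continue
        segs.append(ecg.samples[c - npre : c + npost + 1])
        used_times.append(a)
    if not segs:
        raise ValidationError("no alignment window fits inside the trace")
    arr = np.asarray(segs)
    lags = np.arange(-npre, npost + 1) / fs
    res = AlignedAverage(lags, arr.mean(axis=0), arr.std(axis=0, ddof=0), arr.shape[0])
    if pulses is not None and pulses.n_pulses:
        on_lags = []
        off_lags = []
        for a in used_times:
            on_lags.append(pulses.rising_edges[np.argmin(np.abs(pulses.rising_edges - a))] - a)
            off_lags.append(pulses.falling_edges[np.argmin(np.abs(pulses.falling_edges - a))] - a)
        res.laser_onset_mean_s = float(np.mean(on_lags))
        res.laser_onset_sd_s = float(np.std(on_lags, ddof=0))
        res.laser_offset_mean_s = float(np.mean(off_lags))
        res.laser_offset_sd_s = float(np.std(off_lags, ddof=0))
    return res


def analyze_ecg(
    ecg_raw: TimeTrace,
    ttl: TimeTrace,
    mode: str,
    invert: bool = False,
    passband: float = 100.0,
    min_height: float = 0.4,
    min_separation_ms: float = 50.0,
    search_window_ms: float = 100.0,
    guard_ms: float = 10.0,
) -> pd.DataFrame:
    """Full pipeline: preprocess, detect, classify, measure.

    Returns the completed beat table.
    """
    ecg = preprocess_ecg(ecg_raw, passband=passband, invert=invert)
    pulses = binarize_pulses(ttl)
    r = detect_r_peaks(ecg, min_height=min_height, min_separation_ms=min_separation_ms)
    p = detect_p_waves(ecg, r, search_window_ms=search_window_ms, guard_ms=guard_ms)
    beats = make_beat_table(r, p)
    beats = classify_beats(beats, pulses, mode)
    return measure_intervals(ecg, beats)
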