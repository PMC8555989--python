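"""Retrospective cardiac/respiratory gating and pacing-coupled fluorescence.

Image lines acquired during free-running cardiac motion are assigned a
cardiac phase from the ECG R-peak times (phase 0 at the R peak, linear
within each RR interval), optionally rejected when they fall inside a
respiratory exclusion window, and re-binned into phase-resolved frames —
each reconstructed frame averaging all accepted lines whose phase falls in
its bin (default 10 bins, i.e. 10% increments of the cardiac cycle).

The fluorescence half analyses Ca2+-indicator traces during optical pacing:
transient onsets are detected on a median-detrended trace and matched 1:1 to
laser pulses, yielding per-pulse onset latencies and the coupling fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as spsig
from scipy.ndimage import median_filter

from .exceptions import ValidationError
from .synth import LineRecordSet
from .trace import PulseTrain, TimeTrace

DEFAULT_N_BINS = 10
DEFAULT_EXCLUSION_FRACTION = 0.3


def assign_cardiac_phase(line_times: np.ndarray, r_peaks: np.ndarray) -> np.ndarray:
    """Cardiac phase in [0, 1) per line: (t - R_prev) / (R_next - R_prev).

    Lines before the first or after the last R peak get NaN (unassignable).
    """
    r = np.asarray(r_peaks, dtype=float)
    t = np.asarray(line_times, dtype=float)
    if r.size < 2:
        raise ValidationError("need at least two R peaks to define phase")
    if np.any(np.diff(r) <= 0):
        raise ValidationError("R-peak times must be strictly increasing")
    idx = np.searchsorted(r, t, side="right")
    phase = np.full(t.shape, np.nan)
    inside = (idx >= 1) & (idx < r.size)
    i = idx[inside]
    phase[inside] = (t[inside] - r[i - 1]) / (r[i] - r[i - 1])
    # a line exactly on the last R peak is phase 0 of a cycle we cannot see
    # the end of; keep it assignable at phase 0
    phase[t == r[-1]] = 0.0
    return phase


def respiratory_gate(
    line_times: np.ndarray,
    resp: TimeTrace,
    exclusion_fraction: float = DEFAULT_EXCLUSION_FRACTION,
) -> np.ndarray:
    """Accept mask over lines; False inside the respiratory exclusion window.

    Respiration peaks (inspiration) are detected from the trace; a line is
    rejected when it lies within ``exclusion_fraction / 2`` of a cycle (in
    time: fraction x median period / 2) of the nearest peak.  With no
    detectable peaks all lines are accepted with a warning.
    """
    if not 0 <= exclusion_fraction <= 1:
        raise ValidationError("exclusion_fraction must lie in [0, 1]")
    t = np.asarray(line_times, dtype=float)
    if exclusion_fraction == 0:
        return np.ones(t.shape, dtype=bool)
    x = resp.samples
    rng = np.max(x) - np.min(x)
    if rng == 0:
        warnings.warn("respiration trace is flat; accepting all lines")
        return np.ones(t.shape, dtype=bool)
    idx, _ = spsig.find_peaks(x, prominence=0.5 * rng)
    if idx.size < 2:
        warnings.warn("fewer than two respiratory peaks; accepting all lines")
        return np.ones(t.shape, dtype=bool)
    peaks = resp.start_time + idx / resp.sampling_rate
    period = float(np.median(np.diff(peaks)))
    halfwin = exclusion_fraction * period / 2.0
    # distance to nearest peak (check both neighbours)
    j = np.searchsorted(peaks, t)
    d_prev = np.where(j >= 1, np.abs(t - peaks[np.clip(j - 1, 0, peaks.size - 1)]), np.inf)
    d_next = np.where(j < peaks.size, np.abs(peaks[np.clip(j, 0, peaks.size - 1)] - t), np.inf)
    dist = np.minimum(d_prev, d_next)
    return dist > halfwin


@dataclass
class PhaseBinnedStack:
    """Phase-resolved reconstruction: per-bin mean image and per-bin per-row
    contributing line counts.  Rows no accepted line ever visited are NaN."""

    images: np.ndarray   # (n_bins, rows, cols); NaN where count = 0
    counts: np.ndarray   # (n_bins, rows) non-negative ints

    @property
    def n_bins(self) -> int:
        return self.images.shape[0]


def reconstruct_phase_bins(
    lines: LineRecordSet,
    phases: np.ndarray,
    accept: np.ndarray | None = None,
    n_bins: int = DEFAULT_N_BINS,
) -> PhaseBinnedStack:
    """Average accepted lines into ``floor(phase * n_bins)`` bins by row."""
    if n_bins < 1:
        raise ValidationError("n_bins must be positive")
    phases = np.asarray(phases, dtype=float)
    if phases.shape[0] != lines.pixels.shape[0]:
        raise ValidationError("phase array length != number of lines")
    if accept is None:
        accept = np.ones(phases.shape, dtype=bool)
    use = accept & np.isfinite(phases)
    bins = np.floor(phases[use] * n_bins).astype(int)
    bins = np.clip(bins, 0, n_bins - 1)
    rows = lines.row_index[use]
    px = lines.pixels[use]

    r, c = lines.rows_per_frame, lines.pixels.shape[1]
    sums = np.zeros((n_bins, r, c))
    counts = np.zeros((n_bins, r), dtype=int)
    np.add.at(sums, (bins, rows), px)
    np.add.at(counts, (bins, rows), 1)
    with np.errstate(invalid="ignore"):
        images = sums / counts[:, :, None]
    images[counts == 0] = np.nan
    return PhaseBinnedStack(images, counts)


def extract_roi_trace(
    frames: np.ndarray, frame_rate: float, roi: tuple[int, int, int, int]
) -> TimeTrace:
    """Mean intensity over an ROI rectangle (row0, row1, col0, col1),
    half-open, per frame."""
    r0, r1, c0, c1 = roi
    if r1 <= r0 or c1 <= c0:
        raise ValidationError("empty ROI")
    frames = np.asarray(frames, dtype=float)
    if r0 < 0 or c0 < 0 or r1 > frames.shape[1] or c1 > frames.shape[2]:
        raise ValidationError("ROI outside the frame")
    return TimeTrace(frame_rate, frames[:, r0:r1, c0:c1].mean(axis=(1, 2)))


@dataclass
class CouplingResult:
    """Per-pulse transient onset latencies and the coupling fraction."""

    latencies_ms: np.ndarray      # NaN where the pulse had no transient
    onset_times: np.ndarray       # all detected onsets (s)
    coupling_fraction: float


def detect_transient_onsets(
    trace: TimeTrace,
    detect_threshold: float = 0.2,
    baseline_fraction: float = 0.05,
    min_above_ms: float = 20.0,
    detrend_window_s: float = 1.0,
) -> np.ndarray:
    """Onset times of upward transients in a fluorescence trace.

    The trace is detrended by a running median (window ``detrend_window_s``);
    candidate events cross ``detect_threshold`` x (max - min) of the
    detrended trace and stay above it for at least ``min_above_ms``.  Each
    event's onset is the last sample at or below ``baseline_fraction`` x
    range before the crossing.
    """
    x = np.asarray(trace.samples, dtype=float)
    nwin = max(int(round(detrend_window_s * trace.sampling_rate)) | 1, 3)
    if nwin > x.size:
        nwin = x.size if x.size % 2 else x.size - 1
    x = x - median_filter(x, size=max(nwin, 1), mode="nearest")
    rng = float(np.max(x) - np.min(x))
    if rng == 0:
        raise ValidationError("zero-range trace")
    thr = detect_threshold * rng
    base = baseline_fraction * rng
    min_above = max(int(round(min_above_ms / 1000.0 * trace.sampling_rate)), 1)

    above = x >= thr
    onsets = []
    i = 0
    n = x.size
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_above:
                k = i
                while k > 0 and x[k] > base:
                    k -= 1
                # settle on the foot of the rise (strict local descent)
                while k > 0 and x[k - 1] < x[k]:
                    k -= 1
                onsets.append(trace.start_time + k / trace.sampling_rate)
            i = j
        else:
            i += 1
    return np.asarray(onsets)


def pacing_coupling(
    trace: TimeTrace,
    pulses: PulseTrain,
    detect_threshold: float = 0.2,
    match_window_ms: float = 200.0,
    **detect_kwargs,
) -> CouplingResult:
    """Match fluorescence transient onsets to laser pulses.

    Each pulse is matched (greedily, in time order) to the first unused
    onset within ``match_window_ms`` after its rising edge.  Latency is
    onset - rising edge, in ms; the coupling fraction is matched / total.
    """
    onsets = detect_transient_onsets(trace, detect_threshold, **detect_kwargs)
    n = pulses.n_pulses
    lat = np.full(n, np.nan)
    used = np.zeros(onsets.size, dtype=bool)
    for j in range(n):
        edge = pulses.rising_edges[j]
        cand = np.flatnonzero((onsets >= edge) & (onsets <= edge + match_window_ms / 1000.0) & ~used)
        if cand.size:
            used[cand[0]] = True
            lat[j] = (onsets[cand[0]] - edge) * 1000.0
    frac = float(np.count_nonzero(np.isfinite(lat))) / n if n else 0.0
    return CouplingResult(lat, onsets, frac)
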