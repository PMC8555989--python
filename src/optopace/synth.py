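"""Synthetic-data generators with exact ground truth.

Every generator emulates one class of in vivo recording that the analysis
stages consume — optically paced ECG with a laser TTL channel, brightfield
vessel video with two bright sidewalls, line-scanned fluorescence stacks
modulated by a cardiac cycle, and pacing-locked Ca2+ indicator traces — and
returns, alongside the data, a :class:`GroundTruth` record from which every
downstream measurement can be checked.

Waveform choices are made so that ground truth is analytic, not measured:

* The R-wave is a Ricker (Mexican-hat) wavelet with ``sigma = r_duration/2``.
  Its zero crossings sit exactly at peak ± r_duration/2, and its negative
  side lobes play the role of the Q and S deflections, so the zero-crossing
  definition of R-wave duration is exact by construction.
* P and T waves are narrow Gaussians whose tails are negligible at the QRS
  zero crossings.
* Vessel sidewalls are Gaussian ridges whose analytic peak separation equals
  the commanded width; frame jitter is an integer-pixel wrap-around
  translation recorded per frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import ValidationError
from .trace import PulseTrain, TimeTrace

# Fixed template amplitudes (normalized units; the preprocessing stage
# re-normalizes, so only their ratios matter).
R_AMPLITUDE = 1.0
P_AMPLITUDE = 0.25
T_AMPLITUDE = 0.15
P_SIGMA_MS = 6.0
T_SIGMA_MS = 15.0
T_OFFSET_MS = 60.0  # T-wave peak delay after the R peak


@dataclass
class GroundTruth:
    """Ground-truth record paired with each synthetic output.

    Only the fields relevant to the generator that produced it are set.
    """

    seed: int = 0
    # ECG
    beat_times: np.ndarray | None = None          # R-peak times (s)
    beat_classes: list[str] | None = None         # 'unstimulated' | 'stimulated'
    r_durations_ms: np.ndarray | None = None
    p_times: np.ndarray | None = None
    pr_intervals_ms: np.ndarray | None = None
    matched_pulse_index: np.ndarray | None = None
    pulse_rising: np.ndarray | None = None
    pulse_falling: np.ndarray | None = None
    # vessel video
    shift_per_frame: np.ndarray | None = None     # (n_frames, 2) (dy, dx) px
    width_per_frame: np.ndarray | None = None     # µm
    wall_centers_um: np.ndarray | None = None     # (n_frames, 2)
    # line scan
    phase_per_line: np.ndarray | None = None
    line_times: np.ndarray | None = None
    r_peak_times: np.ndarray | None = None
    resp_peak_times: np.ndarray | None = None
    modulation: Callable[[np.ndarray], np.ndarray] | None = None
    # fluorescence
    transient_onset_times: np.ndarray | None = None
    transient_peak: float | None = None
    params: dict = field(default_factory=dict)


# ----------------------------------------------------------------------------
# ECG + laser TTL
# ----------------------------------------------------------------------------


@dataclass
class EcgSimSpec:
    """Parameters of the synthetic optically paced ECG.

    Times in seconds unless the name says ``_ms``; rates in Hz.  Before
    ``stim_onset_time`` the heart beats autonomously at ``heart_rate``; from
    ``stim_onset_time`` a laser pulse train at ``pulse_rate`` drives one beat
    per pulse at ``stim_latency`` ms after the rising edge (ventricular mode,
    placing the R peak) or after the falling edge (nodal mode, placing the
    P peak).
    """

    sampling_rate: float = 1000.0
    duration: float = 30.0
    heart_rate: float = 5.0
    r_duration_unstim: float = 12.0   # ms
    r_duration_stim: float = 18.0     # ms
    pr_interval_unstim: float = 40.0  # ms
    pr_interval_stim: float = 48.0    # ms
    jitter_sd: float = 1.0            # ms, timing and interval jitter
    noise_sd: float = 0.02            # additive white Gaussian, normalized units
    pulse_rate: float = 5.0           # Hz
    pulse_length: float = 70.0        # ms
    stim_latency: float = 20.0        # ms after the mode's reference edge
    stim_onset_time: float = 1e9      # s; beyond duration = never stimulate
    mode: str = "ventricular"
    dropout: float = 0.0              # probability a pulse fails to capture
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0 or self.heart_rate <= 0 or self.pulse_rate <= 0:
            raise ValidationError("rates must be positive")
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        beat_ms = 1000.0 / self.heart_rate
        for name in ("r_duration_unstim", "r_duration_stim"):
            v = getattr(self, name)
            if not 0 < v < beat_ms:
                raise ValidationError(f"{name} must lie in (0, beat period)")
        if self.stim_latency >= 1000.0 / self.pulse_rate:
            raise ValidationError("stim_latency outside the pulse period")
        if self.mode not in ("ventricular", "nodal"):
            raise ValidationError("mode must be 'ventricular' or 'nodal'")
        if not 0 <= self.dropout < 1:
            raise ValidationError("dropout must lie in [0, 1)")
        if self.noise_sd < 0 or self.jitter_sd < 0:
            raise ValidationError("noise_sd and jitter_sd must be non-negative")


def _ricker(t: np.ndarray, sigma: float) -> np.ndarray:
    """Unit-peak Ricker wavelet; zero crossings at t = ±sigma."""
    z = (t / sigma) ** 2
    return (1.0 - z) * np.exp(-z / 2.0)


def _add_beat(
    samples: np.ndarray,
    fs: float,
    r_time: float,
    r_dur_ms: float,
    pr_ms: float,
) -> tuple[float, float]:
    """Render one PQRST complex into ``samples`` (in place).

    Returns (p_time, pr_ms) for the ground-truth record.  The PR interval is
    defined as the paper defines it: P peak to the first QRS zero crossing,
    which for the Ricker R-wave sits at ``r_time - r_dur/2``.
    """
    sigma_r = r_dur_ms / 2000.0  # s
    qrs_onset = r_time - sigma_r
    p_time = qrs_onset - pr_ms / 1000.0
    t_time = r_time + T_OFFSET_MS / 1000.0

    n = samples.size
    lo = max(int((p_time - 6 * P_SIGMA_MS / 1000.0) * fs), 0)
    hi = min(int((t_time + 6 * T_SIGMA_MS / 1000.0) * fs) + 2, n)
    if lo >= hi:
        return p_time, pr_ms
    t = np.arange(lo, hi) / fs
    seg = R_AMPLITUDE * _ricker(t - r_time, sigma_r)
    seg += P_AMPLITUDE * np.exp(-((t - p_time) ** 2) / (2 * (P_SIGMA_MS / 1000.0) ** 2))
    seg += T_AMPLITUDE * np.exp(-((t - t_time) ** 2) / (2 * (T_SIGMA_MS / 1000.0) ** 2))
    samples[lo:hi] += seg
    return p_time, pr_ms


def synth_ecg(spec: EcgSimSpec) -> tuple[TimeTrace, TimeTrace, GroundTruth]:
    """Generate an ECG trace, the laser TTL trace, and ground truth.

    Autonomous beats occur at multiples of the heart period until
    ``stim_onset_time``; each pulse thereafter captures one beat at the
    commanded latency (minus random dropouts).  Gaussian timing jitter of
    ``jitter_sd`` ms applies to beat times, and independent draws of the same
    SD to each beat's R duration and PR interval.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    n = int(round(spec.duration * fs)) + 1
    ecg = np.zeros(n)

    # laser pulse train
    rising: list[float] = []
    falling: list[float] = []
    if spec.stim_onset_time < spec.duration:
        j = 0
        while True:
            t_on = spec.stim_onset_time + j / spec.pulse_rate
            t_off = t_on + spec.pulse_length / 1000.0
            if t_off > spec.duration:
                break
            rising.append(t_on)
            falling.append(t_off)
            j += 1
    rising_a = np.asarray(rising)
    falling_a = np.asarray(falling)

    beat_times: list[float] = []
    classes: list[str] = []
    r_durs: list[float] = []
    p_times: list[float] = []
    prs: list[float] = []
    matched: list[float] = []

    # autonomous section
    k = 1
    while True:
        nominal = k / spec.heart_rate
        if nominal > spec.duration or nominal >= spec.stim_onset_time:
            break
        r_time = nominal + rng.normal(0.0, spec.jitter_sd / 1000.0)
        d = max(spec.r_duration_unstim + rng.normal(0.0, spec.jitter_sd), 1.0)
        pr = max(spec.pr_interval_unstim + rng.normal(0.0, spec.jitter_sd), 1.0)
        p_t, pr = _add_beat(ecg, fs, r_time, d, pr)
        beat_times.append(r_time)
        classes.append("unstimulated")
        r_durs.append(d)
        p_times.append(p_t)
        prs.append(pr)
        matched.append(math.nan)
        k += 1

    # paced section: one beat per pulse, anchored at the mode's edge
    for j in range(rising_a.size):
        if spec.dropout and rng.random() < spec.dropout:
            continue
        d = max(spec.r_duration_stim + rng.normal(0.0, spec.jitter_sd), 1.0)
        pr = max(spec.pr_interval_stim + rng.normal(0.0, spec.jitter_sd), 1.0)
        jit = rng.normal(0.0, spec.jitter_sd / 1000.0)
        if spec.mode == "ventricular":
            r_time = rising_a[j] + spec.stim_latency / 1000.0 + jit
        else:
            # nodal: the latency anchors the P peak after the falling edge
            p_anchor = falling_a[j] + spec.stim_latency / 1000.0 + jit
            r_time = p_anchor + pr / 1000.0 + d / 2000.0
        if r_time > spec.duration:
            continue
        p_t, pr = _add_beat(ecg, fs, r_time, d, pr)
        beat_times.append(r_time)
        classes.append("stimulated")
        r_durs.append(d)
        p_times.append(p_t)
        prs.append(pr)
        matched.append(j)

    if spec.noise_sd:
        ecg += rng.normal(0.0, spec.noise_sd, n)

    ttl = np.zeros(n)
    t_axis = np.arange(n) / fs
    for t_on, t_off in zip(rising, falling):
        ttl[(t_axis >= t_on) & (t_axis < t_off)] = 1.0

    gt = GroundTruth(
        seed=spec.seed,
        beat_times=np.asarray(beat_times),
        beat_classes=classes,
        r_durations_ms=np.asarray(r_durs),
        p_times=np.asarray(p_times),
        pr_intervals_ms=np.asarray(prs),
        matched_pulse_index=np.asarray(matched),
        pulse_rising=rising_a,
        pulse_falling=falling_a,
        params={"spec": spec},
    )
    return TimeTrace(fs, ecg), TimeTrace(fs, ttl), gt


# ----------------------------------------------------------------------------
# Vessel brightfield video
# ----------------------------------------------------------------------------


@dataclass
class VesselSimSpec:
    """Parameters of the synthetic vessel video.

    The scene is a uniform background plus a fixed smooth texture (so that
    registration has structure to lock onto) plus two vertical Gaussian
    ridges — the vessel sidewalls — whose separation follows
    ``width_timecourse``.  Each frame is translated by an integer-pixel
    jitter (wrap-around) recorded in the ground truth.
    """

    frame_rate: float = 10.0
    n_frames: int = 100
    pixel_size: float = 0.55          # µm/px
    image_shape: tuple[int, int] = (96, 192)  # (rows, cols)
    baseline_width: float = 50.0      # µm
    width_timecourse: Callable[[np.ndarray], np.ndarray] | Sequence[float] | None = None
    wall_profile_sd: float = 2.0      # µm Gaussian ridge width
    wall_intensity: float = 1000.0
    background: float = 100.0
    texture_amplitude: float = 100.0
    noise_sd: float = 0.0
    jitter_max: int = 0               # px
    laser_on: float = 2.0             # s
    laser_off: float = 8.0            # s
    seed: int = 0

    def validate(self) -> None:
        if self.frame_rate <= 0 or self.pixel_size <= 0:
            raise ValidationError("frame_rate and pixel_size must be positive")
        if self.n_frames < 1:
            raise ValidationError("need at least one frame")
        if self.baseline_width <= 4 * self.wall_profile_sd:
            raise ValidationError("baseline_width must exceed 4 x wall_profile_sd")
        widths = self.widths()
        if np.any(widths <= 0):
            raise ValidationError("all commanded widths must be positive")
        fov = self.image_shape[1] * self.pixel_size
        if np.any(widths + 8 * self.wall_profile_sd >= fov):
            raise ValidationError("commanded width exceeds the field of view")
        if self.jitter_max < 0:
            raise ValidationError("jitter_max must be non-negative")

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def widths(self) -> np.ndarray:
        t = self.frame_times()
        if self.width_timecourse is None:
            return np.full(self.n_frames, self.baseline_width)
        if callable(self.width_timecourse):
            return np.asarray(self.width_timecourse(t), dtype=float)
        w = np.asarray(self.width_timecourse, dtype=float)
        if w.size != self.n_frames:
            raise ValidationError("width_timecourse array length != n_frames")
        return w


def step_dilation(
    baseline: float, target: float, onset: float, delay: float = 0.5, rise: float = 2.0
) -> Callable[[np.ndarray], np.ndarray]:
    """Width timecourse: hold ``baseline``, ramp to ``target`` starting
    ``delay`` s after ``onset`` over ``rise`` s."""

    def f(t: np.ndarray) -> np.ndarray:
        frac = np.clip((t - onset - delay) / rise, 0.0, 1.0)
        return baseline + (target - baseline) * frac

    return f


def sinusoid_width(
    baseline: float, amplitude: float, period: float
) -> Callable[[np.ndarray], np.ndarray]:
    """Width timecourse: baseline + amplitude * sin(2 pi t / period)."""

    def f(t: np.ndarray) -> np.ndarray:
        return baseline + amplitude * np.sin(2 * np.pi * t / period)

    return f


def synth_vessel_video(spec: VesselSimSpec) -> tuple[np.ndarray, GroundTruth]:
    """Generate a (n_frames, rows, cols) float stack plus ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_shape
    widths = spec.widths()

    # fixed smooth texture, same in every frame before jitter
    from scipy.ndimage import gaussian_filter

    texture = gaussian_filter(rng.normal(0.0, 1.0, (rows, cols)), sigma=3.0)
    texture *= spec.texture_amplitude / max(texture.std(), 1e-12)

    x_um = np.arange(cols) * spec.pixel_size
    center = cols * spec.pixel_size / 2.0

    if spec.jitter_max:
        jit = rng.integers(-spec.jitter_max, spec.jitter_max + 1, size=(spec.n_frames, 2))
        jit[0] = 0  # reference frame is unshifted
    else:
        jit = np.zeros((spec.n_frames, 2), dtype=int)

    frames = np.empty((spec.n_frames, rows, cols))
    centers = np.empty((spec.n_frames, 2))
    for i in range(spec.n_frames):
        left = center - widths[i] / 2.0
        right = center + widths[i] / 2.0
        ridge = spec.wall_intensity * (
            np.exp(-((x_um - left) ** 2) / (2 * spec.wall_profile_sd**2))
            + np.exp(-((x_um - right) ** 2) / (2 * spec.wall_profile_sd**2))
        )
        scene = spec.background + texture + ridge[np.newaxis, :]
        frame = np.roll(scene, (jit[i, 0], jit[i, 1]), axis=(0, 1))
        if spec.noise_sd:
            frame = frame + rng.normal(0.0, spec.noise_sd, (rows, cols))
        frames[i] = frame
        centers[i] = (left, right)

    gt = GroundTruth(
        seed=spec.seed,
        shift_per_frame=jit,
        width_per_frame=widths,
        wall_centers_um=centers,
        params={"spec": spec},
    )
    return frames, gt


# ----------------------------------------------------------------------------
# Line-scan stack with cardiac modulation
# ----------------------------------------------------------------------------


@dataclass
class LineRecordSet:
    """Line-by-line microscopy acquisitions.

    ``pixels`` holds one acquired line per row, in acquisition order;
    ``times`` the acquisition timestamps and ``row_index`` the spatial row
    each line belongs to within a frame of ``rows_per_frame`` rows.
    """

    pixels: np.ndarray          # (n_lines, n_cols)
    times: np.ndarray           # (n_lines,)
    row_index: np.ndarray       # (n_lines,) ints in [0, rows_per_frame)
    rows_per_frame: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) < 0):
            raise ValidationError("line acquisition times must be non-decreasing")
        if np.any((self.row_index < 0) | (self.row_index >= self.rows_per_frame)):
            raise ValidationError("row_index out of range")


def synth_linescan(
    n_lines_per_frame: int,
    frame_rate: float,
    cardiac_period: float,
    resp_period: float,
    modulation_depth: float,
    seed: int = 0,
    n_frames: int = 30,
    n_cols: int = 32,
    noise_sd: float = 0.0,
) -> tuple[LineRecordSet, TimeTrace, TimeTrace, GroundTruth]:
    """Line-scan stack whose intensity is modulated by a simulated cardiac cycle.

    Lines are acquired row by row at ``n_lines_per_frame * frame_rate`` lines
    per second.  Each line's intensity is ``base_row * (1 + depth * s(phase))``
    with ``s(phase) = sin(2 pi phase)`` and phase measured from the nearest
    preceding simulated R peak (R peaks at exact multiples of
    ``cardiac_period``).  A sinusoidal respiration trace with peaks at
    ``resp_period * (k + 1/4)`` is returned alongside a spike-train ECG.
    """
    if not cardiac_period < resp_period:
        raise ValidationError("cardiac_period must be shorter than resp_period")
    if not 0 <= modulation_depth < 1:
        raise ValidationError("modulation_depth must lie in [0, 1)")
    if n_lines_per_frame < 1 or n_frames < 1 or n_cols < 1:
        raise ValidationError("counts must be positive")
    rng = np.random.default_rng(seed)

    line_rate = n_lines_per_frame * frame_rate
    n_lines = n_lines_per_frame * n_frames
    times = np.arange(n_lines) / line_rate
    row_index = np.arange(n_lines) % n_lines_per_frame

    total = times[-1] if n_lines > 1 else cardiac_period
    r_peaks = np.arange(0.0, total + 2 * cardiac_period, cardiac_period)
    phases = (times % cardiac_period) / cardiac_period

    # static spatial pattern: smooth row x column structure
    rr = row_index[:, None] / n_lines_per_frame
    cc = np.arange(n_cols)[None, :] / n_cols
    base = 100.0 + 30.0 * np.sin(2 * np.pi * rr) * np.cos(2 * np.pi * cc) + 20.0 * cc

    def s(phase: np.ndarray) -> np.ndarray:
        return np.sin(2 * np.pi * np.asarray(phase))

    pixels = base * (1.0 + modulation_depth * s(phases)[:, None])
    if noise_sd:
        pixels = pixels + rng.normal(0.0, noise_sd, pixels.shape)

    lines = LineRecordSet(pixels, times, row_index, n_lines_per_frame)

    # companion traces
    fs_ecg = max(1000.0, 20.0 / cardiac_period)
    n_ecg = int(round((total + cardiac_period) * fs_ecg)) + 1
    ecg = np.zeros(n_ecg)
    for rp in r_peaks:
        i = int(round(rp * fs_ecg))
        if 0 <= i < n_ecg:
            t_loc = np.arange(max(i - 40, 0), min(i + 41, n_ecg)) / fs_ecg
            ecg[max(i - 40, 0) : min(i + 41, n_ecg)] += _ricker(t_loc - rp, 0.006)
    fs_resp = 200.0
    t_resp = np.arange(int(round((total + resp_period) * fs_resp)) + 1) / fs_resp
    resp = np.sin(2 * np.pi * t_resp / resp_period)
    resp_peaks = resp_period * (np.arange(int(total / resp_period) + 1) + 0.25)

    gt = GroundTruth(
        seed=seed,
        phase_per_line=phases,
        line_times=times,
        r_peak_times=r_peaks,
        resp_peak_times=resp_peaks,
        modulation=s,
        params={
            "n_lines_per_frame": n_lines_per_frame,
            "frame_rate": frame_rate,
            "cardiac_period": cardiac_period,
            "resp_period": resp_period,
            "modulation_depth": modulation_depth,
        },
    )
    return lines, TimeTrace(fs_ecg, ecg), TimeTrace(fs_resp, resp), gt


# ----------------------------------------------------------------------------
# Pacing-locked fluorescence transients
# ----------------------------------------------------------------------------


def fluor_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Transient kernel (1 - exp(-t/rise)) * exp(-t/decay) for t >= 0, else 0.

    ``rise`` and ``decay`` in the same units as ``t``.
    """
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, (1.0 - np.exp(-np.maximum(t, 0) / rise)) * np.exp(-np.maximum(t, 0) / decay), 0.0)
    return out


def synth_fluor_trace(
    pulses: PulseTrain,
    latency: float,
    rise: float,
    decay: float,
    amplitude: float,
    noise_sd: float,
    sampling_rate: float,
    seed: int = 0,
    baseline: float = 100.0,
    duration: float | None = None,
) -> tuple[TimeTrace, GroundTruth]:
    """Ca2+-indicator trace with one transient ``latency`` ms after each pulse.

    ``latency``, ``rise`` and ``decay`` are in milliseconds.  Overlapping
    transients sum.  The constant ``baseline`` carries no information; the
    analysis detrends it away.
    """
    if latency <= 0 or rise <= 0 or decay <= 0:
        raise ValidationError("latency, rise and decay must be positive")
    if sampling_rate <= 0:
        raise ValidationError("sampling_rate must be positive")
    rng = np.random.default_rng(seed)
    if duration is None:
        last = pulses.rising_edges[-1] if pulses.n_pulses else 0.0
        duration = last + (latency + 8 * decay) / 1000.0
    n = int(round(duration * sampling_rate)) + 1
    t = np.arange(n) / sampling_rate
    trace = np.full(n, float(baseline))
    onsets = pulses.rising_edges + latency / 1000.0 if pulses.n_pulses else np.empty(0)
    for onset in onsets:
        trace += amplitude * fluor_kernel(t - onset, rise / 1000.0, decay / 1000.0)
    if noise_sd:
        trace += rng.normal(0.0, noise_sd, n)

    # single-transient peak value of the kernel (analytic argmax)
    t_star = rise / 1000.0 * np.log1p(decay / rise)
    peak = amplitude * float(fluor_kernel(np.array([t_star]), rise / 1000.0, decay / 1000.0)[0])

    gt = GroundTruth(
        seed=seed,
        transient_onset_times=onsets,
        transient_peak=peak,
        params={
            "latency_ms": latency,
            "rise_ms": rise,
            "decay_ms": decay,
            "amplitude": amplitude,
            "baseline": baseline,
        },
    )
    return TimeTrace(sampling_rate, trace), gt
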