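"""Vessel-diameter videometry.

Pipeline for brightfield videos of an artery: stabilize frames by integer
translation maximizing normalized cross-correlation with the first frame
(optionally restricted to a region unaffected by laser light leakage),
interpolate a band-averaged intensity profile along a user line across the
vessel, detect the two sidewall peaks with three-point quadratic sub-pixel
refinement, and summarize opto-stimulation responses as
``((MAX - MIN)/MIN) * 100`` with MIN taken over the first seconds after
laser activation and MAX during activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as spsig
from scipy.ndimage import map_coordinates

from .exceptions import PipelineError, TwoWallsNotFoundError, ValidationError
from .stats import holm_sidak, holm_sidak_adjust  # noqa: F401  (this stage's statistics surface)

DEFAULT_BAND_WIDTH_UM = 28.05
DEFAULT_SEARCH_RADIUS_PX = 20
DEFAULT_SMOOTH_WINDOW = 5
DEFAULT_MIN_SEARCH_S = 10.0


@dataclass
class FrameStack:
    """Ordered 2-D frames with acquisition geometry.

    ``exclusion`` is an optional (row0, row1, col0, col1) rectangle (half-open)
    to *ignore* during registration — e.g. the area lit by the stimulation
    laser.
    """

    frames: np.ndarray            # (n, rows, cols)
    frame_rate: float
    pixel_size: float             # µm/px
    exclusion: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValidationError("frames must be a (n, rows, cols) array")
        if self.frame_rate <= 0 or self.pixel_size <= 0:
            raise ValidationError("frame_rate and pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class MeasureLine:
    """A measurement chord across the vessel, in pixel coordinates (x, y),
    with the perpendicular band width (µm) over which intensity is averaged."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    band_width: float = DEFAULT_BAND_WIDTH_UM

    def __post_init__(self) -> None:
        if tuple(self.p0) == tuple(self.p1):
            raise ValidationError("line endpoints must be distinct")
        if self.band_width <= 0:
            raise ValidationError("band_width must be positive")


def _registration_mask(shape: tuple[int, int], exclusion) -> np.ndarray:
    mask = np.ones(shape, dtype=bool)
    if exclusion is not None:
        r0, r1, c0, c1 = exclusion
        mask[r0:r1, c0:c1] = False
    if not mask.any():
        raise ValidationError("exclusion region covers the whole frame")
    return mask


def register_translation(
    ref: np.ndarray,
    frame: np.ndarray,
    mask: np.ndarray | None = None,
    search_radius: int = DEFAULT_SEARCH_RADIUS_PX,
) -> tuple[int, int]:
    """Integer (dy, dx) such that ``np.roll(frame, (dy, dx))`` best matches
    ``ref`` by Pearson correlation over ``mask`` (wrap-around semantics).

    Exhaustive over the ±search_radius grid; ties resolved toward the
    smallest shift (then lexicographically), so identical frames give (0, 0).
    """
    h, w = ref.shape
    if mask is None:
        mask = np.ones_like(ref, dtype=bool)
    m = mask.astype(float)
    n_px = m.sum()
    r0 = np.where(mask, ref - ref[mask].mean(), 0.0)
    rnorm = np.linalg.norm(r0)
    if rnorm == 0:
        return 0, 0
    # For circular shift s, the rolled frame sampled on the mask is
    # f(p - s); all masked sums over shifts come from FFT correlations.
    fm = np.fft.rfft2(frame)
    fm2 = np.fft.rfft2(frame**2)
    mk = np.conj(np.fft.rfft2(m))
    rk = np.conj(np.fft.rfft2(r0))
    s1 = np.fft.irfft2(mk * fm, s=(h, w))    # sum_mask f(p - s)
    s2 = np.fft.irfft2(mk * fm2, s=(h, w))   # sum_mask f(p - s)^2
    sr = np.fft.irfft2(rk * fm, s=(h, w))    # sum_mask r0(p) f(p - s)
    var = np.maximum(s2 - s1**2 / n_px, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = sr / (rnorm * np.sqrt(var))
    corr[var <= 0] = -np.inf

    shifts = [
        (dy, dx)
        for dy in range(-search_radius, search_radius + 1)
        for dx in range(-search_radius, search_radius + 1)
    ]
    shifts.sort(key=lambda s: (s[0] ** 2 + s[1] ** 2, s[0], s[1]))
    best, best_c = (0, 0), -np.inf
    for dy, dx in shifts:
        c = corr[(-dy) % h, (-dx) % w]
        if c > best_c + 1e-9:
            best, best_c = (dy, dx), float(c)
    return best


def stabilize_stack(
    stack: FrameStack, search_radius: int = DEFAULT_SEARCH_RADIUS_PX
) -> tuple[FrameStack, np.ndarray]:
    """Translate every frame to maximize correlation with frame 0.

    Returns the stabilized stack and an (n, 2) array of applied (dy, dx)
    shifts in pixels.
    """
    if stack.n_frames < 2:
        raise ValidationError("need at least two frames to stabilize")
    mask = _registration_mask(stack.frames.shape[1:], stack.exclusion)
    ref = stack.frames[0]
    out = np.empty_like(stack.frames)
    shifts = np.zeros((stack.n_frames, 2), dtype=int)
    out[0] = ref
    for i in range(1, stack.n_frames):
        dy, dx = register_translation(ref, stack.frames[i], mask, search_radius)
        shifts[i] = (dy, dx)
        out[i] = np.roll(stack.frames[i], (dy, dx), axis=(0, 1))
    return FrameStack(out, stack.frame_rate, stack.pixel_size, stack.exclusion), shifts


def band_sample_count(band_width: float, pixel_size: float) -> int:
    """Number of perpendicular samples: band_width/pixel_size rounded to the
    nearest odd integer (spacing one pixel)."""
    k = int(round((band_width / pixel_size - 1.0) / 2.0))
    return max(2 * k + 1, 1)


def extract_profile(
    frame: np.ndarray,
    line: MeasureLine,
    pixel_size: float,
    step_px: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Band-averaged intensity profile along the measurement line.

    Intensities are bilinearly interpolated at ``step_px`` steps along the
    line; at each position the mean is taken over a perpendicular band of
    total width ``line.band_width`` µm sampled at one-pixel spacing.

    Returns (positions_um, intensities); positions measured from ``p0``.
    """
    p0 = np.asarray(line.p0, dtype=float)  # (x, y)
    p1 = np.asarray(line.p1, dtype=float)
    vec = p1 - p0
    length = float(np.linalg.norm(vec))
    u = vec / length
    perp = np.array([-u[1], u[0]])
    n_steps = int(np.floor(length / step_px)) + 1
    s = np.arange(n_steps) * step_px
    nb = band_sample_count(line.band_width, pixel_size)
    offsets = (np.arange(nb) - (nb - 1) / 2.0)
    # sample coordinates: (n_steps, nb, 2) in (x, y)
    pts = p0[None, None, :] + s[:, None, None] * u[None, None, :] + offsets[None, :, None] * perp[None, None, :]
    xcoord, ycoord = pts[..., 0], pts[..., 1]
    h, w = frame.shape
    oob = (xcoord < 0) | (ycoord < 0) | (xcoord > w - 1) | (ycoord > h - 1)
    if oob.any():
        # name whichever endpoint's half of the line carries the violation
        bad = "p0" if np.argwhere(oob)[0][0] < n_steps // 2 else "p1"
        raise ValidationError(f"averaging band around endpoint {bad} exits the frame")
    vals = map_coordinates(frame, [ycoord.ravel(), xcoord.ravel()], order=1, mode="nearest")
    prof = vals.reshape(n_steps, nb).mean(axis=1)
    return s * pixel_size, prof


def _quad_refine(pos: np.ndarray, y: np.ndarray, i: int, halfwidth: int = 1) -> tuple[float, float]:
    """Quadratic-fit refinement of peak index ``i``; returns (position, value)."""
    lo, hi = i - halfwidth, i + halfwidth
    if lo < 0 or hi >= y.size:
        return float(pos[i]), float(y[i])
    if halfwidth == 1:
        denom = y[i - 1] - 2 * y[i] + y[i + 1]
        if denom >= 0:  # not a concave triple; keep the sample
            return float(pos[i]), float(y[i])
        delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
        step = pos[i + 1] - pos[i]
        val = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
        return float(pos[i] + delta * step), float(val)
    coef = np.polyfit(pos[lo : hi + 1], y[lo : hi + 1], 2)
    if coef[0] >= 0:
        return float(pos[i]), float(y[i])
    xv = -coef[1] / (2 * coef[0])
    return float(xv), float(np.polyval(coef, xv))


def detect_walls(
    positions: np.ndarray,
    intensities: np.ndarray,
    fit_halfwidth: int = 2,
) -> tuple[float, float, float, float]:
    """Locate the two vessel sidewalls in a cross-vessel intensity profile.

    The two most *prominent* local maxima are selected (robust to lumen
    glare), each refined by a quadratic fit around the peak.  Returns
    (left_pos, right_pos, left_intensity, right_intensity) with
    left_pos < right_pos.
    """
    y = np.asarray(intensities, dtype=float)
    if y.size < 5:
        raise ValidationError("profile too short (need >= 5 samples)")
    idx, props = spsig.find_peaks(y, prominence=0.0)
    if idx.size < 2:
        raise TwoWallsNotFoundError("fewer than two local maxima in profile")
    top2 = idx[np.argsort(props["prominences"])[-2:]]
    refined = [_quad_refine(np.asarray(positions, float), y, int(i), fit_halfwidth) for i in top2]
    refined.sort(key=lambda pv: pv[0])
    (lp, li), (rp, ri) = refined
    return lp, rp, li, ri


def diameter_series(
    stack: FrameStack,
    line: MeasureLine,
    shifts: np.ndarray | None = None,
    max_fail_fraction: float = 0.5,
    fit_halfwidth: int = 2,
) -> pd.DataFrame:
    """Per-frame vessel width and sidewall positions/intensities.

    The stack is assumed stabilized.  Frames where the two walls cannot be
    found carry NaN (a >``max_fail_fraction`` failure rate is an error).
    """
    n = stack.n_frames
    cols = {
        "time_s": stack.times,
        "width_um": np.full(n, np.nan),
        "left_um": np.full(n, np.nan),
        "right_um": np.full(n, np.nan),
        "left_intensity": np.full(n, np.nan),
        "right_intensity": np.full(n, np.nan),
        "shift_dy_px": shifts[:, 0] if shifts is not None else np.zeros(n),
        "shift_dx_px": shifts[:, 1] if shifts is not None else np.zeros(n),
    }
    failures = 0
    for i in range(n):
        try:
            pos, prof = extract_profile(stack.frames[i], line, stack.pixel_size)
            lp, rp, li, ri = detect_walls(pos, prof, fit_halfwidth)
        except (TwoWallsNotFoundError, ValidationError):
            failures += 1
            continue
        cols["left_um"][i] = lp
        cols["right_um"][i] = rp
        cols["width_um"][i] = rp - lp
        cols["left_intensity"][i] = li
        cols["right_intensity"][i] = ri
    if failures > max_fail_fraction * n:
        raise PipelineError(
            f"wall detection failed on {failures}/{n} frames (> {max_fail_fraction:.0%})"
        )
    return pd.DataFrame(cols)


def smooth_running_average(trace: pd.DataFrame, window: int = DEFAULT_SMOOTH_WINDOW) -> pd.DataFrame:
    """Centered running average of the width column (NaNs skipped)."""
    if window < 1 or window % 2 == 0:
        raise ValidationError("window must be odd and >= 1")
    if window > len(trace):
        raise ValidationError("window longer than the series")
    out = trace.copy()
    out["width_um"] = (
        trace["width_um"].rolling(window, center=True, min_periods=1).mean()
    )
    return out


@dataclass
class ResponseMetrics:
    """Opto-stimulation response summary of a (smoothed) diameter trace."""

    min_width: float
    max_width: float
    net_change: float
    pct_change: float


def response_metrics(
    trace: pd.DataFrame,
    laser_on: float,
    laser_off: float,
    min_search: float = DEFAULT_MIN_SEARCH_S,
    direction: str = "dilate",
) -> ResponseMetrics:
    """MIN / MAX / percent-change response to laser activation.

    For dilation: MIN is the minimum smoothed width in the first
    ``min_search`` seconds after ``laser_on``; MAX the maximum during
    activation ``[laser_on, laser_off]``.  For constriction the roles swap
    (MAX = pre-response maximum in the search window, MIN = minimum during
    activation).  ``pct_change = ((MAX - MIN)/MIN) * 100``;
    ``net_change = MAX - MIN``.
    """
    if laser_on >= laser_off:
        raise ValidationError("laser_on must precede laser_off")
    if direction not in ("dilate", "constrict"):
        raise ValidationError("direction must be 'dilate' or 'constrict'")
    t = trace["time_s"].to_numpy()
    w = trace["width_um"].to_numpy()
    early = (t >= laser_on) & (t <= laser_on + min_search) & np.isfinite(w)
    active = (t >= laser_on) & (t <= laser_off) & np.isfinite(w)
    if not early.any() or not active.any():
        raise ValidationError("no valid width samples in the search window")
    if direction == "dilate":
        wmin = float(np.min(w[early]))
        wmax = float(np.max(w[active]))
    else:
        wmax = float(np.max(w[early]))
        wmin = float(np.min(w[active]))
    return ResponseMetrics(
        min_width=wmin,
        max_width=wmax,
        net_change=wmax - wmin,
        pct_change=(wmax - wmin) / wmin * 100.0,
    )
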