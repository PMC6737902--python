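"""Blood-flow velocimetry by FFT phase correlation, kymographs, heart rate.

The frame-to-frame translation of red blood cells in a cropped vessel movie
is estimated by classic phase correlation: the normalized cross-power
spectrum ``F(a) . conj(F(b)) / |F(a) . conj(F(b))|`` is inverse-transformed
into a correlation map whose peak offset from the origin is the shift
between the frames. The map is smoothed with a small Gaussian before the
argmax is taken, and the offset is unwrapped to the centred range
[-dim/2, dim/2), assuming the dominant motion is less than half the crop.

Speed per frame pair is |displacement| x pixel_size / frame_interval (um/s),
optionally smoothed with a centred moving average (span 5 by default).
Heart rate is extracted from an intensity trace (or a width-1 kymograph) by
peak detection over a window synced to the first detected beat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .datatypes import ImageStack

__all__ = [
    "phase_correlation_shift",
    "velocity_trace",
    "VelocityTrace",
    "build_kymograph",
    "heart_rate",
]


def phase_correlation_shift(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    gaussian_sigma: float = 1.0,
    normalize: bool = True,
    subpixel: bool = False,
) -> tuple[float, float]:
    """Shift ``(dx, dy)`` in pixels such that ``frame_b ~ frame_a`` moved by it.

    Computes the inverse FFT of the (magnitude-normalized) cross-power
    spectrum of the two frames, Gaussian-smooths the resulting correlation
    map (circularly), and locates its maximum; the peak position, unwrapped
    to [-dim/2, dim/2), is the translation of ``frame_b`` relative to
    ``frame_a``. With ``subpixel=True`` a 3-point parabolic refinement is
    applied around the integer peak (off by default).
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("frames must be 2-D arrays of identical shape")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant frame: spectrum normalization undefined")
    fa = np.fft.fft2(a)
    fb = np.fft.fft2(b)
    cross = fa * np.conj(fb)
    if normalize:
        mag = np.abs(cross)
        cross = cross / np.where(mag > 0, mag, 1.0)
    corr = np.real(np.fft.ifft2(cross))
    if gaussian_sigma > 0:
        corr = gaussian_filter(corr, gaussian_sigma, mode="wrap")
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    H, W = corr.shape
    # cross = F(a) conj(F(b)) has its correlation-map peak at index -d
    # (mod frame size) where b(x) = a(x - d), so the displacement of b
    # relative to a is minus the peak position
    dy, dx = float(peak[0]), float(peak[1])
    if subpixel:
        dy += _parabolic_offset(
            corr[(peak[0] - 1) % H, peak[1]], corr[peak], corr[(peak[0] + 1) % H, peak[1]]
        )
        dx += _parabolic_offset(
            corr[peak[0], (peak[1] - 1) % W], corr[peak], corr[peak[0], (peak[1] + 1) % W]
        )
    # negate, then unwrap to the centred range
    dx = (-dx + W / 2.0) % W - W / 2.0
    dy = (-dy + H / 2.0) % H - H / 2.0
    return dx, dy


def _parabolic_offset(cm: float, c0: float, cp: float) -> float:
    denom = cm - 2.0 * c0 + cp
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))


@dataclass
class VelocityTrace:
    """Raw and smoothed speed (um/s) per frame pair."""

    displacements_px: np.ndarray  # (n_frames-1, 2): (dx, dy)
    raw_um_s: np.ndarray
    smoothed_um_s: np.ndarray
    span: int


def moving_average(x: np.ndarray, span: int = 5) -> np.ndarray:
    """Centred moving average with shrinking windows at the trace ends.

    Output has the same length as the input; at each end the window shrinks
    symmetrically (span 5 becomes 3 then 1), so interior values equal the
    plain span-wide mean.
    """
    x = np.asarray(x, dtype=float)
    half = span // 2
    out = np.empty_like(x)
    n = len(x)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = x[i - k : i + k + 1].mean()
    return out


def velocity_trace(
    stack: ImageStack,
    gaussian_sigma: float = 1.0,
    span: int = 5,
    subpixel: bool = False,
) -> VelocityTrace:
    """Per-frame-pair flow speed from phase correlation, with smoothing.

    Speed_i = |shift(frame_i, frame_{i+1})| x pixel_size / frame_interval.
    The displacement magnitude trace is smoothed with a centred moving
    average of the given span (the components are returned unsmoothed).
    """
    disps = np.empty((stack.n_frames - 1, 2))
    for i in range(stack.n_frames - 1):
        disps[i] = phase_correlation_shift(
            stack.frames[i], stack.frames[i + 1], gaussian_sigma, subpixel=subpixel
        )
    raw = (
        np.hypot(disps[:, 0], disps[:, 1])
        * stack.pixel_size_um
        / stack.frame_interval_s
    )
    return VelocityTrace(disps, raw, moving_average(raw, span), span)


def build_kymograph(
    stack: ImageStack,
    line: tuple[tuple[float, float], tuple[float, float]],
    width: int = 1,
) -> np.ndarray:
    """Space x time intensity image sampled along a line in every frame.

    ``line`` is ``((x0, y0), (x1, y1))`` in pixel coordinates (x = column,
    y = row). Width 1 samples the nearest pixel at unit steps along the
    line; larger (odd) widths average over perpendicular unit offsets.
    Returns an array of shape (n_samples, n_frames).
    """
    (x0, y0), (x1, y1) = line
    length = float(np.hypot(x1 - x0, y1 - y0))
    n = max(2, int(round(length)) + 1)
    xs = np.linspace(x0, x1, n)
    ys = np.linspace(y0, y1, n)
    if length == 0:
        ux, uy = 0.0, 0.0
    else:
        ux, uy = (y1 - y0) / length, -(x1 - x0) / length  # unit normal
    offsets = np.arange(width) - (width - 1) / 2.0
    H, W = stack.frames.shape[1:]
    cols = []
    for off in offsets:
        ci = np.rint(xs + off * ux).astype(int)
        ri = np.rint(ys + off * uy).astype(int)
        if ci.min() < 0 or ci.max() >= W or ri.min() < 0 or ri.max() >= H:
            raise ValueError("line (with width offsets) leaves the image bounds")
        cols.append(stack.frames[:, ri, ci].T)  # (n_samples, n_frames)
    return np.mean(cols, axis=0)


def _dominant_period_samples(x: np.ndarray) -> int:
    """Dominant period (samples) from the autocorrelation of the trace.

    The lag-0 main lobe is skipped by walking to the first local minimum of
    the (lightly smoothed) autocorrelation; the period is the argmax beyond
    it. A monotonically decaying autocorrelation means no periodicity.
    """
    xc = x - x.mean()
    ac = np.correlate(xc, xc, mode="full")[len(x) - 1 :]
    ac = gaussian_filter1d(ac, 1.0)
    rising = np.nonzero(np.diff(ac) > 0)[0]
    if len(rising) == 0:
        raise ValueError("no beats detected: trace is flat or aperiodic")
    start = int(rising[0]) + 1
    period = start + int(np.argmax(ac[start:]))
    if period <= 0 or ac[period] <= 0:
        raise ValueError("no beats detected: trace is flat or aperiodic")
    return period


def heart_rate(
    trace: np.ndarray,
    sample_interval_s: float,
    window_s: float = 8.0,
    synced_to_beat_start: bool = True,
    threshold_k: float = 1.0,
) -> float:
    """Heart rate (beats per minute) from an intensity trace or kymograph.

    A 2-D input (kymograph, space x time) is reduced to its spatial-mean
    trace. The dominant beat period is taken from the autocorrelation; the
    trace is lightly Gaussian-smoothed (sigma = 5% of the period), and beats
    are local maxima above mean + k.SD separated by at least 40% of the
    period. Beats are counted over a window of ``window_s`` starting at the
    first detected beat (truncated at the trace end; for a periodic signal
    the count is unaffected), and the rate is beats / window x 60.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim == 2:
        x = x.mean(axis=0)
    if sample_interval_s <= 0:
        raise ValueError("sample_interval_s must be positive")
    duration = len(x) * sample_interval_s
    if window_s > duration + 1e-9:
        raise ValueError("window exceeds trace duration")
    if np.ptp(x) == 0:
        raise ValueError("no beats detected: trace is flat")
    period = _dominant_period_samples(x)
    smooth = gaussian_filter1d(x, sigma=max(1.0, 0.05 * period))
    height = smooth.mean() + threshold_k * smooth.std()
    distance = max(1, int(round(0.4 * period)))
    peaks, _ = signal.find_peaks(smooth, height=height, distance=distance)
    if len(peaks) == 0:
        raise ValueError("no beats detected")
    t_peaks = peaks * sample_interval_s
    t0 = t_peaks[0] if synced_to_beat_start else 0.0
    n_beats = int(np.sum((t_peaks >= t0) & (t_peaks < t0 + window_s)))
    if n_beats == 0:
        raise ValueError("no beats detected in window")
    return n_beats / window_s * 60.0
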