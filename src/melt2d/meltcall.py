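"""Peak calling on melt traces: smoothing, negative derivative, local maxima.

A melting transition appears as a peak in -dF/dT. The derivative is taken
with a Savitzky-Golay local-quadratic filter evaluated at its first
derivative, which is the least-squares analogue of smoothing followed by
central differencing but with lower noise amplification. Peaks are local
maxima above both a relative threshold (fraction of the channel's global
maximum) and an absolute floor tied to a robust noise estimate, separated by
a minimum temperature distance, and refined to sub-grid precision by
parabolic interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import math
from typing import Optional

import numpy as np
from scipy.signal import find_peaks, savgol_coeffs, savgol_filter

from .panel import Channel
from .simulate import MeltTrace

__all__ = [
    "DEFAULT_SMOOTH_WINDOW_C",
    "DEFAULT_MIN_HEIGHT_FRAC",
    "DEFAULT_MIN_SEPARATION_C",
    "DEFAULT_FLOOR_MADS",
    "DerivativeCurve",
    "PeakCall",
    "negative_derivative",
    "detect_peaks",
    "call_peaks",
]

DEFAULT_SMOOTH_WINDOW_C = 0.5
DEFAULT_MIN_HEIGHT_FRAC = 0.25
DEFAULT_MIN_SEPARATION_C = 1.5
DEFAULT_FLOOR_MADS = 5.0
#: absolute minimum peak height above baseline (relative fluorescence units
#: per deg C); guards channels whose only variation is numerical ripple
DEFAULT_MIN_ABS_HEIGHT = 1e-3


@dataclass
class DerivativeCurve:
    """Smoothed -dF/dT of one trace.

    ``noise_sd`` is the propagated standard deviation of the derivative due
    to point noise on the fluorescence trace, estimated independently of any
    melting signal; peak detection uses it for its absolute floor.
    """

    channel: Channel
    temperatures: np.ndarray
    neg_dfdt: np.ndarray
    noise_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.temperatures.shape != self.neg_dfdt.shape:
            raise ValueError("temperature and derivative lengths differ")
        if not np.all(np.isfinite(self.neg_dfdt)):
            raise ValueError("derivative contains non-finite values")


@dataclass(frozen=True)
class PeakCall:
    """One detected melting peak: refined Tm, height and prominence."""

    channel: Channel
    tm_c: float
    height: float
    prominence: float


def negative_derivative(trace: MeltTrace, smooth_window_c: float = DEFAULT_SMOOTH_WINDOW_C) -> DerivativeCurve:
    """Smoothed negative temperature derivative of a melt trace.

    Fits a local quadratic over a ``smooth_window_c``-wide window and takes
    its derivative at each point (Savitzky-Golay, order 2, deriv 1). Output
    has the same length as the input.
    """
    t = trace.temperatures
    f = trace.fluorescence
    if t.size < 5:
        raise ValueError("trace too short for derivative estimation (need >= 5 points)")
    step = float(np.median(np.diff(t)))
    if smooth_window_c < step:
        raise ValueError("smooth_window_c must be at least one grid step")
    window = int(round(smooth_window_c / step)) + 1
    window = max(window, 5)
    if window % 2 == 0:
        window += 1
    window = min(window, t.size if t.size % 2 == 1 else t.size - 1)
    dfdt = savgol_filter(f, window_length=window, polyorder=2, deriv=1, delta=step)
    # Point-noise scale of F from the lower quartile of successive absolute
    # differences (insensitive to melting transitions even when they cover
    # most of the ramp: |d| ~ HalfNormal(sigma*sqrt(2)), q25 = 0.3186 of its
    # scale), propagated through the derivative kernel's L2 norm.
    d = np.abs(np.diff(f))
    sigma_f = float(np.quantile(d, 0.25)) / (0.3186 * math.sqrt(2.0))
    kernel = savgol_coeffs(window, 2, deriv=1, delta=step)
    noise_sd = sigma_f * float(np.sqrt(np.sum(kernel**2)))
    return DerivativeCurve(
        channel=trace.channel, temperatures=t, neg_dfdt=-dfdt, noise_sd=noise_sd
    )


def _robust_sigma(x: np.ndarray) -> float:
    mad = float(np.median(np.abs(x - np.median(x))))
    return 1.4826 * mad


def _baseline_and_sigma(
    y: np.ndarray, distance: int, min_height_frac: float
) -> tuple[float, float]:
    """Robust baseline level and noise scale of a derivative curve.

    Provisionally detects peaks (relative to a low-quantile reference), masks
    their neighbourhoods, and takes median/MAD over the remaining quiet
    region, so neither crowded channels (where melting transitions cover
    most of the ramp) nor empty ones bias the estimates. If nothing is
    quiet - a peakless noise-only trace masks itself entirely - falls back
    to global median/MAD, which is then exactly the noise.
    """
    ref = float(np.quantile(y, 0.10))
    h = y - ref
    hmax = float(h.max(initial=0.0))
    quiet = np.ones(y.size, dtype=bool)
    if hmax > 0:
        idx, _ = find_peaks(h, height=min_height_frac * hmax, distance=distance)
        for i in idx:
            quiet[max(0, i - distance): i + distance + 1] = False
    if quiet.sum() < max(20, y.size // 10):
        return float(np.median(y)), _robust_sigma(y)
    yq = y[quiet]
    base = float(np.median(yq))
    return base, 1.4826 * float(np.median(np.abs(yq - base)))


def _parabolic_refine(t: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through (i-1, i, i+1); falls back to the sample."""
    if i == 0 or i == y.size - 1:
        return float(t[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not locally concave; keep the grid point
        return float(t[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = float(t[i + 1] - t[i]) if delta >= 0 else float(t[i] - t[i - 1])
    tm = float(t[i]) + delta * step
    height = float(y1 - 0.25 * (y0 - y2) * delta)
    return tm, height


def detect_peaks(
    curve: DerivativeCurve,
    min_height_frac: float = DEFAULT_MIN_HEIGHT_FRAC,
    min_separation_c: float = DEFAULT_MIN_SEPARATION_C,
    floor_mads: float = DEFAULT_FLOOR_MADS,
    min_abs_height: float = DEFAULT_MIN_ABS_HEIGHT,
) -> list[PeakCall]:
    """Detect melting peaks on a negative-derivative curve.

    Heights are measured above the channel's quiet between-peak baseline
    (which includes any linear-baseline offset). A local maximum is kept if
    its height reaches ``min_height_frac`` of the channel's maximum height
    and also exceeds an absolute floor - the larger of ``floor_mads`` robust
    noise standard deviations and ``min_abs_height`` - and if it is at least
    ``min_separation_c`` away from any larger peak. Grid-boundary points are
    never peaks. Returned sorted by descending Tm.
    """
    if not 0.0 < min_height_frac < 1.0:
        raise ValueError("min_height_frac must be in (0, 1)")
    if min_separation_c <= 0:
        raise ValueError("min_separation_c must be positive")
    t = curve.temperatures
    y = curve.neg_dfdt
    step = float(np.median(np.diff(t)))
    distance = max(1, int(round(min_separation_c / step)))
    base, sigma_quiet = _baseline_and_sigma(y, distance, min_height_frac)
    sigma = curve.noise_sd if curve.noise_sd is not None else sigma_quiet
    h = y - base
    floor = max(floor_mads * sigma, min_abs_height)
    threshold = max(min_height_frac * float(h.max(initial=0.0)), floor)
    idx, props = find_peaks(h, height=threshold, distance=distance, prominence=0.0)
    calls = []
    for i, prom in zip(idx, props["prominences"]):
        tm, height = _parabolic_refine(t, h, int(i))
        calls.append(PeakCall(channel=curve.channel, tm_c=tm, height=height, prominence=float(prom)))
    calls.sort(key=lambda p: -p.tm_c)
    return calls


def call_peaks(
    trace: MeltTrace,
    smooth_window_c: float = DEFAULT_SMOOTH_WINDOW_C,
    min_height_frac: float = DEFAULT_MIN_HEIGHT_FRAC,
    min_separation_c: float = DEFAULT_MIN_SEPARATION_C,
    floor_mads: float = DEFAULT_FLOOR_MADS,
) -> list[PeakCall]:
    """Derivative plus peak detection in one step."""
    curve = negative_derivative(trace, smooth_window_c=smooth_window_c)
    return detect_peaks(
        curve,
        min_height_frac=min_height_frac,
        min_separation_c=min_separation_c,
        floor_mads=floor_mads,
    )
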