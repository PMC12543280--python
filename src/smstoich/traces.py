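"""Per-spot trace extraction, Z-score normalization, and bleach half-times."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .simulate import Trace

__all__ = [
    "NormalizedTrace",
    "DegenerateTraceError",
    "NoBleachingError",
    "extract_trace",
    "zscore",
    "zscore_values",
    "bleach_half_time",
    "survival_from_bleach_times",
]


class DegenerateTraceError(ValueError):
    """Trace has too few frames or zero variance to normalize."""


class NoBleachingError(ValueError):
    """Survival curve shows no decay; half-time undefined."""


@dataclass
class NormalizedTrace:
    """Z-scored trace: zero mean, unit (population) standard deviation."""

    spot_id: str
    channel: str
    zvalues: np.ndarray


def extract_trace(
    stack: np.ndarray,
    spot,
    roi_radius: int = 2,
    spot_id: str | None = None,
) -> Trace:
    """Sum pixel counts in a square ROI around a spot, frame by frame.

    ``spot`` is anything with ``x``/``y`` attributes (or an ``(x, y)``
    tuple); the ROI is a ``(2*roi_radius+1)^2`` window centered on the
    rounded spot position and must lie fully inside the image.
    """
    x = getattr(spot, "x", None)
    y = getattr(spot, "y", None)
    if x is None:
        x, y = spot
    channel = getattr(spot, "channel", "unknown")
    frames, h, w = stack.shape
    cx, cy = int(round(float(x))), int(round(float(y)))
    r = int(roi_radius)
    if cx - r < 0 or cy - r < 0 or cx + r >= w or cy + r >= h:
        raise ValueError(f"ROI of radius {r} at ({x:.1f}, {y:.1f}) extends outside image")
    values = stack[:, cy - r : cy + r + 1, cx - r : cx + r + 1].sum(axis=(1, 2))
    return Trace(spot_id or f"x{cx}y{cy}", channel, np.asarray(values, dtype=float))


def zscore_values(values: np.ndarray) -> np.ndarray:
    """(x - mean) / sd with population standard deviation (ddof=0)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DegenerateTraceError("need at least 2 frames to Z-score")
    sd = values.std()
    if sd == 0:
        raise DegenerateTraceError("zero-variance trace cannot be Z-scored")
    return (values - values.mean()) / sd


def zscore(trace: Trace) -> NormalizedTrace:
    """Z-score normalize a trace (zero mean, unit population sd)."""
    return NormalizedTrace(trace.spot_id, trace.channel, zscore_values(trace.values))


def survival_from_bleach_times(
    bleach_times: np.ndarray, frames: int, frame_interval: float
) -> np.ndarray:
    """Per-frame count of fluorophores that have not yet bleached."""
    t = np.arange(frames) * frame_interval
    times = np.asarray(bleach_times, dtype=float)
    return (times[None, :] > t[:, None]).sum(axis=1).astype(float)


def bleach_half_time(data: np.ndarray, frame_interval: float = 0.05) -> float:
    """Photobleaching half-time ln2/lambda from exponential decay.

    ``data`` is either a 1-D per-frame survival count N(t) (fit
    ``N0*exp(-lambda t)`` by least squares on log counts, zero-count frames
    excluded) or a 2-D ensemble of traces (rows = traces; the ensemble mean
    is fit to ``A*exp(-lambda t) + c``).  Raises
    :class:`NoBleachingError` when the fitted rate is not positive.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        mean = data.mean(axis=0)
        t = np.arange(mean.size) * frame_interval
        a0 = mean[0] - mean[-1]
        c0 = mean[-1]
        lam0 = 1.0 / (t[-1] / 3.0 + 1e-12)
        model = lambda t, a, lam, c: a * np.exp(-lam * t) + c  # noqa: E731
        try:
            popt, _ = optimize.curve_fit(
                model, t, mean, p0=(max(a0, 1e-6), lam0, c0), maxfev=10000
            )
            # second, variance-weighted pass: the dominant error is binomial
            # noise of the surviving fraction S(t), with variance ~ S(1-S)
            s = np.clip(np.exp(-popt[1] * t), 1e-6, 1 - 1e-6)
            # additive floor keeps camera noise from letting the fully
            # bleached tail dominate the fit
            sigma = np.sqrt(s * (1.0 - s) + 0.01)
            popt, _ = optimize.curve_fit(
                model, t, mean, p0=popt, sigma=sigma, maxfev=10000
            )
        except RuntimeError as exc:  # pragma: no cover - pathological fits
            raise NoBleachingError(f"exponential fit failed: {exc}") from exc
        lam = popt[1]
        if not np.isfinite(lam) or lam <= 0:
            raise NoBleachingError("fitted bleach rate is not positive")
        return float(np.log(2.0) / lam)

    if data.size < 10:
        raise ValueError("need at least 10 frames of survival counts")
    t = np.arange(data.size) * frame_interval
    keep = data > 0
    if keep.sum() < 2:
        raise NoBleachingError("survival counts contain fewer than 2 positive frames")
    slope, _, _, _, _ = stats.linregress(t[keep], np.log(data[keep]))
    lam = -slope
    if lam <= 0:
        raise NoBleachingError("survival curve does not decay")
    return float(np.log(2.0) / lam)
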