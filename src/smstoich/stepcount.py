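"""Deterministic photobleaching step-counting rubric.

Operationalizes manual trace annotation: a photobleaching step is a stepwise,
sustained decrease in raw fluorescence larger than a fixed count threshold;
counting stops early when the trace *increases* by a step; a trace is
rejected when no steps are counted or when within-plateau variability is too
high for steps to be visually discrete.  Serves both as the ground-truth
labeler for synthetic training data and as the independent oracle the
trained classifiers are validated against.

Thresholds operate on raw camera counts.  Passing a Z-scored trace is a
contract violation and is guarded against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StepAnnotation",
    "TraceClass",
    "FARRED_CLASSES",
    "GREEN_CLASSES",
    "segment_plateaus",
    "count_steps_reference",
    "bin_class",
    "annotate_trace",
    "ground_truth_class",
    "has_coincident_bleaches",
]

FARRED_CLASSES = ("rejected", "1-step", "2-step", "3plus")
GREEN_CLASSES = ("rejected", "1-step")

#: Minimum sustained decrease, in camera counts, to count as one step.
DEFAULT_STEP_THRESHOLD = 25.0
#: Minimum plateau length in frames for a step to count as "sustained"
#: (0.25 s at 20 frames/s).
DEFAULT_MIN_PLATEAU = 5


@dataclass
class StepAnnotation:
    n_steps: int
    stopped_early: bool = False
    rejected: bool = False
    reject_reason: str | None = None  # no-steps | high-variability | multi-event-green

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")


@dataclass(frozen=True)
class TraceClass:
    channel: str
    label: str

    def __post_init__(self) -> None:
        allowed = FARRED_CLASSES if self.channel == "farred" else GREEN_CLASSES
        if self.label not in allowed:
            raise ValueError(f"label {self.label!r} not valid for channel {self.channel!r}")


def _robust_noise_sd(values: np.ndarray) -> float:
    # sd of first differences is sqrt(2)*sigma for iid Gaussian noise;
    # the median of |diff| is robust to the sparse step edges.
    d = np.abs(np.diff(values))
    med = np.median(d)
    return float(med / 0.95387)  # median(|N(0, 2 sigma^2)|) = 0.95387 sigma


def _best_split(x: np.ndarray, min_len: int) -> tuple[int, float]:
    """Best single mean-shift changepoint of ``x`` by SSE reduction.

    Returns (index, |mean_left - mean_right|); index is the first frame of
    the right plateau.  Index -1 when no admissible split exists.
    """
    n = len(x)
    if n < 2 * min_len:
        return -1, 0.0
    cs = np.cumsum(x)
    total = cs[-1]
    k = np.arange(min_len, n - min_len + 1)  # split points
    left_mean = cs[k - 1] / k
    right_mean = (total - cs[k - 1]) / (n - k)
    gain = k * (n - k) / n * (left_mean - right_mean) ** 2
    best = int(np.argmax(gain))
    return int(k[best]), float(abs(left_mean[best] - right_mean[best]))


def segment_plateaus(
    values: np.ndarray,
    min_plateau_frames: int = DEFAULT_MIN_PLATEAU,
    min_amplitude: float = 0.0,
    noise_scale: float = 4.0,
) -> list[int]:
    """Changepoints of a piecewise-constant trace by recursive binary segmentation.

    A candidate changepoint (the SSE-optimal single split of a segment) is
    accepted when both resulting plateaus have >= ``min_plateau_frames``
    frames and the plateau mean difference exceeds
    ``max(min_amplitude, noise_scale * sigma_hat)``, where ``sigma_hat`` is a
    robust per-frame noise estimate from the first differences of the whole
    trace.  Returns sorted changepoint indices (first frame of each new
    plateau).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2 * min_plateau_frames:
        raise ValueError("trace shorter than two minimum plateaus")
    sigma = _robust_noise_sd(values)
    threshold = max(min_amplitude, noise_scale * sigma, 1e-9)

    changepoints: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        k, amp = _best_split(values[lo:hi], min_plateau_frames)
        if k < 0 or amp <= threshold:
            return
        changepoints.append(lo + k)
        recurse(lo, lo + k)
        recurse(lo + k, hi)

    recurse(0, len(values))
    return sorted(changepoints)


def _looks_zscored(values: np.ndarray) -> bool:
    return abs(float(values.mean())) < 1e-6 and abs(float(values.std()) - 1.0) < 1e-6


def count_steps_reference(
    values: np.ndarray,
    step_threshold: float = DEFAULT_STEP_THRESHOLD,
    min_plateau_frames: int = DEFAULT_MIN_PLATEAU,
) -> StepAnnotation:
    """Count photobleaching steps in one raw trace.

    Plateaus are walked in time order; each mean decrease greater than
    ``step_threshold`` counts as one step.  On the first mean *increase*
    greater than the threshold, counting stops early.  The trace is rejected
    when the pooled within-plateau standard deviation exceeds
    ``step_threshold / 2`` (steps not visually discrete) or when no steps
    were counted.
    """
    values = np.asarray(values, dtype=float)
    if _looks_zscored(values):
        raise ValueError(
            "trace appears Z-scored (mean 0, sd 1); step counting operates on raw counts"
        )
    cps = segment_plateaus(values, min_plateau_frames=min_plateau_frames)
    bounds = [0, *cps, len(values)]
    segments = [values[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
    means = [s.mean() for s in segments]

    n_steps = 0
    stopped_early = False
    for prev, nxt in zip(means[:-1], means[1:]):
        delta = nxt - prev
        if delta < -step_threshold:
            n_steps += 1
        elif delta > step_threshold:
            stopped_early = True
            break

    # pooled within-plateau sd, weighted by degrees of freedom
    ss = sum(float(((s - s.mean()) ** 2).sum()) for s in segments)
    dof = sum(len(s) - 1 for s in segments)
    pooled_sd = (ss / dof) ** 0.5 if dof > 0 else 0.0

    if pooled_sd > step_threshold / 2.0:
        return StepAnnotation(n_steps, stopped_early, rejected=True, reject_reason="high-variability")
    if n_steps == 0:
        return StepAnnotation(0, stopped_early, rejected=True, reject_reason="no-steps")
    return StepAnnotation(n_steps, stopped_early)


def bin_class(channel: str, annotation: StepAnnotation) -> TraceClass:
    """Bin a step annotation into the channel's class set.

    Far-red: rejected / 1-step / 2-step / 3plus (three and more steps share
    one class).  Green: exactly one photobleaching event -> 1-step, anything
    else (zero, or more than one event) -> rejected.
    """
    if channel == "farred":
        if annotation.rejected or annotation.n_steps == 0:
            return TraceClass(channel, "rejected")
        if annotation.n_steps == 1:
            return TraceClass(channel, "1-step")
        if annotation.n_steps == 2:
            return TraceClass(channel, "2-step")
        return TraceClass(channel, "3plus")
    if channel == "green":
        if not annotation.rejected and annotation.n_steps == 1:
            return TraceClass(channel, "1-step")
        return TraceClass(channel, "rejected")
    raise ValueError(f"unknown channel: {channel!r}")


def annotate_trace(
    values: np.ndarray,
    channel: str,
    step_threshold: float = DEFAULT_STEP_THRESHOLD,
    min_plateau_frames: int = DEFAULT_MIN_PLATEAU,
) -> tuple[StepAnnotation, TraceClass]:
    """Count steps and bin into a class; fills green multi-event reject reason."""
    ann = count_steps_reference(values, step_threshold, min_plateau_frames)
    cls = bin_class(channel, ann)
    if channel == "green" and not ann.rejected and ann.n_steps > 1:
        ann.rejected = True
        ann.reject_reason = "multi-event-green"
    return ann, cls


# ---------------------------------------------------------------------------
# generative ground truth helpers (for validating the oracle itself)


def ground_truth_class(
    bleach_times: np.ndarray, total_time: float, channel: str
) -> TraceClass:
    """Idealized class implied by the generative bleach times.

    Only bleach events inside the imaging window produce observable steps; a
    fluorophore surviving past ``total_time`` contributes none.
    """
    n = int(np.sum(np.asarray(bleach_times) < total_time))
    ann = StepAnnotation(n, rejected=(n == 0), reject_reason="no-steps" if n == 0 else None)
    return bin_class(channel, ann)


def has_coincident_bleaches(
    bleach_times: np.ndarray,
    total_time: float,
    frame_interval: float,
    min_plateau_frames: int = DEFAULT_MIN_PLATEAU,
) -> bool:
    """True when two bleach events (or an event and a window edge) fall within
    one minimum plateau of each other, making separate steps unresolvable."""
    window = min_plateau_frames * frame_interval
    times = np.sort(np.asarray(bleach_times, dtype=float))
    times = times[times < total_time]
    if len(times) == 0:
        return False
    if np.any(np.diff(times) < window):
        return True
    return bool(times[0] < window or times[-1] > total_time - window)
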