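"""Synthetic photobleaching traces, two-channel spot fields, and labeled datasets.

Generative model: each immobilized complex carries one green-tagged bait and
0..K far-red-tagged subunits.  Incomplete dye labeling is independent
Bernoulli thinning per fluorophore.  Each labeled fluorophore photobleaches
at an exponentially distributed time with a channel-specific half-time, so a
spot's intensity is a descending staircase: baseline + step_height * (number
of surviving fluorophores) + additive Gaussian camera noise.  Blinking and
partial-frame bleaching are not modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig

__all__ = [
    "GroundTruthComplex",
    "Trace",
    "draw_labeled_copies",
    "simulate_trace",
    "simulate_experiment",
    "simulate_classified_pairs",
    "render_field",
    "make_labeled_dataset",
]

CHANNELS = ("green", "farred")


@dataclass
class Trace:
    """One spot's per-frame fluorescence in one channel, in camera counts."""

    spot_id: str
    channel: str
    values: np.ndarray
    bio_rep: int = 0
    tech_rep: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")


@dataclass
class GroundTruthComplex:
    """Simulated complex with its true and labeled fluorophore content."""

    spot_id: str
    true_farred_copies: int
    labeled_farred_copies: int
    green_labeled: bool
    farred_bleach_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    green_bleach_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    position: tuple[float, float] | None = None
    bio_rep: int = 0
    tech_rep: int = 0

    def __post_init__(self) -> None:
        if self.labeled_farred_copies > self.true_farred_copies:
            raise ValueError("labeled copies cannot exceed true copies")
        for times in (self.farred_bleach_times, self.green_bleach_times):
            if np.any(np.asarray(times) < 0):
                raise ValueError("bleach times must be >= 0")


def draw_labeled_copies(n_true: int, p_label: float, rng: np.random.Generator) -> int:
    """Number of fluorescently labeled copies among ``n_true`` subunits.

    Each subunit independently carries a functional dye with probability
    ``p_label`` (binomial thinning).
    """
    if not (0.0 <= p_label <= 1.0):
        raise ValueError("p_label must lie in [0, 1]")
    if n_true < 0:
        raise ValueError("n_true must be >= 0")
    return int(rng.binomial(n_true, p_label))


def _draw_bleach_times(n: int, half_time: float, rng: np.random.Generator) -> np.ndarray:
    rate = math.log(2.0) / half_time
    return np.sort(rng.exponential(1.0 / rate, size=n))


def simulate_trace(
    n_labeled: int,
    channel: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    spot_id: str = "spot",
    bio_rep: int = 0,
    tech_rep: int = 0,
    bleach_times: np.ndarray | None = None,
) -> tuple[Trace, np.ndarray]:
    """Simulate one photobleaching trace with ``n_labeled`` fluorophores.

    Bleach times are exponential with the channel's half-time; the intensity
    at frame f counts the fluorophores still fluorescent at time f*dt.
    Returns the trace and the ascending bleach times (seconds).
    """
    if n_labeled < 0:
        raise ValueError("n_labeled must be >= 0")
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel: {channel!r}")
    if bleach_times is None:
        bleach_times = _draw_bleach_times(n_labeled, config.half_time(channel), rng)
    else:
        bleach_times = np.sort(np.asarray(bleach_times, dtype=float))
    t = np.arange(config.frames) * config.frame_interval
    surviving = (bleach_times[None, :] > t[:, None]).sum(axis=1) if n_labeled else np.zeros(config.frames)
    values = config.baseline + config.step_height * surviving
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=config.frames)
    trace = Trace(spot_id, channel, values, bio_rep, tech_rep)
    return trace, bleach_times


def _draw_positions(n: int, shape: tuple[int, int], margin: float, rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    xy = np.empty((n, 2))
    xy[:, 0] = rng.uniform(margin, w - 1 - margin, size=n)
    xy[:, 1] = rng.uniform(margin, h - 1 - margin, size=n)
    return xy


def simulate_complexes(
    config: SimulationConfig, rng: np.random.Generator
) -> list[GroundTruthComplex]:
    """Draw the ground-truth composition of every complex in the experiment."""
    copies = np.array(sorted(config.copy_number_dist), dtype=int)
    probs = np.array([config.copy_number_dist[int(k)] for k in copies], dtype=float)
    probs = probs / probs.sum()
    margin = 4.0 * config.psf_sd + max(
        abs(config.registration_shift[0]), abs(config.registration_shift[1])
    )
    out: list[GroundTruthComplex] = []
    for b in range(config.n_bio):
        for tr in range(config.n_tech):
            n = config.spots_per_field
            true_copies = rng.choice(copies, size=n, p=probs)
            positions = (
                _draw_positions(n, config.image_shape, margin, rng)
                if config.image_shape is not None
                else None
            )
            for s in range(n):
                n_true = int(true_copies[s])
                n_lab = draw_labeled_copies(n_true, config.labeling_prob, rng)
                green_lab = bool(rng.random() < config.green_labeling_prob)
                out.append(
                    GroundTruthComplex(
                        spot_id=f"b{b}t{tr}s{s}",
                        true_farred_copies=n_true,
                        labeled_farred_copies=n_lab,
                        green_labeled=green_lab,
                        farred_bleach_times=_draw_bleach_times(
                            n_lab, config.farred_half_time, rng
                        ),
                        green_bleach_times=_draw_bleach_times(
                            int(green_lab), config.green_half_time, rng
                        ),
                        position=tuple(positions[s]) if positions is not None else None,
                        bio_rep=b,
                        tech_rep=tr,
                    )
                )
    return out


def truth_table(complexes: list[GroundTruthComplex]) -> pd.DataFrame:
    """Ground-truth manifest as a DataFrame (bleach times ';'-joined seconds)."""
    rows = []
    for c in complexes:
        rows.append(
            {
                "spot_id": c.spot_id,
                "bio_rep": c.bio_rep,
                "tech_rep": c.tech_rep,
                "true_farred_copies": c.true_farred_copies,
                "labeled_farred_copies": c.labeled_farred_copies,
                "green_labeled": c.green_labeled,
                "farred_bleach_times": ";".join(f"{t:.6f}" for t in c.farred_bleach_times),
                "green_bleach_times": ";".join(f"{t:.6f}" for t in c.green_bleach_times),
                "x": np.nan if c.position is None else c.position[0],
                "y": np.nan if c.position is None else c.position[1],
            }
        )
    return pd.DataFrame(rows)


def _traces_frame(meta: list[dict], values: list[np.ndarray], frames: int) -> pd.DataFrame:
    value_cols = [f"frame_{i}" for i in range(frames)]
    df = pd.DataFrame(meta)
    vals = pd.DataFrame(
        np.asarray(values, dtype=np.float32).reshape(len(values), frames), columns=value_cols
    )
    return pd.concat([df, vals], axis=1)


def simulate_experiment(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full replicate-structured experiment.

    Returns ``(traces, truth)``: a trace table with columns
    ``spot_id, channel, bio_rep, tech_rep, frame_0..frame_{L-1}`` and the
    ground-truth manifest.  Every complex yields one far-red trace (a
    noise-only trace when no far-red copy is labeled); a green trace is
    present only when the bait's tag is fluorescent.
    """
    complexes = simulate_complexes(config, rng)
    meta: list[dict] = []
    values: list[np.ndarray] = []
    for c in complexes:
        tr, _ = simulate_trace(
            c.labeled_farred_copies,
            "farred",
            config,
            rng,
            spot_id=c.spot_id,
            bio_rep=c.bio_rep,
            tech_rep=c.tech_rep,
            bleach_times=c.farred_bleach_times,
        )
        meta.append(
            {"spot_id": c.spot_id, "channel": "farred", "bio_rep": c.bio_rep, "tech_rep": c.tech_rep}
        )
        values.append(tr.values)
        if c.green_labeled:
            tg, _ = simulate_trace(
                1,
                "green",
                config,
                rng,
                spot_id=c.spot_id,
                bio_rep=c.bio_rep,
                tech_rep=c.tech_rep,
                bleach_times=c.green_bleach_times,
            )
            meta.append(
                {"spot_id": c.spot_id, "channel": "green", "bio_rep": c.bio_rep, "tech_rep": c.tech_rep}
            )
            values.append(tg.values)
    return _traces_frame(meta, values, config.frames), truth_table(complexes)


def simulate_classified_pairs(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Fast class-level simulation: classified spot pairs without traces.

    Draws the same generative model (copy number -> binomial thinning ->
    class binning; green fluorescent with ``green_labeling_prob``) but maps
    labeled copy counts directly to idealized classes, skipping trace
    synthesis and step counting.  Useful for statistical power studies of the
    replicate-level analysis.
    """
    copies = np.array(sorted(config.copy_number_dist), dtype=int)
    probs = np.array([config.copy_number_dist[int(k)] for k in copies], dtype=float)
    probs = probs / probs.sum()
    rows = []
    for b in range(config.n_bio):
        for tr in range(config.n_tech):
            n = config.spots_per_field
            true_copies = rng.choice(copies, size=n, p=probs)
            labeled = rng.binomial(true_copies, config.labeling_prob)
            green = rng.random(n) < config.green_labeling_prob
            far_class = np.select(
                [labeled == 0, labeled == 1, labeled == 2],
                ["rejected", "1-step", "2-step"],
                default="3plus",
            )
            for s in range(n):
                rows.append(
                    {
                        "spot_id": f"b{b}t{tr}s{s}",
                        "green_class": "1-step" if green[s] else "rejected",
                        "farred_class": far_class[s],
                        "bio_rep": b,
                        "tech_rep": tr,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rendering


def _render_spots(
    shape: tuple[int, int],
    positions: np.ndarray,
    amplitudes: np.ndarray,
    psf_sd: float,
) -> np.ndarray:
    """Render Gaussian spots into an image stack.

    ``amplitudes`` has shape (n_spots,) for a single image or
    (n_frames, n_spots) for a stack; each spot's PSF is normalized to unit
    sum so the rendered integrated intensity equals its amplitude.
    """
    h, w = shape
    single = amplitudes.ndim == 1
    amps = amplitudes[None, :] if single else amplitudes
    stack = np.zeros((amps.shape[0], h, w), dtype=np.float32)
    r = max(1, int(math.ceil(4.0 * psf_sd)))
    for j, (x, y) in enumerate(positions):
        cx, cy = int(round(x)), int(round(y))
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError(f"spot position ({x:.1f}, {y:.1f}) outside image")
        x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
        y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        psf = np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * psf_sd**2))
        psf /= psf.sum()
        stack[:, y0:y1, x0:x1] += amps[:, j, None, None] * psf[None, :, :]
    return stack[0] if single else stack


def render_field(
    complexes: list[GroundTruthComplex],
    config: SimulationConfig,
    rng: np.random.Generator,
    n_beads: int = 12,
    bead_amplitude: float | None = None,
) -> tuple[dict[str, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Render a two-channel image stack plus a bead registration image pair.

    Far-red spots (and far-red bead images) are offset by
    ``config.registration_shift``; per-frame spot amplitude is
    ``step_height * surviving fluorophores``.  Returns
    ``({"green": stack, "farred": stack}, (bead_green, bead_farred))``
    with stacks of shape ``(frames, H, W)``.
    """
    if config.image_shape is None:
        raise ValueError("config.image_shape must be set to render")
    h, w = config.image_shape
    dx, dy = config.registration_shift
    t = np.arange(config.frames) * config.frame_interval
    stacks: dict[str, np.ndarray] = {}
    for channel in CHANNELS:
        pos_list, amp_list = [], []
        for c in complexes:
            if c.position is None:
                raise ValueError("complexes need positions for rendering")
            times = c.green_bleach_times if channel == "green" else c.farred_bleach_times
            if len(times) == 0:
                continue
            surviving = (np.asarray(times)[None, :] > t[:, None]).sum(axis=1)
            amp_list.append(config.step_height * surviving)
            x, y = c.position
            pos_list.append((x + dx, y + dy) if channel == "farred" else (x, y))
        if pos_list:
            amps = np.stack(amp_list, axis=1).astype(np.float32)
            stack = _render_spots((h, w), np.asarray(pos_list), amps, config.psf_sd)
        else:
            stack = np.zeros((config.frames, h, w), dtype=np.float32)
        stack += config.baseline
        if config.noise_sd > 0:
            stack += rng.normal(0.0, config.noise_sd, size=stack.shape).astype(np.float32)
        stacks[channel] = stack

    if bead_amplitude is None:
        bead_amplitude = 40.0 * config.step_height
    margin = 4.0 * config.psf_sd + max(abs(dx), abs(dy))
    bead_xy = _draw_positions(n_beads, (h, w), margin, rng)
    amps = np.full(n_beads, bead_amplitude, dtype=np.float32)
    bead_green = _render_spots((h, w), bead_xy, amps, config.psf_sd) + config.baseline
    bead_far = _render_spots((h, w), bead_xy + np.array([dx, dy]), amps, config.psf_sd) + config.baseline
    if config.noise_sd > 0:
        bead_green = bead_green + rng.normal(0.0, config.noise_sd, size=bead_green.shape)
        bead_far = bead_far + rng.normal(0.0, config.noise_sd, size=bead_far.shape)
    return stacks, (bead_green.astype(np.float32), bead_far.astype(np.float32))


# ---------------------------------------------------------------------------
# labeled datasets


def make_labeled_dataset(
    config: SimulationConfig,
    rng: np.random.Generator,
    channel: str = "farred",
    n_traces: int | None = None,
):
    """Z-scored traces with step-rubric class labels for classifier training.

    Simulates complexes, synthesizes the requested channel's raw traces,
    labels each with the deterministic step-counting rubric, and Z-score
    normalizes.  ``n_traces`` overrides the replicate-structure total.
    Returns a :class:`~smstoich.cnn.LabeledDataset`.
    """
    from .cnn import LabeledDataset
    from .stepcount import count_steps_reference, bin_class
    from .traces import zscore_values

    if channel not in CHANNELS:
        raise ValueError(f"unknown channel: {channel!r}")
    complexes = simulate_complexes(config, rng)
    if n_traces is not None:
        complexes = complexes[:n_traces]
    X = np.empty((0, config.frames), dtype=np.float32)
    rows_X: list[np.ndarray] = []
    labels: list[str] = []
    meta: list[dict] = []
    for c in complexes:
        if channel == "green":
            n_lab = int(c.green_labeled)
            times = c.green_bleach_times
        else:
            n_lab = c.labeled_farred_copies
            times = c.farred_bleach_times
        tr, _ = simulate_trace(
            n_lab, channel, config, rng,
            spot_id=c.spot_id, bio_rep=c.bio_rep, tech_rep=c.tech_rep,
            bleach_times=times,
        )
        ann = count_steps_reference(tr.values)
        labels.append(bin_class(channel, ann).label)
        sd = tr.values.std()
        z = zscore_values(tr.values) if sd > 0 else np.zeros_like(tr.values)
        rows_X.append(z.astype(np.float32))
        meta.append({"spot_id": c.spot_id, "bio_rep": c.bio_rep, "tech_rep": c.tech_rep})
    X = np.asarray(rows_X, dtype=np.float32)
    return LabeledDataset.from_labels(X, labels, channel, pd.DataFrame(meta))
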