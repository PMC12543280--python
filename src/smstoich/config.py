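"""Simulation configuration for synthetic single-molecule pull-down experiments.

The defaults mirror a typical SiMPull acquisition: 1000 frames per channel at
20 frames/s (50 s total), a far-red photobleaching half-time of one fifth of
the imaging time and a green half-time of one tenth, and a ~40% dye-labeling
probability for the far-red (HaloTag-style) channel.  Intensities are in
arbitrary camera counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "SimulationConfig",
    "copy_mixture_for_multimeric_fraction",
    "DEFAULT_OBSERVED_MULTIMERIC",
]

#: Target post-thinning observed multimeric fraction used for the default
#: copy-number mixture (the wild-type measurement this pipeline quantifies).
DEFAULT_OBSERVED_MULTIMERIC = 0.39


def copy_mixture_for_multimeric_fraction(
    target: float,
    p_label: float,
    unit_copies: int = 1,
    multi_copies: int = 3,
) -> dict[int, float]:
    """Two-point copy-number mixture with a prescribed *observed* multimeric fraction.

    Solves for the weight ``a`` on ``unit_copies`` in the mixture
    ``{unit_copies: a, multi_copies: 1 - a}`` such that, after independent
    Bernoulli(p_label) thinning of each fluorophore, the fraction of
    complexes with >= 2 labeled copies among those with >= 1 labeled copy
    equals ``target``.

    Raises ``ValueError`` if the target is unreachable for the given pair of
    copy numbers and labeling probability.
    """
    if not (0 < p_label <= 1):
        raise ValueError("p_label must be in (0, 1]")

    def probs(n: int) -> tuple[float, float]:
        q = 1.0 - p_label
        p_ge1 = 1.0 - q**n
        p_ge2 = p_ge1 - n * p_label * q ** (n - 1)
        return p_ge1, p_ge2

    g1_u, g2_u = probs(unit_copies)
    g1_m, g2_m = probs(multi_copies)
    # target = (a*g2_u + (1-a)*g2_m) / (a*g1_u + (1-a)*g1_m) ; linear in a
    num = g2_m - target * g1_m
    den = (g2_m - g2_u) - target * (g1_m - g1_u)
    if den == 0:
        raise ValueError("degenerate mixture: copy numbers do not separate the target")
    a = num / den
    if not (0.0 <= a <= 1.0):
        raise ValueError(
            f"target multimeric fraction {target} unreachable with copies "
            f"({unit_copies}, {multi_copies}) at p_label={p_label}"
        )
    return {unit_copies: a, multi_copies: 1.0 - a}


def _default_copy_dist() -> dict[int, float]:
    return copy_mixture_for_multimeric_fraction(DEFAULT_OBSERVED_MULTIMERIC, 0.4)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic photobleaching experiment.

    Attributes
    ----------
    frames:
        Frames acquired per channel (>= 2).
    frame_interval:
        Seconds per frame (20 frames/s -> 0.05 s).
    step_height:
        Fluorescence increment of one fluorophore, in camera counts.
    baseline:
        Background offset of a trace, in counts.
    noise_sd:
        Per-frame additive Gaussian noise, in counts.
    farred_half_time, green_half_time:
        Photobleaching half-times in seconds.  ``None`` defaults to one fifth
        (far-red) and one tenth (green) of the total imaging time.
    labeling_prob:
        Probability that any one far-red fluorophore site carries a dye.
    green_labeling_prob:
        Probability the bait's green tag is fluorescent.  The green tag is a
        fluorescent protein rather than a dye, so this defaults to 1.
    copy_number_dist:
        Probability mass over the true far-red copy number per complex.
        The default is a {1, 3} mixture whose post-thinning observed
        multimeric fraction is 0.39 at labeling_prob 0.4.
    n_bio, n_tech:
        Biological replicates, and technical replicates nested in each.
    spots_per_field:
        Complexes per technical replicate (per field).
    image_shape, psf_sd, registration_shift:
        Optional rendering parameters: field size in pixels, Gaussian PSF
        standard deviation in pixels, and the green->far-red channel offset.
    seed:
        Seed recorded for provenance; generators are passed explicitly.
    """

    frames: int = 1000
    frame_interval: float = 0.05
    step_height: float = 50.0
    baseline: float = 100.0
    noise_sd: float = 10.0
    farred_half_time: float | None = None
    green_half_time: float | None = None
    labeling_prob: float = 0.4
    green_labeling_prob: float = 1.0
    copy_number_dist: Mapping[int, float] = field(default_factory=_default_copy_dist)
    n_bio: int = 10
    n_tech: int = 7
    spots_per_field: int = 200
    image_shape: tuple[int, int] | None = None
    psf_sd: float = 1.2
    registration_shift: tuple[float, float] = (0.0, 0.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        total_time = self.frames * self.frame_interval
        if self.farred_half_time is None:
            self.farred_half_time = total_time / 5.0
        if self.green_half_time is None:
            self.green_half_time = total_time / 10.0
        self.copy_number_dist = {int(k): float(v) for k, v in self.copy_number_dist.items()}
        self.validate()

    def validate(self) -> None:
        if self.frames < 2:
            raise ValueError("frames must be >= 2")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not (0.0 <= self.labeling_prob <= 1.0):
            raise ValueError("labeling_prob must lie in [0, 1]")
        if not (0.0 <= self.green_labeling_prob <= 1.0):
            raise ValueError("green_labeling_prob must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.step_height <= 0:
            raise ValueError("step_height must be positive")
        if self.farred_half_time <= 0 or self.green_half_time <= 0:
            raise ValueError("half-times must be positive")
        dist = self.copy_number_dist
        if any(k < 0 for k in dist):
            raise ValueError("copy numbers must be >= 0")
        if any(v < 0 for v in dist.values()):
            raise ValueError("copy_number_dist entries must be >= 0")
        if not math.isclose(sum(dist.values()), 1.0, abs_tol=1e-9):
            raise ValueError("copy_number_dist must sum to 1 (+/- 1e-9)")

    @property
    def total_time(self) -> float:
        """Total imaging time in seconds."""
        return self.frames * self.frame_interval

    def half_time(self, channel: str) -> float:
        if channel == "farred":
            return float(self.farred_half_time)
        if channel == "green":
            return float(self.green_half_time)
        raise ValueError(f"unknown channel: {channel!r}")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["copy_number_dist"] = {str(k): v for k, v in self.copy_number_dist.items()}
        if self.image_shape is not None:
            d["image_shape"] = list(self.image_shape)
        d["registration_shift"] = list(self.registration_shift)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "copy_number_dist" in d:
            d["copy_number_dist"] = {int(k): float(v) for k, v in d["copy_number_dist"].items()}
        if d.get("image_shape") is not None:
            d["image_shape"] = tuple(d["image_shape"])
        if "registration_shift" in d:
            d["registration_shift"] = tuple(d["registration_shift"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load from YAML or JSON (by extension; YAML parses JSON too)."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))
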