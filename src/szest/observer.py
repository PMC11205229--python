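"""Simulated psychophysical observers.

Seen/not-seen responses are drawn from a Gaussian psychometric function
whose slope (standard deviation) widens as sensitivity falls, with
false-positive and false-negative rates mixed in multiplicatively:
``P(seen) = fp + (1 - fp - fn) * Phi((threshold - stimulus) / sd)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .grid import VFPoint
from .structfunc import ThicknessMap

__all__ = [
    "ObserverParams",
    "EyeProfile",
    "RELIABLE",
    "UNRELIABLE",
    "OBSERVER_PRESETS",
    "henson_sd",
    "prob_seen",
    "respond",
]


@dataclass(frozen=True)
class ObserverParams:
    """False-response rates and the sensitivity-dependent slope model.

    The slope follows ``min(cap, exp(A * sensitivity + B))``; the default
    constants are the canonical values used by perimetric simulators and
    are overridable.
    """

    fp: float = 0.05
    fn: float = 0.05
    slope_A: float = -0.081  # per dB
    slope_B: float = 3.27
    slope_cap: float = 6.0  # dB

    def __post_init__(self) -> None:
        if self.fp < 0 or self.fn < 0:
            raise ValueError("false-response rates must be nonnegative")
        if self.fp + self.fn >= 1.0:
            raise ValueError("fp + fn must be < 1")
        if self.slope_cap <= 0:
            raise ValueError("slope_cap must be positive")


RELIABLE = ObserverParams(fp=0.05, fn=0.05)
UNRELIABLE = ObserverParams(fp=0.20, fn=0.20)
OBSERVER_PRESETS = {"reliable": RELIABLE, "unreliable": UNRELIABLE}


@dataclass(frozen=True)
class EyeProfile:
    """Ground truth for one simulated eye."""

    true_thresholds: np.ndarray  # dB, one per grid location
    gcl_map: ThicknessMap | None = None
    cohort: str = "healthy"  # {healthy, glaucoma}
    severity: str = "none"  # {none, early, moderate, advanced}
    fovea: VFPoint = VFPoint(0.0, 0.0)
    onh_center: VFPoint = VFPoint(15.0, 2.0)
    eye_id: str = ""
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.true_thresholds, dtype=float)
        if t.ndim != 1:
            raise ValueError("true_thresholds must be a 1-D vector")
        if t.min() < 0.0 or t.max() > 40.0:
            raise ValueError("true thresholds must lie in [0, 40] dB")
        if self.cohort not in ("healthy", "glaucoma"):
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.severity not in ("none", "early", "moderate", "advanced"):
            raise ValueError(f"unknown severity {self.severity!r}")
        if self.cohort == "healthy" and self.severity != "none":
            raise ValueError("healthy eyes must have severity 'none'")
        object.__setattr__(self, "true_thresholds", t)


def henson_sd(sensitivity, params: ObserverParams | None = None):
    """Psychometric slope (dB) at a given sensitivity, capped."""
    p = params or ObserverParams()
    s = np.asarray(sensitivity, dtype=float)
    sd = np.minimum(p.slope_cap, np.exp(p.slope_A * s + p.slope_B))
    return float(sd) if sd.ndim == 0 else sd


def prob_seen(true_t, stimulus, params: ObserverParams | None = None):
    """Probability of a 'seen' response; bounded in [fp, 1 - fn]."""
    p = params or ObserverParams()
    t = np.asarray(true_t, dtype=float)
    s = np.asarray(stimulus, dtype=float)
    core = ndtr((t - s) / henson_sd(t, p))
    out = p.fp + (1.0 - p.fp - p.fn) * core
    return float(out) if np.ndim(out) == 0 else out


def respond(true_t: float, stimulus: float, params: ObserverParams,
            rng: np.random.Generator) -> bool:
    """One Bernoulli draw from :func:`prob_seen`; reproducible per rng state."""
    return bool(rng.random() < prob_seen(true_t, stimulus, params))
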