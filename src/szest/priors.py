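"""Discrete prior/posterior distributions over candidate thresholds.

The belief state of the Bayesian strategy at one test location is a
probability mass function over a fixed, uniformly spaced dB domain
(default 0..40 in 1-dB steps).  Standard priors are a 4:1 mixture of a
normal and an abnormal Gaussian component; structural priors shift the
normal peak to the structure-function prediction and replace the mixing
weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiscretePdf",
    "PriorConfig",
    "default_domain",
    "make_component",
    "make_standard_prior",
    "make_structural_prior",
    "mixture_component_masses",
    "pdf_mean",
    "pdf_sd",
    "pdf_to_text",
    "pdf_from_text",
]

_NORM_TOL = 1e-6


def default_domain(step: float = 1.0) -> np.ndarray:
    """Candidate thresholds 0..40 dB inclusive, uniformly spaced."""
    return np.arange(0.0, 40.0 + step / 2.0, step)


@dataclass(frozen=True)
class DiscretePdf:
    """Probability mass over a fixed ascending, uniformly spaced dB domain."""

    domain: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.domain, dtype=float)
        m = np.asarray(self.mass, dtype=float)
        if d.shape != m.shape or d.ndim != 1:
            raise ValueError("domain and mass must be 1-D arrays of equal length")
        if d.size >= 2:
            steps = np.diff(d)
            if steps.min() <= 0 or np.ptp(steps) > 1e-9:
                raise ValueError("domain must be ascending and uniformly spaced")
        if m.min() < 0:
            raise ValueError("negative probability mass")
        object.__setattr__(self, "domain", d)
        object.__setattr__(self, "mass", m)

    def normalized(self) -> "DiscretePdf":
        s = self.mass.sum()
        if s <= 0:
            raise ValueError("cannot normalize an all-zero pdf")
        return DiscretePdf(self.domain, self.mass / s)


@dataclass(frozen=True)
class PriorConfig:
    """Shape of the normal/abnormal mixture prior.

    Component shapes are Gaussian bumps standing in for published
    normal/abnormal threshold histograms.  ``floor`` adds a small uniform
    mass fraction that guards against zero-mass lockout under repeated
    asymptotic likelihood updates.
    """

    normal_sd: float = 5.0
    abnormal_peak: float = 3.0
    abnormal_sd: float = 4.0
    abnormal_weight: float = 0.2
    floor: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 <= self.abnormal_weight <= 1.0:
            raise ValueError("abnormal_weight must lie in [0, 1]")
        if self.normal_sd <= 0 or self.abnormal_sd <= 0:
            raise ValueError("component standard deviations must be positive")
        if not 0.0 <= self.floor <= 0.05:
            raise ValueError("floor must lie in [0, 0.05]")


def make_component(peak: float, sd: float, domain: np.ndarray) -> DiscretePdf:
    """Discretized, renormalized Gaussian bump centred on ``peak``."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not np.isfinite(peak):
        raise ValueError("peak must be finite")
    d = np.asarray(domain, dtype=float)
    mass = np.exp(-0.5 * ((d - peak) / sd) ** 2)
    return DiscretePdf(d, mass / mass.sum())


def mixture_component_masses(
    normal_peak: float, abnormal_weight: float, cfg: PriorConfig, domain: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """The two weighted component mass vectors, before flooring.

    Returned vectors sum to ``1 - w`` and ``w`` respectively; their sum is
    the un-floored mixture.
    """
    normal = make_component(normal_peak, cfg.normal_sd, domain)
    abnormal = make_component(cfg.abnormal_peak, cfg.abnormal_sd, domain)
    return (1.0 - abnormal_weight) * normal.mass, abnormal_weight * abnormal.mass


def _floored(mix: np.ndarray, floor: float, domain: np.ndarray) -> DiscretePdf:
    mass = (1.0 - floor) * mix + floor / mix.size
    return DiscretePdf(domain, mass / mass.sum())


def make_standard_prior(
    normative: float, cfg: PriorConfig | None = None, domain: np.ndarray | None = None
) -> DiscretePdf:
    """Population prior: normal component peaked at the normative value,
    mixed 4:1 (by default) with a low-sensitivity abnormal component."""
    cfg = cfg or PriorConfig()
    d = default_domain() if domain is None else np.asarray(domain, dtype=float)
    if not d.min() <= normative <= d.max():
        raise ValueError(f"normative value {normative} outside domain")
    nm, am = mixture_component_masses(normative, cfg.abnormal_weight, cfg, d)
    return _floored(nm + am, cfg.floor, d)


def make_structural_prior(
    predicted: float,
    abnormal_weight: float,
    cfg: PriorConfig | None = None,
    domain: np.ndarray | None = None,
) -> DiscretePdf:
    """Individualized prior: normal peak at the structure-function
    prediction, abnormal weight set from the predicted deficit."""
    cfg = cfg or PriorConfig()
    d = default_domain() if domain is None else np.asarray(domain, dtype=float)
    if not d.min() <= predicted <= d.max():
        raise ValueError(f"predicted value {predicted} outside domain")
    if not 0.0 <= abnormal_weight <= 1.0:
        raise ValueError("abnormal_weight must lie in [0, 1]")
    nm, am = mixture_component_masses(predicted, abnormal_weight, cfg, d)
    return _floored(nm + am, cfg.floor, d)


def _check_normalized(p: DiscretePdf) -> None:
    if abs(p.mass.sum() - 1.0) > _NORM_TOL:
        raise ValueError("pdf is not normalized")


def pdf_mean(p: DiscretePdf) -> float:
    _check_normalized(p)
    return float(p.mass @ p.domain)


def pdf_sd(p: DiscretePdf) -> float:
    _check_normalized(p)
    m = p.mass @ p.domain
    var = p.mass @ (p.domain - m) ** 2
    return float(np.sqrt(max(var, 0.0)))


def pdf_to_text(p: DiscretePdf, path) -> None:
    np.savetxt(path, np.column_stack([p.domain, p.mass]),
               fmt="%.6f\t%.12e", header="domain_db\tmass")


def pdf_from_text(path) -> DiscretePdf:
    data = np.loadtxt(path)
    return DiscretePdf(data[:, 0], data[:, 1])
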