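"""The adaptive Bayesian testing loop (ZEST / S-ZEST).

Each location holds a discrete belief over its threshold.  The next
stimulus is the posterior mean; responses update the belief through a
Gaussian-cdf likelihood with asymptotes at 0.03 / 0.97; a location
terminates when the posterior standard deviation drops to 1.5 dB or its
presentation count hits the safety cap.  Optional spatial enhancement
propagates a flattened likelihood to connected, unterminated neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .grid import NeighborGraph, TestGrid
from .observer import EyeProfile, ObserverParams, prob_seen
from .priors import DiscretePdf, pdf_mean, pdf_sd

__all__ = [
    "StrategyConfig",
    "LocationState",
    "TestResult",
    "likelihood_seen",
    "update_pdf",
    "spatial_update",
    "select_stimulus",
    "is_terminated",
    "run_test",
    "result_to_text",
]


@dataclass(frozen=True)
class StrategyConfig:
    """Strategy knobs; defaults match the standard procedure."""

    mode: str = "standard"  # {standard, structural}
    spatial: bool = False
    likelihood_sd: float = 1.0  # dB
    asymptote_lo: float = 0.03
    asymptote_hi: float = 0.97
    term_sd: float = 1.5  # dB
    max_presentations_per_location: int = 15
    stimulus_rounding: float = 1.0  # dB; 0 disables rounding
    presentation_time_s: float = 1.6  # reporting only

    def __post_init__(self) -> None:
        if not 0.0 < self.asymptote_lo < self.asymptote_hi < 1.0:
            raise ValueError("need 0 < asymptote_lo < asymptote_hi < 1")
        if self.likelihood_sd <= 0 or self.term_sd <= 0:
            raise ValueError("likelihood_sd and term_sd must be positive")
        if self.mode not in ("standard", "structural"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.max_presentations_per_location < 1:
            raise ValueError("presentation cap must be >= 1")


@dataclass
class LocationState:
    pdf: DiscretePdf
    presentations: list[tuple[float, bool]] = field(default_factory=list)
    terminated: bool = False
    capped: bool = False


@dataclass(frozen=True)
class TestResult:
    """Outcome of one simulated examination."""

    __test__ = False  # not a pytest collection target

    estimates: np.ndarray  # posterior means, dB
    posterior_sd: np.ndarray  # final posterior SDs, dB
    n_per_location: np.ndarray  # presentation counts
    capped: np.ndarray  # bool: terminated by the cap, not the criterion
    trace: tuple  # (step, location, intensity, response)
    seed: object
    duration_model_s: float

    @property
    def n_presentations(self) -> int:
        return int(self.n_per_location.sum())


def likelihood_seen(presented: float, domain: np.ndarray,
                    cfg: StrategyConfig | None = None) -> np.ndarray:
    """P(seen | candidate threshold) for one presented intensity.

    Gaussian cdf in the candidate threshold, centred on the presented
    intensity, squeezed between the two asymptotes; strictly increasing.
    """
    cfg = cfg or StrategyConfig()
    if not np.isfinite(presented):
        raise ValueError("presented intensity must be finite")
    d = np.asarray(domain, dtype=float)
    lo, hi = cfg.asymptote_lo, cfg.asymptote_hi
    return lo + (hi - lo) * ndtr((d - presented) / cfg.likelihood_sd)


def update_pdf(pdf: DiscretePdf, presented: float, response: bool,
               cfg: StrategyConfig | None = None) -> DiscretePdf:
    """Bayes update: posterior mass proportional to prior x likelihood."""
    cfg = cfg or StrategyConfig()
    like = likelihood_seen(presented, pdf.domain, cfg)
    if not response:
        like = 1.0 - like
    post = pdf.mass * like
    s = post.sum()
    if s <= 0:
        raise ValueError("posterior has zero total mass")
    return DiscretePdf(pdf.domain, post / s)


def spatial_update(
    states: list[LocationState],
    graph: NeighborGraph,
    tested_index: int,
    presented: float,
    response: bool,
    cfg: StrategyConfig | None = None,
) -> list[LocationState]:
    """Full update at the tested location; flattened update at neighbours.

    A neighbour connected with weight ``w`` receives the convex flattening
    ``L_w = (1 - w) + w * L`` of the response-appropriate likelihood.
    Terminated neighbours are left untouched (termination stays monotone).
    """
    cfg = cfg or StrategyConfig()
    states[tested_index].pdf = update_pdf(states[tested_index].pdf, presented, response, cfg)
    w = graph.weight
    for j in graph.neighbors(tested_index):
        st = states[j]
        if st.terminated:
            continue
        like = likelihood_seen(presented, st.pdf.domain, cfg)
        if not response:
            like = 1.0 - like
        flattened = (1.0 - w) + w * like
        post = st.pdf.mass * flattened
        st.pdf = DiscretePdf(st.pdf.domain, post / post.sum())
    return states


def select_stimulus(pdf: DiscretePdf, cfg: StrategyConfig | None = None) -> float:
    """Posterior mean, rounded (half-even) to the device step, clipped to [0, 40]."""
    cfg = cfg or StrategyConfig()
    m = pdf_mean(pdf)
    if cfg.stimulus_rounding > 0:
        r = cfg.stimulus_rounding
        m = float(np.round(m / r) * r)
    return float(np.clip(m, pdf.domain.min(), pdf.domain.max()))


def is_terminated(pdf: DiscretePdf, cfg: StrategyConfig | None = None) -> bool:
    """True once the posterior SD is at or below the termination bound."""
    cfg = cfg or StrategyConfig()
    return pdf_sd(pdf) <= cfg.term_sd


def run_test(
    eye: EyeProfile,
    grid: TestGrid,
    graph: NeighborGraph | None,
    priors: list[DiscretePdf],
    observer: ObserverParams,
    cfg: StrategyConfig | None = None,
    seed: object = 0,
) -> TestResult:
    """Run one full simulated examination.

    The next location is drawn uniformly at random among unterminated
    locations; everything is driven by ``numpy.random.default_rng(seed)``,
    so identical seeds give bit-identical results.
    """
    cfg = cfg or StrategyConfig()
    n = len(priors)
    if eye.true_thresholds.shape[0] != n:
        raise ValueError("eye thresholds and priors disagree in length")
    if cfg.spatial and graph is None:
        raise ValueError("spatial enhancement requires a neighbour graph")
    domain = priors[0].domain
    for p in priors:
        if p.domain.shape != domain.shape or not np.allclose(p.domain, domain):
            raise ValueError("all priors must share one domain")

    rng = np.random.default_rng(seed)
    states = [LocationState(pdf=p.normalized()) for p in priors]

    # Stimuli are quantized to cfg.stimulus_rounding, so the likelihood and
    # the observer's seen-probability can be tabulated once per test.
    use_lut = cfg.stimulus_rounding > 0
    if use_lut:
        r = cfg.stimulus_rounding
        levels = np.round(np.arange(domain.min(), domain.max() + r / 2, r) / r) * r
        lut_seen = np.stack([likelihood_seen(s, domain, cfg) for s in levels])
        lut_notseen = 1.0 - lut_seen
        w = graph.weight if graph is not None else 0.0
        lutw_seen = (1.0 - w) + w * lut_seen
        lutw_notseen = (1.0 - w) + w * lut_notseen
        p_seen = np.stack(
            [prob_seen(eye.true_thresholds, s, observer) for s in levels]
        ).T  # (n, n_levels)
        lvl_of = {round(float(s), 9): k for k, s in enumerate(levels)}

    mass = [st.pdf.mass.copy() for st in states]
    domain2 = domain**2
    active = list(range(n))
    trace: list[tuple[int, int, float, bool]] = []
    step = 0

    def _sd(m: np.ndarray) -> float:
        mu = m @ domain
        return float(np.sqrt(max(m @ domain2 - mu * mu, 0.0)))

    # locations already sharp enough under their prior terminate immediately
    for i in range(n - 1, -1, -1):
        if _sd(mass[i]) <= cfg.term_sd:
            states[i].terminated = True
            active.remove(i)

    while active:
        idx = active[int(rng.integers(len(active)))]
        m = mass[idx]
        stim = float(np.clip(m @ domain, domain.min(), domain.max()))
        if use_lut:
            stim = float(np.round(stim / cfg.stimulus_rounding) * cfg.stimulus_rounding)
            k = lvl_of[round(stim, 9)]
            response = bool(rng.random() < p_seen[idx, k])
            like = lut_seen[k] if response else lut_notseen[k]
        else:
            response = bool(rng.random() < prob_seen(eye.true_thresholds[idx], stim, observer))
            like = likelihood_seen(stim, domain, cfg)
            if not response:
                like = 1.0 - like
        trace.append((step, idx, stim, response))
        states[idx].presentations.append((stim, response))
        post = m * like
        mass[idx] = post / post.sum()

        if cfg.spatial and graph is not None:
            if use_lut:
                flat = lutw_seen[k] if response else lutw_notseen[k]
            else:
                flat = (1.0 - graph.weight) + graph.weight * like
            for j in graph.neighbors(idx):
                if states[j].terminated:
                    continue
                postj = mass[j] * flat
                mass[j] = postj / postj.sum()
                if _sd(mass[j]) <= cfg.term_sd:
                    states[j].terminated = True
                    active.remove(j)

        done = _sd(mass[idx]) <= cfg.term_sd
        if not done and len(states[idx].presentations) >= cfg.max_presentations_per_location:
            done = True
            states[idx].capped = True
        if done:
            states[idx].terminated = True
            active.remove(idx)
        step += 1

    for st, m in zip(states, mass):
        st.pdf = DiscretePdf(domain, m)

    estimates = np.array([pdf_mean(st.pdf) for st in states])
    post_sd = np.array([pdf_sd(st.pdf) for st in states])
    counts = np.array([len(st.presentations) for st in states], dtype=int)
    capped = np.array([st.capped for st in states], dtype=bool)
    return TestResult(
        estimates=estimates,
        posterior_sd=post_sd,
        n_per_location=counts,
        capped=capped,
        trace=tuple(trace),
        seed=seed,
        duration_model_s=float(counts.sum()) * cfg.presentation_time_s,
    )


def result_to_text(result: TestResult, path, trace_path=None) -> None:
    """Per-location summary table; optionally the full presentation trace."""
    with open(path, "w") as fh:
        fh.write("index\testimate_db\tposterior_sd_db\tn_presentations\tcapped\n")
        for i in range(len(result.estimates)):
            fh.write(
                f"{i}\t{result.estimates[i]:.4f}\t{result.posterior_sd[i]:.4f}"
                f"\t{result.n_per_location[i]}\t{int(result.capped[i])}\n"
            )
    if trace_path is not None:
        with open(trace_path, "w") as fh:
            fh.write("step\tlocation\tintensity_db\tseen\n")
            for step, loc, stim, resp in result.trace:
                fh.write(f"{step}\t{loc}\t{stim:.2f}\t{int(resp)}\n")
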