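"""Simulation harness and summary statistics.

Runs strategy x spatial x reliability x cohort experiments over a cohort of
eyes, summarizes accuracy (mean absolute error) and speed (presentation
counts) with 2.5%/97.5% quantiles, and provides Bland-Altman test-retest /
agreement analysis with subject-level bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import StrategyConfig, TestResult, run_test
from .grid import (
    NeighborGraph,
    TestGrid,
    build_10_2_grid,
    build_neighbor_graph,
    displace_locations,
    rotate_grid,
)
from .observer import OBSERVER_PRESETS, EyeProfile, ObserverParams
from .priors import DiscretePdf, PriorConfig, make_standard_prior, make_structural_prior
from .structfunc import (
    SFModelParams,
    predict_abnormal_weight,
    predict_sensitivity,
    sample_gcl,
)
from .synth import NormativeMap, make_normative_map

__all__ = [
    "ExperimentSpec",
    "BlandAltmanResult",
    "mae",
    "prepare_strategy",
    "run_experiment",
    "summarize",
    "summarize_quantiles",
    "bland_altman",
]

CONDITIONS_ALL = (("standard", False), ("standard", True),
                  ("structural", False), ("structural", True))


@dataclass(frozen=True)
class ExperimentSpec:
    """One simulation experiment over a cohort of eyes."""

    eyes: tuple[EyeProfile, ...]
    conditions: tuple[tuple[str, bool], ...] = CONDITIONS_ALL
    observers: tuple[str, ...] = ("reliable",)
    reps_per_eye: int = 500
    base_seed: int = 0
    prior_cfg: PriorConfig = field(default_factory=PriorConfig)
    sf_params: SFModelParams = field(default_factory=SFModelParams)
    normative: NormativeMap | None = None
    window_deg: float = 2.0

    def __post_init__(self) -> None:
        if self.reps_per_eye < 1:
            raise ValueError("reps_per_eye must be >= 1")
        if not self.conditions:
            raise ValueError("at least one condition is required")
        for mode, _ in self.conditions:
            if mode not in ("standard", "structural"):
                raise ValueError(f"unknown strategy mode {mode!r}")
        for obs in self.observers:
            if obs not in OBSERVER_PRESETS:
                raise ValueError(f"unknown observer preset {obs!r}")


def mae(result: TestResult | np.ndarray, truth: np.ndarray) -> float:
    """Mean absolute error (dB) between estimates and true thresholds."""
    est = result.estimates if isinstance(result, TestResult) else np.asarray(result, float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise ValueError("estimates and truth differ in length")
    return float(np.mean(np.abs(est - truth)))


def prepare_strategy(
    eye: EyeProfile,
    mode: str,
    spatial: bool,
    *,
    normative: NormativeMap | None = None,
    prior_cfg: PriorConfig | None = None,
    sf_params: SFModelParams | None = None,
    cfg: StrategyConfig | None = None,
    window_deg: float = 2.0,
    grid: TestGrid | None = None,
) -> tuple[TestGrid, NeighborGraph, list[DiscretePdf], StrategyConfig]:
    """Build the per-eye grid, neighbour graph, priors and config for one run.

    The grid is rotated along the eye's fovea-disc axis and ganglion-cell
    displaced.  Structural mode samples the GCL map at the displaced
    locations and shifts / reweights the priors accordingly.
    """
    prior_cfg = prior_cfg or PriorConfig()
    sf_params = sf_params or SFModelParams()
    if grid is None:
        grid = displace_locations(rotate_grid(build_10_2_grid(), eye.fovea, eye.onh_center))
    normative = normative or make_normative_map(grid)
    cfg = cfg or StrategyConfig()
    cfg = StrategyConfig(
        mode=mode, spatial=spatial, likelihood_sd=cfg.likelihood_sd,
        asymptote_lo=cfg.asymptote_lo, asymptote_hi=cfg.asymptote_hi,
        term_sd=cfg.term_sd,
        max_presentations_per_location=cfg.max_presentations_per_location,
        stimulus_rounding=cfg.stimulus_rounding,
        presentation_time_s=cfg.presentation_time_s,
    )
    if mode == "standard":
        priors = [make_standard_prior(v, prior_cfg) for v in normative.values]
        graph = build_neighbor_graph(grid, "standard")
    else:
        if eye.gcl_map is None:
            raise ValueError("structural mode requires a GCL thickness map")
        samples = sample_gcl(eye.gcl_map, grid, window_deg)
        predicted = np.array(
            [predict_sensitivity(s.mean_thickness, sf_params) for s in samples]
        )
        weights = predict_abnormal_weight(predicted, normative.values, sf_params)
        priors = [
            make_structural_prior(p, float(w), prior_cfg)
            for p, w in zip(predicted, weights)
        ]
        graph = build_neighbor_graph(grid, "structural", predictions=predicted)
    return grid, graph, priors, cfg


def run_experiment(spec: ExperimentSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every (eye, condition, observer, rep) cell; return raw rows and summary.

    Per-run seeds are derived deterministically from ``base_seed`` and the
    cell indices, so identical specs give identical tables.
    """
    rows = []
    for e_idx, eye in enumerate(spec.eyes):
        prepared = {
            (mode, spatial): prepare_strategy(
                eye, mode, spatial, normative=spec.normative,
                prior_cfg=spec.prior_cfg, sf_params=spec.sf_params,
                window_deg=spec.window_deg,
            )
            for (mode, spatial) in spec.conditions
        }
        for c_idx, cond in enumerate(spec.conditions):
            grid, graph, priors, cfg = prepared[cond]
            for o_idx, obs_name in enumerate(spec.observers):
                observer = OBSERVER_PRESETS[obs_name]
                for rep in range(spec.reps_per_eye):
                    seed = (spec.base_seed, e_idx, c_idx, o_idx, rep)
                    result = run_test(eye, grid, graph, priors, observer, cfg, seed=seed)
                    rows.append({
                        "eye_id": eye.eye_id or f"eye_{e_idx:03d}",
                        "cohort": eye.cohort,
                        "severity": eye.severity,
                        "strategy": "szest" if cond[0] == "structural" else "zest",
                        "spatial": cond[1],
                        "observer": obs_name,
                        "rep": rep,
                        "mae": mae(result, eye.true_thresholds),
                        "n_presentations": result.n_presentations,
                        "n_capped": int(result.capped.sum()),
                        "duration_model_s": result.duration_model_s,
                    })
    raw = pd.DataFrame(rows)
    return raw, summarize(raw)


def summarize(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean and 2.5%/97.5% quantiles of MAE and speed."""
    def _agg(g: pd.DataFrame) -> pd.Series:
        out = {}
        for col in ("mae", "n_presentations"):
            q_lo, q_hi = summarize_quantiles(g[col].to_numpy())
            out[f"{col}_mean"] = g[col].mean()
            out[f"{col}_q025"] = q_lo
            out[f"{col}_q975"] = q_hi
        out["n_runs"] = len(g)
        return pd.Series(out)

    keys = ["cohort", "strategy", "spatial", "observer"]
    return raw.groupby(keys, as_index=False).apply(_agg, include_groups=False)


def summarize_quantiles(values, probs=(0.025, 0.975)) -> np.ndarray:
    """Linear-interpolation (type-7) sample quantiles."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot take quantiles of an empty sample")
    return np.quantile(v, probs, method="linear")


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias, 95% limits and their bootstrap CIs for paired measurements."""

    bias: float
    lor_lo: float
    lor_hi: float
    ci_bias: tuple[float, float]
    ci_lo: tuple[float, float]
    ci_hi: tuple[float, float]
    bias_slope: float
    bias_intercept: float
    n_points: int
    n_subjects: int


def bland_altman(
    test1,
    test2,
    subject_ids=None,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    *,
    limit_multiplier: float = 1.96,
) -> BlandAltmanResult:
    """Point-wise Bland-Altman analysis with subjects as the bootstrap unit.

    ``d = test1 - test2``; bias = mean(d); limits = bias +/- 1.96 * sd(d)
    (sample sd, ddof 1).  The bias equation regresses d on the pairwise
    means.  Bootstrap (if ``n_boot > 0``) resamples subjects with
    replacement and reports percentile CIs for the bias and both limits.
    """
    t1 = np.asarray(test1, dtype=float).ravel()
    t2 = np.asarray(test2, dtype=float).ravel()
    if t1.shape != t2.shape:
        raise ValueError("test1 and test2 differ in length")
    if subject_ids is None:
        subject_ids = np.zeros(t1.shape, dtype=int)
    subj = np.asarray(subject_ids).ravel()
    if subj.shape != t1.shape:
        raise ValueError("subject_ids must match the measurement length")
    uniq = np.unique(subj)
    if n_boot > 0 and uniq.size < 2:
        raise ValueError("bootstrap needs at least 2 subjects")

    def _stats(d: np.ndarray) -> tuple[float, float, float]:
        bias = float(np.mean(d))
        sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
        return bias, bias - limit_multiplier * sd, bias + limit_multiplier * sd

    d = t1 - t2
    bias, lo, hi = _stats(d)
    means = (t1 + t2) / 2.0
    if np.ptp(means) < 1e-12:
        slope, intercept = 0.0, bias
    else:
        slope, intercept = (float(c) for c in np.polyfit(means, d, 1))

    if n_boot > 0:
        rng = rng if rng is not None else np.random.default_rng()
        groups = {s: np.nonzero(subj == s)[0] for s in uniq}
        boot = np.empty((n_boot, 3))
        for b in range(n_boot):
            pick = rng.choice(uniq, size=uniq.size, replace=True)
            idx = np.concatenate([groups[s] for s in pick])
            boot[b] = _stats(d[idx])
        ci = np.quantile(boot, [0.025, 0.975], axis=0)
        ci_bias = (float(ci[0, 0]), float(ci[1, 0]))
        ci_lo = (float(ci[0, 1]), float(ci[1, 1]))
        ci_hi = (float(ci[0, 2]), float(ci[1, 2]))
    else:
        ci_bias = (bias, bias)
        ci_lo = (lo, lo)
        ci_hi = (hi, hi)

    return BlandAltmanResult(
        bias=bias, lor_lo=lo, lor_hi=hi, ci_bias=ci_bias, ci_lo=ci_lo, ci_hi=ci_hi,
        bias_slope=slope, bias_intercept=intercept,
        n_points=int(t1.size), n_subjects=int(uniq.size),
    )
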