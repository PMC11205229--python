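import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr

from szest.engine import (
    LocationState,
    StrategyConfig,
    is_terminated,
    likelihood_seen,
    result_to_text,
    run_test,
    select_stimulus,
    spatial_update,
    update_pdf,
)
from szest.grid import NeighborGraph, build_10_2_grid, build_neighbor_graph
from szest.observer import RELIABLE, EyeProfile, ObserverParams
from szest.priors import DiscretePdf, default_domain, make_standard_prior, pdf_mean, pdf_sd


def _phi(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


DETERMINISTIC = ObserverParams(fp=0.0, fn=0.0, slope_A=0.0, slope_B=-20.0)


class TestLikelihood:
    def test_half_at_presented_intensity(self, domain):
        L = likelihood_seen(20.0, domain)
        assert L[domain == 20.0][0] == pytest.approx(0.03 + 0.94 * 0.5)

    def test_asymptotes(self, domain):
        L = likelihood_seen(20.0, domain)
        assert L[0] == pytest.approx(0.03, abs=1e-6)  # 20 SD below
        assert L[-1] == pytest.approx(0.97, abs=1e-6)

    def test_one_db_above(self, domain):
        L = likelihood_seen(20.0, domain)
        assert L[domain == 21.0][0] == pytest.approx(0.03 + 0.94 * _phi(1.0), rel=1e-9)
        assert L[domain == 21.0][0] == pytest.approx(0.8209, abs=1e-4)

    def test_strictly_increasing(self, domain):
        L = likelihood_seen(20.0, domain)
        assert (np.diff(L) >= 0).all()
        # strict away from double-precision cdf saturation (~ +/- 8 SD)
        central = np.abs(domain - 20.0) <= 8.0
        assert (np.diff(L[central]) > 0).all()

    def test_not_seen_is_complement(self, domain, strategy_cfg):
        p = DiscretePdf(domain, np.full(41, 1 / 41.0))
        seen = update_pdf(p, 20.0, True, strategy_cfg)
        notseen = update_pdf(p, 20.0, False, strategy_cfg)
        L = likelihood_seen(20.0, domain, strategy_cfg)
        np.testing.assert_allclose(seen.mass, L / L.sum(), rtol=1e-12)
        np.testing.assert_allclose(notseen.mass, (1 - L) / (1 - L).sum(), rtol=1e-12)


class TestUpdatePdf:
    def test_seen_shifts_mean_up(self, domain):
        p = DiscretePdf(domain, np.full(41, 1 / 41.0))
        assert pdf_mean(update_pdf(p, 20.0, True)) > 20.0
        assert pdf_mean(update_pdf(p, 20.0, False)) < 20.0

    def test_point_mass_prior_unchanged(self, domain):
        mass = np.zeros(41)
        mass[25] = 1.0
        p = DiscretePdf(domain, mass)
        post = update_pdf(p, 20.0, True)
        np.testing.assert_allclose(post.mass, mass)

    def test_three_bin_hand_oracle(self):
        # 3-bin pdf (0.2, 0.5, 0.3) at {10, 20, 30}, seen at 20
        domain = np.array([10.0, 20.0, 30.0])
        p = DiscretePdf(domain, np.array([0.2, 0.5, 0.3]))
        L = [0.03 + 0.94 * _phi((t - 20.0) / 1.0) for t in (10.0, 20.0, 30.0)]
        w = [0.2 * L[0], 0.5 * L[1], 0.3 * L[2]]
        expected = np.array(w) / sum(w)
        post = update_pdf(p, 20.0, True)
        np.testing.assert_allclose(post.mass, expected, rtol=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 5000), presented=st.floats(0, 40),
           response=st.booleans())
    def test_posterior_always_normalized(self, seed, presented, response):
        rng = np.random.default_rng(seed)
        mass = rng.uniform(0, 1, 41)
        p = DiscretePdf(default_domain(), mass / mass.sum())
        post = update_pdf(p, presented, response)
        assert abs(post.mass.sum() - 1.0) <= 1e-9
        assert post.mass.min() >= 0


class TestSpatialUpdate:
    def _states(self, domain, n=3):
        return [LocationState(pdf=DiscretePdf(domain, np.full(41, 1 / 41.0)))
                for _ in range(n)]

    def test_w0_leaves_neighbor_unchanged(self, domain, strategy_cfg):
        graph = NeighborGraph(edges=frozenset({(0, 1)}), weight=0.0, n=3)
        states = self._states(domain)
        spatial_update(states, graph, 0, 20.0, True, strategy_cfg)
        np.testing.assert_allclose(states[1].pdf.mass, 1 / 41.0, rtol=1e-12)

    def test_w1_equals_full_update(self, domain, strategy_cfg):
        graph = NeighborGraph(edges=frozenset({(0, 1)}), weight=1.0, n=3)
        states = self._states(domain)
        spatial_update(states, graph, 0, 20.0, True, strategy_cfg)
        np.testing.assert_allclose(states[1].pdf.mass, states[0].pdf.mass, rtol=1e-12)

    def test_w04_hand_oracle(self, domain, strategy_cfg):
        # uniform neighbour prior, seen at 20: posterior ~ 0.6 + 0.4 * L
        graph = NeighborGraph(edges=frozenset({(0, 1)}), weight=0.4, n=3)
        states = self._states(domain)
        spatial_update(states, graph, 0, 20.0, True, strategy_cfg)
        L = np.array([0.03 + 0.94 * _phi(t - 20.0) for t in domain])
        expected = (0.6 + 0.4 * L) / (0.6 + 0.4 * L).sum()
        np.testing.assert_allclose(states[1].pdf.mass, expected, rtol=1e-10)

    def test_unconnected_location_unchanged(self, domain, strategy_cfg):
        graph = NeighborGraph(edges=frozenset({(0, 1)}), weight=0.4, n=3)
        states = self._states(domain)
        spatial_update(states, graph, 0, 20.0, True, strategy_cfg)
        np.testing.assert_allclose(states[2].pdf.mass, 1 / 41.0, rtol=1e-12)

    def test_terminated_neighbor_untouched(self, domain, strategy_cfg):
        graph = NeighborGraph(edges=frozenset({(0, 1)}), weight=0.4, n=3)
        states = self._states(domain)
        states[1].terminated = True
        before = states[1].pdf.mass.copy()
        spatial_update(states, graph, 0, 20.0, True, strategy_cfg)
        np.testing.assert_allclose(states[1].pdf.mass, before)


class TestSelectStimulus:
    def test_uniform_prior_gives_20(self, domain):
        p = DiscretePdf(domain, np.full(41, 1 / 41.0))
        assert select_stimulus(p) == 20.0

    def test_point_mass(self, domain):
        mass = np.zeros(41)
        mass[33] = 1.0
        assert select_stimulus(DiscretePdf(domain, mass)) == 33.0

    def test_round_half_even(self, domain):
        # mean 20.4 -> 20; half-even: 20.5 -> 20, 21.5 -> 22
        def two_point(a, b, wa):
            mass = np.zeros(41)
            mass[a], mass[b] = wa, 1 - wa
            return DiscretePdf(domain, mass)

        assert select_stimulus(two_point(20, 21, 0.6)) == 20.0  # mean 20.4
        assert select_stimulus(two_point(20, 21, 0.5)) == 20.0  # mean 20.5
        assert select_stimulus(two_point(21, 22, 0.5)) == 22.0  # mean 21.5


class TestTermination:
    def test_point_mass_terminates(self, domain):
        mass = np.zeros(41)
        mass[10] = 1.0
        assert is_terminated(DiscretePdf(domain, mass))

    def test_uniform_does_not(self, domain):
        assert not is_terminated(DiscretePdf(domain, np.full(41, 1 / 41.0)))

    def test_boundary_inclusive(self, domain):
        # two equal masses at 19 and 22: sd exactly 1.5
        mass = np.zeros(41)
        mass[19] = mass[22] = 0.5
        p = DiscretePdf(domain, mass)
        assert pdf_sd(p) == pytest.approx(1.5)
        assert is_terminated(p)


@pytest.fixture(scope="module")
def ready_eye():
    grid = build_10_2_grid()
    graph = build_neighbor_graph(grid, "standard")
    thresholds = np.full(68, 30.0)
    eye = EyeProfile(true_thresholds=thresholds)
    priors = [make_standard_prior(30.0) for _ in range(68)]
    return eye, grid, graph, priors


class TestRunTest:
    def test_noiseless_observer_recovers_thresholds(self, ready_eye):
        eye, grid, graph, priors = ready_eye
        cfg = StrategyConfig()
        r = run_test(eye, grid, graph, priors, DETERMINISTIC, cfg, seed=11)
        assert not r.capped.any()
        np.testing.assert_allclose(r.estimates, 30.0, atol=1.0)
        assert (r.posterior_sd <= cfg.term_sd + 1e-12).all()

    def test_same_seed_bit_identical(self, ready_eye):
        eye, grid, graph, priors = ready_eye
        a = run_test(eye, grid, graph, priors, RELIABLE, seed=42)
        b = run_test(eye, grid, graph, priors, RELIABLE, seed=42)
        assert a.trace == b.trace
        np.testing.assert_array_equal(a.estimates, b.estimates)
        np.testing.assert_array_equal(a.n_per_location, b.n_per_location)

    def test_different_seed_differs(self, ready_eye):
        eye, grid, graph, priors = ready_eye
        a = run_test(eye, grid, graph, priors, RELIABLE, seed=1)
        b = run_test(eye, grid, graph, priors, RELIABLE, seed=2)
        assert a.trace != b.trace

    def test_count_bookkeeping(self, ready_eye):
        eye, grid, graph, priors = ready_eye
        r = run_test(eye, grid, graph, priors, RELIABLE, seed=3)
        assert r.n_presentations == int(r.n_per_location.sum())
        assert r.n_presentations == len(r.trace)
        counts = np.bincount([t[1] for t in r.trace], minlength=68)
        np.testing.assert_array_equal(counts, r.n_per_location)
        assert r.duration_model_s == pytest.approx(r.n_presentations * 1.6)

    def test_estimates_within_domain(self, ready_eye):
        eye, grid, graph, priors = ready_eye
        r = run_test(eye, grid, graph, priors, RELIABLE, seed=4)
        assert (r.estimates >= 0.0).all() and (r.estimates <= 40.0).all()

    def test_termination_contract(self, ready_eye):
        eye, grid, graph, priors = ready_eye
        cfg = StrategyConfig()
        r = run_test(eye, grid, graph, priors, RELIABLE, cfg, seed=5)
        ok = r.capped | (r.posterior_sd <= cfg.term_sd + 1e-12)
        assert ok.all()
        assert (r.n_per_location[r.capped] == cfg.max_presentations_per_location).all()

    def test_presentation_cap_enforced(self, ready_eye):
        eye, grid, graph, priors = ready_eye
        cfg = StrategyConfig(max_presentations_per_location=2)
        r = run_test(eye, grid, graph, priors, RELIABLE, cfg, seed=6)
        assert (r.n_per_location <= 2).all()

    def test_spatial_requires_graph(self, ready_eye):
        eye, grid, _, priors = ready_eye
        with pytest.raises(ValueError, match="graph"):
            run_test(eye, grid, None, priors, RELIABLE,
                     StrategyConfig(spatial=True), seed=0)

    def test_monotone_informativeness(self):
        # noiseless observer: moving the prior peak onto the true threshold
        # never increases the presentation count (averaged over seeds)
        grid = build_10_2_grid()
        graph = build_neighbor_graph(grid, "standard")
        truth = np.full(68, 12.0)
        eye = EyeProfile(true_thresholds=truth)
        counts = []
        for peak in (30.0, 20.0, 12.0):
            priors = [make_standard_prior(peak) for _ in range(68)]
            n = np.mean([
                run_test(eye, grid, graph, priors, DETERMINISTIC, seed=s).n_presentations
                for s in range(5)
            ])
            counts.append(n)
        assert counts[0] >= counts[1] >= counts[2]

    def test_spatial_reduces_presentations_on_flat_field(self, ready_eye):
        eye, grid, graph, priors = ready_eye
        base = StrategyConfig(spatial=False)
        spat = StrategyConfig(spatial=True)
        n_base = np.mean([run_test(eye, grid, graph, priors, RELIABLE, base, seed=s).n_presentations
                          for s in range(8)])
        n_spat = np.mean([run_test(eye, grid, graph, priors, RELIABLE, spat, seed=s).n_presentations
                          for s in range(8)])
        assert n_spat < n_base

    def test_unrounded_stimuli_path(self, ready_eye):
        eye, grid, graph, priors = ready_eye
        cfg = StrategyConfig(stimulus_rounding=0.0)
        r = run_test(eye, grid, graph, priors, DETERMINISTIC, cfg, seed=9)
        assert not r.capped.any()
        np.testing.assert_allclose(r.estimates, 30.0, atol=1.0)

    def test_result_export(self, tmp_path, ready_eye):
        eye, grid, graph, priors = ready_eye
        r = run_test(eye, grid, graph, priors, RELIABLE, seed=8)
        out = tmp_path / "result.tsv"
        trace = tmp_path / "trace.tsv"
        result_to_text(r, out, trace)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 69
        assert len(trace.read_text().strip().splitlines()) == r.n_presentations + 1


class TestScriptedBayesOracle:
    """Single-location run on a 5-bin domain vs an exhaustive hand Bayes."""

    def test_matches_pure_python_sequence(self):
        domain = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
        prior = [0.1, 0.2, 0.4, 0.2, 0.1]
        responses = [True, False, True, True, False]
        cfg = StrategyConfig()

        # independent oracle: plain-float Bayes with the cdf likelihood
        mass = list(prior)
        oracle_stims = []
        for resp in responses:
            mean = sum(m * x for m, x in zip(mass, domain))
            stim = float(np.round(mean))  # same half-even rounding convention
            oracle_stims.append(stim)
            like = [0.03 + 0.94 * _phi(x - stim) for x in domain]
            if not resp:
                like = [1.0 - v for v in like]
            mass = [m * l for m, l in zip(mass, like)]
            s = sum(mass)
            mass = [m / s for m in mass]

        pdf = DiscretePdf(domain, np.array(prior))
        stims = []
        for resp in responses:
            stim = select_stimulus(pdf, cfg)
            stims.append(stim)
            pdf = update_pdf(pdf, stim, resp, cfg)

        assert stims == oracle_stims
        np.testing.assert_allclose(pdf.mass, mass, rtol=1e-12)
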