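"""Synchronous SIR reference chain: semantics, summaries, invariants."""

import numpy as np
import pytest

from esses.network import BrainNetwork
from esses.sir import (
    AbsorptionError,
    SIRParameters,
    aggregate_pattern,
    infection_ratio,
    mean_ir,
    simulate_ensemble,
    simulate_sir,
    simulate_sir_async,
)
from conftest import make_net
from oracles import exact_final_state_distribution


class TestSimulateSIR:
    def test_isolated_seed_never_spreads(self):
        net = make_net(np.zeros((5, 5)))
        r = simulate_sir(net, {2}, SIRParameters(gamma=0.4, rng_seed=0))
        assert r.ir == pytest.approx(1 / 5)
        assert r.activation_step[2] == 0

    def test_certain_transmission_beats_recovery(self):
        # w=1: the neighbour is recruited in step 1 before any recovery applies
        net = make_net([[0, 1.0], [1.0, 0]])
        for seed in range(20):
            r = simulate_sir(net, {0}, SIRParameters(gamma=1.0, rng_seed=seed))
            assert r.ir == 1.0

    def test_seed_validation(self, star3):
        params = SIRParameters(gamma=0.5)
        with pytest.raises(ValueError, match="nonempty"):
            simulate_sir(star3, set(), params)
        with pytest.raises(ValueError, match="range"):
            simulate_sir(star3, {7}, params)

    def test_reproducible_given_seed(self, star3):
        params = SIRParameters(gamma=0.5, rng_seed=99)
        a = simulate_sir(star3, {0}, params)
        b = simulate_sir(star3, {0}, params)
        assert np.array_equal(a.activation_step, b.activation_step)
        assert np.array_equal(a.final_states, b.final_states)

    def test_step_cap_raises_or_truncates(self):
        # near-zero recovery with a nearly untransmittable link keeps the
        # seed ictal past the 10 * N cap
        net = make_net([[0, 1e-9], [1e-9, 0]])
        with pytest.raises(AbsorptionError):
            simulate_sir(net, {0}, SIRParameters(gamma=1e-9, rng_seed=0))
        params = SIRParameters(gamma=1e-9, rng_seed=0, on_cap="truncate")
        r = simulate_sir(net, {0}, params)
        assert set(np.unique(r.final_states)) <= {0, 2}
        assert r.ir == pytest.approx(0.5)

    def test_star_infection_ratio_matches_closed_form(self, star3):
        # spoke recruited with probability w / (1 - (1-w)(1-gamma)) = 2/3,
        # so E[IR] = (1 + 2 * 2/3) / 3 = 7/9
        params = SIRParameters(gamma=0.5, n_realizations=10_000, rng_seed=5)
        irs = np.array([r.ir for r in simulate_ensemble(star3, {0}, params)])
        se = irs.std() / np.sqrt(irs.size)
        assert abs(irs.mean() - 7 / 9) < 3 * se


class TestInfectionRatio:
    def test_counts_recovered_nodes(self):
        net = make_net(np.eye(10) * 0)
        r = simulate_sir(net, {0, 1}, SIRParameters(gamma=1.0, rng_seed=0))
        assert infection_ratio(r) == pytest.approx(0.2)

    def test_conservation_identity(self, star3, rng):
        for seed in range(10):
            r = simulate_sir(star3, {0}, SIRParameters(gamma=0.3, rng_seed=seed))
            n_s = np.count_nonzero(r.final_states == 0)
            assert infection_ratio(r) == pytest.approx(1 - n_s / r.n_roi)


class TestAggregatePattern:
    def test_fixture_arithmetic(self):
        from esses.sir import SeizureRealization

        def real(steps):
            steps = np.asarray(steps, dtype=float)
            final = np.where(np.isfinite(steps), 2, 0).astype(np.int8)
            return SeizureRealization(frozenset({0}), steps, final)

        inf = np.inf
        reals = [real([0, 2, inf]), real([0, 4, inf]), real([0, inf, inf]), real([0, inf, inf])]
        pat = aggregate_pattern(reals)
        assert pat.participation[0] == 1.0
        assert pat.participation[1] == 0.5
        assert pat.participation[2] == 0.0
        assert pat.mean_activation_step[1] == pytest.approx(3.0)
        assert np.isnan(pat.mean_activation_step[2])

    def test_aggregation_linearity_over_halves(self, star3):
        params = SIRParameters(gamma=0.5, n_realizations=40, rng_seed=3)
        reals = simulate_ensemble(star3, {0}, params)
        whole = aggregate_pattern(reals)
        a, b = aggregate_pattern(reals[:20]), aggregate_pattern(reals[20:])
        assert np.allclose(whole.participation, (a.participation + b.participation) / 2)

    def test_p_i_t_estimates_sum_to_participation(self, star3):
        params = SIRParameters(gamma=0.5, n_realizations=200, rng_seed=4)
        pat = aggregate_pattern(simulate_ensemble(star3, {0}, params), include_p_it=True)
        assert np.allclose(pat.p_i_t.sum(axis=0), pat.participation)


class TestMeanIR:
    def test_deterministic_full_spread(self):
        w = 1.0 - np.eye(4)
        np.fill_diagonal(w, 0)
        net = make_net(w)
        mean, sd = mean_ir(net, {0}, SIRParameters(gamma=0.9, n_realizations=50, rng_seed=0))
        assert mean == 1.0 and sd == 0.0

    def test_isolated_seed_regime(self):
        net = make_net(np.zeros((10, 10)))
        mean, sd = mean_ir(net, {1, 2}, SIRParameters(gamma=0.5, n_realizations=30, rng_seed=0))
        assert mean == pytest.approx(0.2)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_seed_sampler_callable_uses_substream(self, star3):
        sampler = lambda rng: {int(rng.integers(3))}
        params = SIRParameters(gamma=0.5, n_realizations=64, rng_seed=11)
        a = mean_ir(star3, sampler, params)
        b = mean_ir(star3, sampler, params)
        assert a == b


class TestChainInvariants:
    def test_ir_nonincreasing_in_gamma(self, rng):
        # paired seeds: higher recovery cannot increase expected spread
        w = np.triu((rng.random((8, 8)) < 0.5) * (0.3 + 0.4 * rng.random((8, 8))), k=1)
        w += w.T
        net = make_net(w)
        means = []
        for gamma in (0.2, 0.5, 0.9):
            params = SIRParameters(gamma=gamma, n_realizations=400, rng_seed=21)
            means.append(np.mean([r.ir for r in simulate_ensemble(net, {0}, params)]))
        assert means[0] >= means[1] - 0.05
        assert means[1] >= means[2] - 0.05

    def test_edge_removal_never_increases_ir(self, rng):
        w = np.triu((rng.random((8, 8)) < 0.6) * (0.3 + 0.5 * rng.random((8, 8))), k=1)
        w += w.T
        net = make_net(w)
        w2 = w.copy()
        nz = np.argwhere(np.triu(w2, k=1) > 0)
        for i, j in nz[:3]:
            w2[i, j] = w2[j, i] = 0.0
        pruned = make_net(w2)
        params = SIRParameters(gamma=0.4, n_realizations=600, rng_seed=8)
        ir_full = np.mean([r.ir for r in simulate_ensemble(net, {0}, params)])
        ir_pruned = np.mean([r.ir for r in simulate_ensemble(pruned, {0}, params)])
        assert ir_pruned <= ir_full + 0.03

    def test_final_state_distribution_matches_enumeration_small(self, star3):
        # quick version of the exhaustive-oracle check (one topology)
        gamma = 0.5
        expected = exact_final_state_distribution(star3.weights, {0}, gamma)
        params = SIRParameters(gamma=gamma, n_realizations=4000, rng_seed=17)
        counts = {}
        for r in simulate_ensemble(star3, {0}, params):
            key = tuple(int(s) for s in r.final_states)
            counts[key] = counts.get(key, 0) + 1
        for state, p in expected.items():
            if p > 0.02:
                assert counts.get(state, 0) / 4000 == pytest.approx(p, abs=4 * np.sqrt(p * (1 - p) / 4000))


class TestAsyncSampler:
    def test_one_activation_per_event_rank(self, star3):
        r = simulate_sir_async(star3, {0}, SIRParameters(gamma=0.1, rng_seed=2))
        finite = np.sort(r.activation_step[np.isfinite(r.activation_step)])
        assert finite[0] == 0
        assert np.array_equal(finite[1:], np.arange(1, finite.size))

    def test_absorbs_and_reproduces(self, rng):
        w = np.triu((rng.random((10, 10)) < 0.4) * (0.4 + 0.5 * rng.random((10, 10))), k=1)
        w += w.T
        net = make_net(w)
        params = SIRParameters(gamma=0.3, rng_seed=5)
        a = simulate_sir_async(net, {0, 1}, params)
        b = simulate_sir_async(net, {0, 1}, params)
        assert np.array_equal(a.activation_step, b.activation_step)
        assert set(np.unique(a.final_states)) <= {0, 2}

    def test_high_recovery_limits_reach(self):
        # line of weak links: gamma near 1 should usually stop the spread early
        n = 12
        w = np.zeros((n, n))
        for i in range(n - 1):
            w[i, i + 1] = w[i + 1, i] = 0.3
        net = make_net(w)
        irs_low, irs_high = [], []
        for s in range(200):
            irs_low.append(simulate_sir_async(net, {0}, SIRParameters(gamma=0.01, rng_seed=s)).ir)
            irs_high.append(simulate_sir_async(net, {0}, SIRParameters(gamma=1.0, rng_seed=s)).ir)
        assert np.mean(irs_low) > np.mean(irs_high)
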