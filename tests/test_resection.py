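"""Virtual resections: application, seed efficiency, delta-IR, annealing."""

import numpy as np
import pytest

from esses.network import EDRSpec, generate_edr_network, threshold_density
from esses.resection import (
    Resection,
    SAConfig,
    _PanelEnergy,
    _edge_lengths,
    anneal_min_seed_efficiency,
    apply_resection,
    delta_ir,
    overlap_with_plan,
    resection_size_sweep,
    seed_efficiency,
)
from esses.seeds import SeedProbabilityMap
from esses.sir import SIRParameters
from conftest import make_net
from oracles import brute_force_min_energy


def star(n):
    w = np.zeros((n, n))
    w[0, 1:] = w[1:, 0] = 0.8
    return make_net(w)


def path(n, weight=0.8):
    w = np.zeros((n, n))
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = weight
    return make_net(w)


class TestApplyResection:
    def test_empty_resection_is_identity(self, complete4):
        out = apply_resection(complete4, Resection(frozenset()))
        assert np.array_equal(out.weights, complete4.weights)

    def test_total_resection_zeroes_matrix(self, complete4):
        out = apply_resection(complete4, range(4))
        assert not out.weights.any()

    def test_hub_resection_disconnects_star(self):
        out = apply_resection(star(5), {0})
        assert not out.weights.any()

    def test_node_count_preserved_and_original_untouched(self, complete4):
        before = complete4.weights.copy()
        out = apply_resection(complete4, {1})
        assert out.n_roi == 4
        assert np.array_equal(complete4.weights, before)

    def test_out_of_range_rejected(self, complete4):
        with pytest.raises(ValueError):
            apply_resection(complete4, {9})


class TestSeedEfficiency:
    def test_star_hub_seed_hop_distances(self):
        assert seed_efficiency(star(6), {0}, "hop") == pytest.approx(1.0)

    def test_disconnected_seed_scores_zero(self):
        net = make_net(np.zeros((4, 4)))
        assert seed_efficiency(net, {0}) == 0.0

    def test_path_example(self):
        # 4-node path, seed {a}, hop: (1 + 1/2 + 1/3)/3 = 11/18
        assert seed_efficiency(path(4), {0}, "hop") == pytest.approx(11 / 18)

    def test_search_energy_monotone_under_resection_growth(self):
        # the unrestricted inverse-distance objective can only fall as the
        # resection grows (edge removal never shortens a path); the
        # giant-component-restricted value may rise when remote nodes drop
        # out of the component, which is why the annealer does not use it
        net = threshold_density(generate_edr_network(EDRSpec(20, alpha=1.0), seed=2), 0.4)
        energy = _PanelEnergy(_edge_lengths(net.weights, "hop"), [frozenset({0, 1})])
        prev = energy(np.empty(0, dtype=int))
        resected = []
        for node in (5, 9, 13, 17):
            resected.append(node)
            cur = energy(np.asarray(resected))
            assert cur <= prev + 1e-12
            prev = cur

    def test_empty_seed_rejected(self, complete4):
        with pytest.raises(ValueError):
            seed_efficiency(complete4, set())


class TestDeltaIR:
    params = SIRParameters(gamma=0.4, n_realizations=60, rng_seed=3)

    def test_empty_resection_exactly_zero(self):
        net = star(6)
        mean, sd = delta_ir(net, Resection(frozenset()), {0}, self.params)
        assert mean == 0.0 and sd == 0.0

    def test_resecting_unreachable_node_zero(self):
        # two components; resect in the far one
        w = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (3, 4), (4, 5)]:
            w[i, j] = w[j, i] = 0.9
        net = make_net(w)
        mean, _ = delta_ir(net, {4}, {0}, self.params)
        assert mean == 0.0

    def test_seed_isolation_reaches_ceiling(self):
        net = star(8)
        seed_map = SeedProbabilityMap(np.array([1.0] + [0.0] * 7), 3.0)
        params = SIRParameters(gamma=0.4, n_realizations=200, rng_seed=5)
        ir0 = None
        mean, _ = delta_ir(net, {0}, seed_map, params)
        # resecting the hub seed blocks all spread: IR_R = 1/8 per realization
        from esses.resection import _draw_seed_sets, paired_infection_ratios, apply_resection

        rng = np.random.default_rng(params.rng_seed + 999_983)
        seeds = _draw_seed_sets(seed_map, params.n_realizations, rng)
        ir0_arr, _ = paired_infection_ratios(net, net, seeds, params)
        expected = 1 - (1 / 8) / ir0_arr.mean()
        assert mean == pytest.approx(expected, abs=1e-9)

    def test_resected_seed_still_counts_as_ictal(self):
        net = star(4)
        mean, _ = delta_ir(net, {0}, {0}, SIRParameters(gamma=0.9, n_realizations=50, rng_seed=1))
        # hub resected: IR_R = 1/4 every time, IR0 = 1 every time
        assert mean == pytest.approx(1 - 0.25, abs=0.05)


class TestAnnealing:
    def test_star_leaf_seed_finds_disconnecting_single_node(self):
        # removing the hub (or the seed leaf itself) fully isolates the seed;
        # both are global optima with zero energy
        net = star(6)
        res, energy = anneal_min_seed_efficiency(
            net, [frozenset({1})], 1, SAConfig(n_restarts=3), rng=0
        )
        assert energy == 0.0
        assert res.nodes in ({0}, {1})

    def test_invalid_size_rejected(self, complete4):
        with pytest.raises(ValueError):
            anneal_min_seed_efficiency(complete4, [frozenset({0})], 4, rng=0)

    def test_matches_exhaustive_minimum_small_networks(self, rng):
        hits, trials = 0, 12
        for t in range(trials):
            net = threshold_density(
                generate_edr_network(EDRSpec(10, alpha=1.0), seed=100 + t), 0.35
            )
            panel = [frozenset({int(rng.integers(10))}), frozenset({int(rng.integers(10))})]
            energy_fn = _PanelEnergy(_edge_lengths(net.weights, "inverse_weight"), panel)
            e_star, _ = brute_force_min_energy(energy_fn, 10, 3)
            res, e_ann = anneal_min_seed_efficiency(
                net, panel, 3, SAConfig(n_restarts=4), rng=int(rng.integers(2**31))
            )
            assert e_ann <= e_star * 1.05 + 1e-12
            if e_ann <= e_star + 1e-12:
                hits += 1
        assert hits >= 0.75 * trials

    def test_never_worse_than_warm_start(self):
        net = threshold_density(generate_edr_network(EDRSpec(15, alpha=1.0), seed=9), 0.3)
        panel = [frozenset({0, 1})]
        energy_fn = _PanelEnergy(_edge_lengths(net.weights, "inverse_weight"), panel)
        warm = np.array([3, 4, 5])
        e_warm = energy_fn(warm)
        _, e_ann = anneal_min_seed_efficiency(
            net, panel, 3, SAConfig(n_restarts=2), rng=1, warm_start=warm
        )
        assert e_ann <= e_warm + 1e-12


class TestSizeSweep:
    def make_patient_net(self):
        net = threshold_density(generate_edr_network(EDRSpec(24, alpha=1.0), seed=4), 0.3)
        sp = np.zeros(24)
        sp[[0, 1, 2]] = [0.9, 0.8, 0.7]
        return net, SeedProbabilityMap(sp, 3.0)

    def test_rop_first_crossing_and_rd(self):
        net, sp_map = self.make_patient_net()
        sweep = resection_size_sweep(
            net,
            sp_map,
            sizes=range(1, 9),
            sir_params=SIRParameters(gamma=0.3, n_realizations=60, rng_seed=2),
            sa_config=SAConfig(n_restarts=2, proposals_per_temp=30),
            rng_seed=2,
        )
        assert sweep.seed_eff[0] >= sweep.seed_eff[-1]
        # best energies non-increasing in size (warm-started chain)
        assert np.all(np.diff(sweep.seed_eff_norm) <= 1e-9)
        if sweep.r_op is not None:
            k = list(sweep.sizes).index(sweep.r_op.size)
            assert sweep.delta_ir_mean[k] >= 0.90
            assert np.all(sweep.delta_ir_mean[:k] < 0.90)
        if sweep.r_d is not None:
            k = list(sweep.sizes).index(sweep.r_d.size)
            assert sweep.seed_eff[k] == 0.0
            assert np.all(sweep.seed_eff[:k] > 0.0)

    def test_censored_when_target_unreachable(self):
        net, sp_map = self.make_patient_net()
        sweep = resection_size_sweep(
            net,
            sp_map,
            sizes=[1],
            sir_params=SIRParameters(gamma=0.3, n_realizations=40, rng_seed=2),
            sa_config=SAConfig(n_restarts=1, proposals_per_temp=10),
            target_delta=0.999,
            rng_seed=2,
        )
        assert sweep.censored and sweep.r_op is None
        assert sweep.delta_ir_of_optimal() == pytest.approx(np.max(sweep.delta_ir_mean))


class TestOverlap:
    def test_identical_sets(self):
        assert overlap_with_plan(Resection(frozenset({1, 2})), {1, 2}) == 1.0

    def test_disjoint_sets(self):
        assert overlap_with_plan({1, 2}, {3, 4}) == 0.0

    def test_min_normalization(self):
        assert overlap_with_plan(set(range(4)), set(range(3, 13))) == pytest.approx(1 / 4)
        r = {0, 1, 2, 3}
        ra = set(range(2, 12))
        assert overlap_with_plan(r, ra) == pytest.approx(2 / 4)

    def test_jaccard_option(self):
        assert overlap_with_plan({1, 2}, {2, 3}, method="jaccard") == pytest.approx(1 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            overlap_with_plan(set(), {1})
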