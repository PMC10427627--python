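"""Annealing machinery: initial trees, proposal validity and reversibility,
region-weight estimation, candidate selection, small-space optimality."""

import numpy as np
import pytest

from amplitree.data_model import ModelParams
from amplitree.em import fit_em
from amplitree.inference import (
    InferenceConfig,
    anneal,
    default_region_weights,
    estimate_region_weights,
    infer,
    initial_tree,
    propose,
    prufer_to_parent,
    select_candidate_regions,
)
from amplitree.likelihood import LikelihoodWorkspace
from amplitree.prior import tree_log_prior
from amplitree.simulate import SimulationConfig, simulate_cells, simulate_dataset, simulate_tree
from amplitree.tree import GAIN, LOSS, SNV, Event, EventTree, validate_tree

from conftest import make_panel


class TestInitialTree:
    def test_prufer_star(self):
        # the all-zero sequence on 4 nodes decodes to the star centred at 0
        parent = prufer_to_parent([0, 0], 4)
        assert parent == [None, 0, 0, 0]

    def test_deterministic_given_seed(self):
        t1 = initial_tree(5, np.random.default_rng(7))
        t2 = initial_tree(5, np.random.default_rng(7))
        assert t1 == t2

    def test_every_variant_once_no_cnas(self, rng):
        for _ in range(50):
            t = initial_tree(6, rng)
            assert validate_tree(t, 6, 3, [0, 1, 2, 0, 1, 2]) == []
            assert not t.cna_events()
            assert 2 <= t.n_nodes <= 10

    def test_node_count_capped_by_variants(self, rng):
        for _ in range(20):
            t = initial_tree(1, rng)
            assert t.n_nodes == 2


class TestPropose:
    def test_always_valid(self, rng):
        data = make_panel(n_cells=4, n_regions=4, n_variants=3,
                          variant_region=[0, 1, 1], rng=rng)
        tree = initial_tree(3, rng)
        for _ in range(2000):
            tree, _, move = propose(tree, data, rng, allow_cnas=True)
            assert validate_tree(
                tree, data.n_variants, data.n_regions, data.variant_region
            ) == []

    def test_snv_uniqueness_preserved(self, rng):
        data = make_panel(n_cells=4, n_regions=3, n_variants=4,
                          variant_region=[0, 1, 2, 0], rng=rng)
        tree = initial_tree(4, rng)
        for _ in range(500):
            tree, _, _ = propose(tree, data, rng, allow_cnas=False)
        placed = sorted(ev.target for _, ev in tree.snv_events())
        assert placed == [0, 1, 2, 3]

    def test_no_cna_moves_when_disabled(self, rng):
        data = make_panel(n_cells=4, n_regions=3, n_variants=2,
                          variant_region=[0, 1], rng=rng)
        tree = initial_tree(2, rng)
        for _ in range(500):
            tree, _, move = propose(tree, data, rng, allow_cnas=False)
            assert move not in ("add_remove_cna", "toggle_allele")
        assert not tree.cna_events()

    def test_cna_additions_respect_candidates(self, rng):
        data = make_panel(n_cells=4, n_regions=5, n_variants=2,
                          variant_region=[0, 1], rng=rng)
        tree = initial_tree(2, rng, n_nodes=3)
        candidates = {3}
        for _ in range(800):
            tree, _, _ = propose(
                tree, data, rng, allow_cnas=True, candidate_regions=candidates
            )
        for _, ev in tree.cna_events():
            if ev.kind in (GAIN, LOSS):
                assert ev.target == 3
            else:  # CNLOH allowed on any usable variant-bearing region
                assert ev.target in (0, 1)

    def test_add_remove_cna_reversible_with_zero_log_ratio(self, rng):
        """A specific add-CNA draw and its paired removal have Hastings
        log-ratios that sum to zero and restore the original tree."""
        from amplitree.inference import _add_remove_cna

        data = make_panel(n_cells=4, n_regions=4, n_variants=1,
                          variant_region=[0], rng=rng)
        tree = EventTree([None, 0], [[], [Event(SNV, 0)]])
        usable = set(range(4))
        cands = set(range(4))
        found = 0
        for _ in range(300):
            out = _add_remove_cna(
                tree, data, rng, candidate_regions=cands, usable_regions=usable
            )
            if out is None:
                continue
            new, logq_add = out
            if len(new.cna_events()) != 1:
                continue
            if validate_tree(new, 1, 4, [0]):
                continue
            # now remove that exact event
            for _ in range(400):
                out2 = _add_remove_cna(
                    new, data, rng, candidate_regions=cands, usable_regions=usable
                )
                if out2 is None:
                    continue
                back, logq_del = out2
                if back == tree:
                    assert logq_add + logq_del == pytest.approx(0.0, abs=1e-12)
                    found += 1
                    break
            if found >= 5:
                break
        assert found >= 5


class TestRegionWeights:
    def test_all_cells_at_root_equal_depths(self, params):
        rng = np.random.default_rng(0)
        depth = np.full((20, 4), 25)
        data = make_panel(n_cells=20, n_regions=4, n_variants=1, rng=rng)
        data.region_depth = depth
        data.cell_total = depth.sum(axis=1)
        tree = EventTree([None], [[Event(SNV, 0)]])
        state = fit_em(tree, data, params, max_iter=5, tol=1e-3)
        rho = estimate_region_weights(tree, state, data)
        np.testing.assert_allclose(rho, 0.25, atol=1e-12)
        assert rho.sum() == pytest.approx(1.0)

    def test_recovers_simulated_weights(self):
        cfg = SimulationConfig(
            n_cells=1000, n_regions=10, n_nodes=3, n_snvs=3, n_cnas=0,
            coverage_mode="nonuniform", seed=21,
        )
        data, truth = simulate_dataset(cfg)
        params = ModelParams()
        state = fit_em(truth.tree, data, params, max_iter=30, tol=1e-4,
                       rho=truth.region_weights)
        rho = estimate_region_weights(truth.tree, state, data)
        rel_err = np.abs(rho - truth.region_weights) / truth.region_weights
        assert np.max(rel_err) <= 0.10


class TestCandidateSelection:
    def _fit(self, data, truth, params):
        return fit_em(truth.tree, data, params, max_iter=40, tol=1e-4,
                      rho=truth.region_weights)

    def test_subclonal_loss_selected(self):
        # a one-copy loss halves the normalised depth (expected ratio 0.5),
        # far outside [0.8, 1.2]
        rng = np.random.default_rng(3)
        cfg = SimulationConfig(
            n_cells=800, n_regions=8, n_nodes=3, n_snvs=2, n_cnas=0,
            node_weight_concentration=5.0, coverage_mode="uniform", seed=3,
        )
        tree, variants, regions = simulate_tree(cfg, rng)
        # plant a loss on a variant-free region in node 2
        free = [k for k in range(8) if all(v.region != k for v in variants)]
        target = free[0]
        tree.events[2].append(Event(LOSS, target))
        tree.canonicalize()
        data, truth = simulate_cells(tree, cfg, rng, variants, regions)
        params = ModelParams()
        # score against the CNA-free version of the tree, as phase 1 would
        cna_free = tree.copy()
        cna_free.events[2] = [e for e in cna_free.events[2] if not e.is_cna]
        state = fit_em(cna_free, data, params, max_iter=40, tol=1e-4)
        rho = estimate_region_weights(cna_free, state, data)
        selected = select_candidate_regions(cna_free, state, data, rho)
        assert target in selected

    def test_diploid_simulation_selects_nothing(self):
        # at the reference scale (3000 cells, 30 regions) noise in the
        # normalised depth ratios stays well inside the +-20% band
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(
                n_cells=3000, n_regions=30, n_nodes=3, n_snvs=3, n_cnas=0,
                coverage_mode="nonuniform", seed=seed,
            )
            data, truth = simulate_dataset(cfg)
            params = ModelParams()
            state = self._fit(data, truth, params)
            rho = estimate_region_weights(truth.tree, state, data)
            selected = select_candidate_regions(truth.tree, state, data, rho)
            hits += bool(selected)
        assert hits <= 1

    def test_low_weight_region_never_selected(self):
        cfg = SimulationConfig(
            n_cells=300, n_regions=6, n_nodes=3, n_snvs=3, n_cnas=0, seed=5,
        )
        data, truth = simulate_dataset(cfg)
        params = ModelParams()
        state = self._fit(data, truth, params)
        rho = np.array([0.9, 0.02, 0.02, 0.02, 0.02, 0.02])
        rho[1] = 0.001  # below the usability floor of 0.1 / 6
        rho /= rho.sum()
        selected = select_candidate_regions(
            truth.tree, state, data, rho, min_region_depth_fraction=0.1
        )
        assert 1 not in selected


def enumerate_trees(n_variants, max_nodes):
    """All rooted labelled CNA-free trees with <= max_nodes nodes and every
    SNV placed (exhaustive oracle for tiny spaces)."""
    import itertools

    for n_nodes in range(1, max_nodes + 1):
        parents = itertools.product(*[range(n) for n in range(1, n_nodes)])
        for parent_tail in parents:
            parent = [None] + list(parent_tail)
            for assign in itertools.product(range(n_nodes), repeat=n_variants):
                events = [[] for _ in range(n_nodes)]
                for i, node in enumerate(assign):
                    events[node].append(Event(SNV, i))
                yield EventTree(parent, events)


def test_sa_attains_global_optimum_on_enumerable_space():
    """On a tiny instance the annealer's best tree reaches the globally
    optimal posterior found by exhaustive enumeration in >= 18/20 runs."""
    cfg = SimulationConfig(
        n_cells=60, n_regions=4, n_nodes=3, n_snvs=3, n_cnas=0,
        fraction_germline_snps=0.0, node_weight_concentration=3.0, seed=13,
    )
    data, truth = simulate_dataset(cfg)
    params = ModelParams()
    config = InferenceConfig(iterations_phase1=300, iterations_phase2=300)
    ws = LikelihoodWorkspace(data, params)
    rho = default_region_weights(data)

    best_lp = -np.inf
    for tree in enumerate_trees(3, 3):
        state = fit_em(tree, data, params, max_iter=60, tol=1e-6, rho=rho,
                       workspace=ws)
        lp = state.log_post[-1] + tree_log_prior(tree, data, config.penalties)
        best_lp = max(best_lp, lp)

    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        t, st, lp, _ = anneal(
            data, config, params, rng, allow_cnas=False, rho=rho, workspace=ws
        )
        # refit at the full budget for comparability with the oracle
        st = fit_em(t, data, params, max_iter=60, tol=1e-6, rho=rho, workspace=ws)
        lp = st.log_post[-1] + tree_log_prior(t, data, config.penalties)
        if lp >= best_lp - 1e-6:
            hits += 1
    assert hits >= 18


def test_anneal_returns_at_least_initial_posterior(rng):
    data = make_panel(n_cells=20, n_regions=3, n_variants=2,
                      variant_region=[0, 1], rng=rng)
    params = ModelParams()
    config = InferenceConfig(iterations_phase1=50, iterations_phase2=50)
    init = initial_tree(2, rng)
    ws = LikelihoodWorkspace(data, params)
    rho = default_region_weights(data)
    st0 = fit_em(init, data, params, max_iter=config.em_max_iter_search,
                 tol=config.em_tol_search, rho=rho, workspace=ws)
    lp0 = st0.log_post[-1] + tree_log_prior(init, data, config.penalties)
    _, _, lp, _ = anneal(
        data, config, params, rng, allow_cnas=False, rho=rho,
        init_tree=init, workspace=ws,
    )
    assert lp >= lp0 - 1e-9


def test_infer_deterministic_given_seed():
    cfg = SimulationConfig(
        n_cells=120, n_regions=5, n_nodes=3, n_snvs=3, n_cnas=1, seed=2,
    )
    data, _ = simulate_dataset(cfg)
    config = InferenceConfig(
        seed=9, iterations_phase1=80, iterations_phase2=80
    )
    r1 = infer(data, config)
    r2 = infer(data, config)
    assert r1.best_tree == r2.best_tree
    assert r1.log_post == pytest.approx(r2.log_post, abs=1e-12)
    np.testing.assert_array_equal(r1.responsibilities, r2.responsibilities)


def test_phase2_posterior_at_least_phase1():
    cfg = SimulationConfig(
        n_cells=150, n_regions=5, n_nodes=3, n_snvs=3, n_cnas=1, seed=4,
    )
    data, _ = simulate_dataset(cfg)
    config = InferenceConfig(seed=5, iterations_phase1=100, iterations_phase2=100)
    res = infer(data, config)
    assert res.diagnostics["phase2_log_post"] >= res.diagnostics["phase1_log_post"] - 1e-6
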