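"""Likelihood components: limiting forms, normalisation, independent
oracles and the brute-force attachment marginalisation."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import betabinom, nbinom

from amplitree.data_model import ModelParams
from amplitree.likelihood import (
    LikelihoodWorkspace,
    allelic_loglik,
    attachment_logliks,
    beta_binomial_loglik,
    nb_loglik,
    region_depth_loglik,
    tree_loglik,
    unordered_pairs,
)
from amplitree.tree import (
    ALT,
    REF,
    SNV,
    Event,
    EventTree,
    all_genotypes,
    doublet_genotype,
    relabel_nodes,
)

from conftest import make_panel, random_valid_tree


class TestNegativeBinomial:
    def test_matches_scipy_parameterisation(self):
        # independent oracle: scipy's nbinom with n=theta, p=theta/(theta+m)
        for d, m, th in [(5, 4.0, 10.0), (0, 2.5, 3.0), (40, 20.0, 6.0)]:
            expected = nbinom.logpmf(d, th, th / (th + m))
            assert nb_loglik(d, m, th) == pytest.approx(expected, abs=1e-10)

    def test_poisson_limit(self):
        # theta -> inf recovers the Poisson pmf
        from scipy.stats import poisson

        rho = np.array([0.1] + [0.9 / 9] * 9)
        for d in range(0, 30):
            ll = region_depth_loglik(d, 100, np.full(10, 2), 0, rho, 1e9)
            assert ll == pytest.approx(poisson.logpmf(d, 10.0), abs=1e-4)

    def test_normalisation(self):
        total = sum(np.exp(nb_loglik(d, 20.0, 5.0)) for d in range(10001))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_mean_follows_copy_number(self):
        # a region at one copy has half the diploid expected depth; compare
        # against explicit nbinom means
        rho = np.array([0.5, 0.5])
        ll_diploid = region_depth_loglik(25, 100, [2, 2], 0, rho, 6.0)
        ll_loss = region_depth_loglik(25, 100, [1, 2], 0, rho, 6.0)
        m_loss = 100 * 1 * 0.5 / (1 * 0.5 + 2 * 0.5)
        assert ll_loss == pytest.approx(
            nbinom.logpmf(25, 6.0, 6.0 / (6.0 + m_loss)), abs=1e-10
        )
        assert ll_diploid == pytest.approx(
            nbinom.logpmf(25, 6.0, 6.0 / (6.0 + 50.0)), abs=1e-10
        )

    def test_all_zero_profile_errors(self):
        with pytest.raises(ValueError, match="no genome"):
            region_depth_loglik(5, 100, [0, 0], 0, np.array([0.5, 0.5]), 6.0)


class TestBetaBinomial:
    def test_matches_scipy(self):
        for a, d, f, om in [(3, 10, 0.5, 50.0), (0, 25, 0.3, 15.0), (7, 7, 0.9, 8.0)]:
            expected = betabinom.logpmf(a, d, om * f, om * (1 - f))
            assert beta_binomial_loglik(a, d, f, om) == pytest.approx(
                expected, abs=1e-10
            )

    def test_binomial_limit(self):
        from scipy.stats import binom

        for a in range(11):
            assert beta_binomial_loglik(a, 10, 0.5, 1e8) == pytest.approx(
                binom.logpmf(a, 10, 0.5), abs=1e-4
            )

    def test_normalisation(self):
        total = sum(
            np.exp(beta_binomial_loglik(a, 25, 0.3, 50.0)) for a in range(26)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_rejects_degenerate_fraction(self):
        with pytest.raises(ValueError):
            beta_binomial_loglik(1, 5, 0.0, 10.0)


class TestAllelicLoglik:
    def test_no_dropout_het_reduces_to_beta_binomial(self, params):
        # with mu -> 0 and genotype (1,1) the mixture collapses to a single
        # beta-binomial at f = 0.5 (error contributions cancel by symmetry)
        mu = 1e-12
        f = 0.5 * (1 - params.eps) + 0.5 * params.eps
        for a in range(13):
            got = allelic_loglik(a, 12, 1, 1, mu, params)
            want = beta_binomial_loglik(a, 12, f, params.omega_het)
            assert got == pytest.approx(want, abs=1e-6)

    def test_no_dropout_hom_ref(self, params):
        mu = 1e-12
        for a in range(7):
            got = allelic_loglik(a, 6, 1, 0, mu, params)
            want = beta_binomial_loglik(a, 6, params.eps, params.omega_hom)
            assert got == pytest.approx(want, abs=1e-6)

    def test_hand_enumeration_2_1(self, params):
        # genotype (2,1), mu = 0.3: five admissible (k,l) outcomes, summed
        # explicitly from first principles
        mu, eps = 0.3, params.eps
        a, d = 4, 12
        terms = []
        for k in range(3):
            for l in range(2):
                if (k, l) == (0, 0):
                    continue
                from math import comb, log

                w = comb(2, k) * comb(1, l) * mu ** (3 - k - l) * (1 - mu) ** (k + l)
                f = (l * (1 - eps) + k * eps) / (k + l)
                om = params.omega_hom if (k == 0 or l == 0) else params.omega_het
                terms.append(np.log(w) + beta_binomial_loglik(a, d, f, om))
        expected = logsumexp(terms) - np.log1p(-(mu ** 3))
        assert allelic_loglik(a, d, 2, 1, mu, params) == pytest.approx(
            expected, abs=1e-10
        )

    def test_literal_mode_skips_renormalisation(self, params):
        lit = ModelParams(dropout_renormalize=False)
        mu = 0.2
        got_renorm = allelic_loglik(3, 10, 1, 1, mu, params)
        got_literal = allelic_loglik(3, 10, 1, 1, mu, lit)
        assert got_renorm == pytest.approx(
            got_literal - np.log1p(-(mu ** 2)), abs=1e-12
        )

    def test_zero_depth_contributes_nothing(self, params):
        assert allelic_loglik(0, 0, 1, 1, 0.1, params) == 0.0

    def test_deleted_locus_errors(self, params):
        with pytest.raises(ValueError, match="absent"):
            allelic_loglik(1, 5, 0, 0, 0.1, params)


class TestWorkspaceAgreesWithScalars:
    """The cached vectorised path must reproduce the scalar formulas."""

    def test_region_channel(self, params, rng):
        data = make_panel(n_cells=6, n_regions=4, n_variants=2,
                          variant_region=[0, 1], rng=rng)
        ws = LikelihoodWorkspace(data, params)
        rho = np.array([0.4, 0.3, 0.2, 0.1])
        cn = np.array([2, 1, 2, 3])
        got = ws.region_ll(cn, rho)
        for j in range(data.n_cells):
            want = sum(
                region_depth_loglik(
                    int(data.region_depth[j, k]), int(data.cell_total[j]),
                    cn, k, rho, params.theta,
                )
                for k in range(4)
            )
            assert got[j] == pytest.approx(want, abs=1e-8)

    def test_allelic_channel(self, params, rng):
        data = make_panel(n_cells=6, n_regions=3, n_variants=2,
                          variant_region=[0, 2], rng=rng)
        ws = LikelihoodWorkspace(data, params)
        for (c_r, c_a) in [(2, 0), (1, 1), (0, 2), (2, 1), (1, 0)]:
            got = ws.allelic_ll(1, c_r, c_a, 0.08)
            for j in range(data.n_cells):
                want = allelic_loglik(
                    int(data.alt_counts[j, 1]), int(data.var_depth[j, 1]),
                    c_r, c_a, 0.08, params,
                )
                assert got[j] == pytest.approx(want, abs=1e-8)


class TestTreeLoglik:
    def test_single_node_sums_cells(self, params):
        data = make_panel(n_cells=4, n_regions=2, n_variants=1)
        tree = EventTree([None], [[Event(SNV, 0)]])
        att = attachment_logliks(tree, data, params, mu=np.array([0.05]))
        got = tree_loglik(tree, data, params, np.array([1.0]), mu=np.array([0.05]))
        assert got == pytest.approx(att.singlet_ll[:, 0].sum(), abs=1e-10)

    def test_duplicate_genotype_columns_identical(self, params):
        data = make_panel(n_cells=4, n_regions=2, n_variants=1)
        tree = EventTree([None, 0], [[Event(SNV, 0)], []])  # child = root genotype
        att = attachment_logliks(tree, data, params, mu=np.array([0.05]))
        np.testing.assert_allclose(att.singlet_ll[:, 0], att.singlet_ll[:, 1])

    def test_delta_zero_equals_delta_limit(self, rng):
        data = make_panel(n_cells=5, n_regions=3, n_variants=2,
                          variant_region=[0, 1], rng=rng)
        tree = EventTree([None, 0], [[Event(SNV, 0)], [Event(SNV, 1)]])
        pi = np.array([0.4, 0.6])
        mu = np.array([0.05, 0.05])
        p0 = ModelParams(doublet_rate=0.0)
        p_eps = ModelParams(doublet_rate=1e-12)
        ll0 = tree_loglik(tree, data, p0, pi, mu=mu, doublets=True)
        ll_eps = tree_loglik(tree, data, p_eps, pi, mu=mu, doublets=True)
        assert ll0 == pytest.approx(ll_eps, abs=1e-9)

    def test_invariant_under_node_relabelling(self, params, rng):
        data = make_panel(n_cells=5, n_regions=3, n_variants=3,
                          variant_region=[0, 1, 2], rng=rng)
        mu = np.full(3, 0.05)
        for _ in range(10):
            tree = random_valid_tree(rng, 3, 3, [0, 1, 2], n_nodes=4)
            pi = rng.dirichlet(np.ones(4))
            perm = [0] + list(1 + rng.permutation(3))
            tree2 = relabel_nodes(tree, perm)
            pi2 = np.empty(4)
            for old, new in enumerate(perm):
                pi2[new] = pi[old]
            ll1 = tree_loglik(tree, data, params, pi, mu=mu, doublets=True)
            ll2 = tree_loglik(tree2, data, params, pi2, mu=mu, doublets=True)
            assert ll1 == pytest.approx(ll2, abs=1e-8)

    def test_additive_over_cells(self, params, rng):
        data = make_panel(n_cells=6, n_regions=2, n_variants=1, rng=rng)
        tree = EventTree([None, 0], [[], [Event(SNV, 0)]])
        pi = np.array([0.3, 0.7])
        mu = np.array([0.05])
        full = tree_loglik(tree, data, params, pi, mu=mu)
        att = attachment_logliks(tree, data, params, mu=mu)
        per_cell = logsumexp(att.singlet_ll + np.log(pi)[None, :], axis=1)
        assert full == pytest.approx(per_cell.sum(), abs=1e-10)


def brute_force_tree_loglik(tree, data, params, pi, mu, rho, delta):
    """Oracle: enumerate every attachment (each node, each ordered node
    pair) and sum in probability space, cell by cell, using only the scalar
    likelihood functions."""
    genos = all_genotypes(tree, data.n_variants, data.n_regions, data.variant_region)
    n = tree.n_nodes

    def cell_ll(j, g):
        ll = 0.0
        for k in range(data.n_regions):
            ll += region_depth_loglik(
                int(data.region_depth[j, k]), int(data.cell_total[j]),
                g.region_cn, k, rho, params.theta,
            )
        for i in range(data.n_variants):
            c_r, c_a = int(g.allele_cn[i, 0]), int(g.allele_cn[i, 1])
            a, d = int(data.alt_counts[j, i]), int(data.var_depth[j, i])
            if c_r + c_a == 0:
                ll += (
                    beta_binomial_loglik(a, d, params.eps, params.omega_hom)
                    if d > 0 else 0.0
                )
            else:
                ll += allelic_loglik(a, d, c_r, c_a, float(mu[i]), params)
        return ll

    total = 0.0
    for j in range(data.n_cells):
        p = 0.0
        for node in range(n):
            p += (1 - delta) * pi[node] * np.exp(cell_ll(j, genos[node]))
        if delta > 0:
            for a in range(n):
                for b in range(n):
                    g = doublet_genotype(genos[a], genos[b])
                    p += delta * pi[a] * pi[b] * np.exp(cell_ll(j, g))
        total += np.log(p)
    return total


def test_marginalisation_matches_brute_force(rng):
    """tree_loglik equals full attachment enumeration (singlets + ordered
    doublet pairs) on random small instances."""
    for trial in range(25):
        n_variants = int(rng.integers(1, 4))
        n_regions = int(rng.integers(2, 5))
        variant_region = [int(rng.integers(0, n_regions)) for _ in range(n_variants)]
        data = make_panel(
            n_cells=int(rng.integers(2, 8)),
            n_regions=n_regions,
            n_variants=n_variants,
            variant_region=variant_region,
            rng=rng,
        )
        tree = random_valid_tree(
            rng, n_variants, n_regions, variant_region,
            n_nodes=int(rng.integers(2, 5)),
        )
        pi = rng.dirichlet(np.ones(tree.n_nodes))
        mu = rng.uniform(0.02, 0.3, size=n_variants)
        rho = rng.dirichlet(np.ones(n_regions))
        delta = float(rng.choice([0.0, 0.1]))
        params = ModelParams(doublet_rate=delta)
        got = tree_loglik(
            tree, data, params, pi, mu=mu, rho=rho, doublets=delta > 0
        )
        want = brute_force_tree_loglik(tree, data, params, pi, mu, rho, delta)
        assert got == pytest.approx(want, abs=1e-8)


def test_unordered_pair_weights_match_ordered_double_sum(rng):
    """The unordered-pair evaluation must reproduce the ordered double sum
    exactly (self-pairs weight pi^2, cross pairs 2 pi pi')."""
    data = make_panel(n_cells=3, n_regions=2, n_variants=1, rng=rng)
    tree = EventTree([None, 0, 0], [[], [Event(SNV, 0)], []])
    pi = np.array([0.2, 0.5, 0.3])
    mu = np.array([0.1])
    params = ModelParams(doublet_rate=0.15)
    got = tree_loglik(tree, data, params, pi, mu=mu, doublets=True)
    want = brute_force_tree_loglik(
        tree, data, params, pi, mu,
        np.full(2, 0.5), 0.15,
    )
    assert got == pytest.approx(want, abs=1e-8)
    assert len(unordered_pairs(3)) == 6
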