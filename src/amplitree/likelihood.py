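"""Read-count likelihoods and the attachment-marginalised tree likelihood.

Two observation channels per cell:

* the total read count in each region follows a negative binomial with mean
  ``D_j * c_k * rho_k / sum_l c_l rho_l`` (total cell depth apportioned by
  copy-number-scaled region weights) and inverse dispersion ``theta``;
* the ALT read count at each variant follows a beta-binomial mixture over
  the possible allelic-dropout outcomes: with ``c_r`` reference and ``c_a``
  alternative copies, each copy independently fails to amplify with
  probability ``mu_i``; conditioned on at least one amplified copy (k, l),
  the ALT fraction is ``l/(k+l)*(1-eps) + k/(k+l)*eps`` with concentration
  ``omega_hom`` when a single allele amplified and ``omega_het`` otherwise.

The tree likelihood marginalises cell attachments over nodes (and optionally
over unordered node pairs for doublets) with learned node weights ``pi``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, log, log1p
from typing import Optional, Sequence

import numpy as np
from scipy.special import betaln, gammaln, logsumexp

from .data_model import ModelParams, PanelData
from .tree import EventTree, Genotype, all_genotypes, doublet_genotype

__all__ = [
    "region_depth_loglik",
    "beta_binomial_loglik",
    "allelic_loglik",
    "AttachmentLogLik",
    "attachment_logliks",
    "tree_loglik",
    "LikelihoodWorkspace",
]


# ---------------------------------------------------------------------------
# scalar building blocks
# ---------------------------------------------------------------------------


def nb_loglik(d: int, mean: float, theta: float) -> float:
    """log NB(d; mean, theta) with variance mean + mean^2/theta."""
    if mean < 0 or theta <= 0:
        raise ValueError("mean must be >= 0 and theta > 0")
    if mean == 0.0:
        return 0.0 if d == 0 else -np.inf
    return float(
        gammaln(d + theta)
        - gammaln(d + 1)
        - gammaln(theta)
        + theta * log(theta / (theta + mean))
        + d * log(mean / (theta + mean))
    )


def region_depth_loglik(
    d_kj: int,
    d_j: int,
    cn_profile: Sequence[float],
    k: int,
    rho: Sequence[float],
    theta: float,
) -> float:
    """Log-probability of the read count in region ``k`` for a cell with
    total depth ``d_j`` attached to a genotype with region copy numbers
    ``cn_profile``."""
    cn = np.asarray(cn_profile, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if d_j <= 0:
        raise ValueError("cell total depth must be positive")
    denom = float(cn @ rho)
    if denom <= 0:
        raise ValueError("cell cannot attach to a genotype with no genome")
    mean = d_j * cn[k] * rho[k] / denom
    return nb_loglik(d_kj, mean, theta)


def beta_binomial_loglik(a: int, d: int, f: float, omega: float) -> float:
    """log BetaBinomial(a; d, omega*f, omega*(1-f))."""
    if not (0 <= a <= d):
        raise ValueError("require 0 <= a <= d")
    if not (0.0 < f < 1.0):
        raise ValueError("f must lie strictly inside (0, 1); clamp upstream")
    if omega <= 0:
        raise ValueError("omega must be positive")
    return float(
        gammaln(d + 1)
        - gammaln(a + 1)
        - gammaln(d - a + 1)
        + betaln(a + omega * f, d - a + omega * (1 - f))
        - betaln(omega * f, omega * (1 - f))
    )


def _dropout_terms(
    c_r: int, c_a: int, mu: float, eps: float
) -> list[tuple[int, int, float, float]]:
    """Admissible amplification outcomes (k, l) with their log weights and
    ALT fractions."""
    out = []
    for k in range(c_r + 1):
        for l in range(c_a + 1):
            if k == 0 and l == 0:
                continue
            logw = (
                log(comb(c_r, k))
                + log(comb(c_a, l))
                + (c_r + c_a - k - l) * log(mu)
                + (k + l) * log1p(-mu)
            )
            f = (l * (1 - eps) + k * eps) / (k + l)
            out.append((k, l, logw, f))
    return out


def allelic_loglik(
    a_ij: int,
    d_ij: int,
    c_r: int,
    c_a: int,
    mu_i: float,
    params: ModelParams,
    renormalize: Optional[bool] = None,
) -> float:
    """Log-probability of the ALT count at one locus in one cell.

    Mixture over allelic-dropout outcomes; by default renormalised by
    ``1 - mu^(c_r + c_a)`` so the retained terms form a proper distribution.
    Zero observed depth contributes log-probability 0 (no observation); a
    fully deleted locus (``c_r + c_a = 0``) must be handled by the caller.
    """
    if c_r + c_a < 1:
        raise ValueError("locus absent from genotype (c_r + c_a = 0)")
    if d_ij == 0:
        return 0.0
    if not (0.0 < mu_i < 1.0):
        raise ValueError("dropout rate must lie in (0, 1)")
    if renormalize is None:
        renormalize = params.dropout_renormalize
    terms = []
    for k, l, logw, f in _dropout_terms(c_r, c_a, mu_i, params.eps):
        omega = params.omega_hom if (k == 0 or l == 0) else params.omega_het
        terms.append(logw + beta_binomial_loglik(a_ij, d_ij, f, omega))
    ll = float(logsumexp(terms))
    if renormalize:
        ll -= log1p(-(mu_i ** (c_r + c_a)))
    return ll


# ---------------------------------------------------------------------------
# vectorised workspace
# ---------------------------------------------------------------------------


class LikelihoodWorkspace:
    """Per-dataset caches for fast repeated tree scoring.

    The expensive cell-level beta-binomial terms depend only on the data, the
    error rate and the concentrations -- not on the dropout rates or the tree
    -- so they are computed once per (variant, k, l) and reused across EM
    iterations and annealing steps.
    """

    def __init__(self, data: PanelData, params: ModelParams):
        self.data = data
        self.params = params
        th = params.theta
        d = data.region_depth
        # negative-binomial data-only terms
        self._nb_const = (
            gammaln(d + th) - gammaln(d + 1) - gammaln(th)
        )  # (cells, regions)
        self._cell_total = data.cell_total.astype(float)
        # beta-binomial data-only terms
        A = data.alt_counts.astype(float)
        D = data.var_depth.astype(float)
        self._log_binom = gammaln(D + 1) - gammaln(A + 1) - gammaln(D - A + 1)
        self._A, self._D = A, D
        self._has_depth = D > 0
        self._bb_cache: dict[tuple[int, int, int], np.ndarray] = {}
        self._err_cache: dict[int, np.ndarray] = {}
        self._stack_cache: dict[tuple[int, int, int], tuple] = {}
        self._region_cache: dict[tuple, np.ndarray] = {}
        self._allelic_cache: dict[tuple, np.ndarray] = {}

    # -- depth channel -------------------------------------------------------
    def region_ll(self, region_cn: np.ndarray, rho: np.ndarray) -> np.ndarray:
        """Summed depth log-likelihood per cell for one region copy profile.

        ``region_cn`` may be fractional (doublet genotypes).  Results are
        cached per (profile, rho) since annealing revisits the same copy
        profiles constantly."""
        key = (tuple(np.asarray(region_cn, dtype=float)), rho.tobytes())
        cached = self._region_cache.get(key)
        if cached is not None:
            return cached
        cn = np.asarray(region_cn, dtype=float)
        rho = np.asarray(rho, dtype=float)
        w = cn * rho
        denom = w.sum()
        if denom <= 0:
            raise ValueError("cell cannot attach to a genotype with no genome")
        frac = w / denom  # (regions,)
        th = self.params.theta
        mean = self._cell_total[:, None] * frac[None, :]
        d = self.data.region_depth
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = (
                self._nb_const
                + th * np.log(th / (th + mean))
                + d * np.log(mean / (th + mean))
            )
        if np.any(frac == 0.0):
            zero = frac == 0.0
            ll[:, zero] = np.where(d[:, zero] == 0, 0.0, -np.inf)
        out = ll.sum(axis=1)
        if len(self._region_cache) > 4096:
            self._region_cache.clear()
        self._region_cache[key] = out
        return out

    # -- allelic channel -------------------------------------------------------
    def _bb(self, i: int, k: int, l: int) -> np.ndarray:
        """Beta-binomial log-likelihood vector over cells for variant ``i``
        given amplified copies (k, l).  Zero-depth cells contribute 0."""
        key = (i, k, l)
        cached = self._bb_cache.get(key)
        if cached is not None:
            return cached
        p = self.params
        f = (l * (1 - p.eps) + k * p.eps) / (k + l)
        omega = p.omega_hom if (k == 0 or l == 0) else p.omega_het
        A, D = self._A[:, i], self._D[:, i]
        ll = (
            self._log_binom[:, i]
            + betaln(A + omega * f, D - A + omega * (1 - f))
            - betaln(omega * f, omega * (1 - f))
        )
        ll = np.where(self._has_depth[:, i], ll, 0.0)
        self._bb_cache[key] = ll
        return ll

    def _err_ll(self, i: int) -> np.ndarray:
        """Pure sequencing-error model for reads at a fully deleted locus."""
        cached = self._err_cache.get(i)
        if cached is None:
            cached = self._bb(i, 1, 0)
            self._err_cache[i] = cached
        return cached

    def allelic_term_stack(
        self, i: int, c_r: int, c_a: int, mu_i: float
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(log-weights, amplified-copy counts, per-cell term matrix) for the
        dropout mixture of variant ``i`` under genotype (c_r, c_a).

        The mu-independent parts (binomial coefficients, term matrix) are
        cached; only the dropout log-weights are recomputed."""
        key = (i, c_r, c_a)
        cached = self._stack_cache.get(key)
        if cached is None:
            terms = _dropout_terms(c_r, c_a, 0.5, self.params.eps)
            log_comb = np.array(
                [log(comb(c_r, k)) + log(comb(c_a, l)) for k, l, _, _ in terms]
            )
            amplified = np.array([k + l for k, l, _, _ in terms], dtype=float)
            mat = np.stack([self._bb(i, k, l) for k, l, _, _ in terms])
            cached = (log_comb, amplified, mat)
            self._stack_cache[key] = cached
        log_comb, amplified, mat = cached
        c = c_r + c_a
        logw = log_comb + (c - amplified) * log(mu_i) + amplified * log1p(-mu_i)
        return logw, amplified, mat

    def allelic_ll(self, i: int, c_r: int, c_a: int, mu_i: float) -> np.ndarray:
        """Per-cell allelic log-likelihood vector for variant ``i``."""
        if c_r + c_a == 0:
            return self._err_ll(i)
        key = (i, c_r, c_a, round(float(mu_i), 12))
        cached = self._allelic_cache.get(key)
        if cached is not None:
            return cached
        logw, _, mat = self.allelic_term_stack(i, c_r, c_a, mu_i)
        ll = logsumexp(mat + logw[:, None], axis=0)
        if self.params.dropout_renormalize:
            ll = ll - log1p(-(mu_i ** (c_r + c_a)))
        ll = np.where(self._has_depth[:, i], ll, 0.0)
        if len(self._allelic_cache) > 16384:
            self._allelic_cache.clear()
        self._allelic_cache[key] = ll
        return ll

    # -- per-genotype ----------------------------------------------------------
    def genotype_ll(
        self, genotype: Genotype, mu: np.ndarray, rho: np.ndarray
    ) -> np.ndarray:
        """Full per-cell log-likelihood (depth + allelic) for one genotype."""
        ll = self.region_ll(genotype.region_cn, rho)
        for i in range(self.data.n_variants):
            c_r, c_a = int(genotype.allele_cn[i, 0]), int(genotype.allele_cn[i, 1])
            ll = ll + self.allelic_ll(i, c_r, c_a, float(mu[i]))
        return ll


# ---------------------------------------------------------------------------
# attachment log-likelihoods and the marginalised tree likelihood
# ---------------------------------------------------------------------------


@dataclass
class AttachmentLogLik:
    """Per-cell log-likelihoods of every attachment.

    ``pairs`` lists the unordered node pairs (n <= n') backing the columns of
    ``doublet_ll``; self-pairs are included."""

    singlet_ll: np.ndarray
    pairs: Optional[list[tuple[int, int]]] = None
    doublet_ll: Optional[np.ndarray] = None


def unordered_pairs(n_nodes: int) -> list[tuple[int, int]]:
    return [(n, m) for n in range(n_nodes) for m in range(n, n_nodes)]


def attachment_logliks(
    tree: EventTree,
    data: PanelData,
    params: ModelParams,
    mu: Optional[np.ndarray] = None,
    rho: Optional[np.ndarray] = None,
    doublets: bool = False,
    workspace: Optional[LikelihoodWorkspace] = None,
) -> AttachmentLogLik:
    """Per-cell per-attachment log-likelihoods under ``tree``."""
    ws = workspace or LikelihoodWorkspace(data, params)
    if mu is None:
        mu = params.dropout_rates
    if mu is None:
        mu = np.full(data.n_variants, 0.05)
    if rho is None:
        rho = params.region_weights
    if rho is None:
        rho = np.full(data.n_regions, 1.0 / data.n_regions)
    genos = all_genotypes(tree, data.n_variants, data.n_regions, data.variant_region)
    singlet = np.stack([ws.genotype_ll(g, mu, rho) for g in genos], axis=1)
    if not doublets:
        return AttachmentLogLik(singlet_ll=singlet)
    pairs = unordered_pairs(tree.n_nodes)
    doublet = np.stack(
        [
            ws.genotype_ll(doublet_genotype(genos[n], genos[m]), mu, rho)
            for n, m in pairs
        ],
        axis=1,
    )
    return AttachmentLogLik(singlet_ll=singlet, pairs=pairs, doublet_ll=doublet)


def pair_log_weights(
    pi: np.ndarray, pairs: list[tuple[int, int]], delta: float
) -> np.ndarray:
    """log delta * pi_n * pi_n' summed over both orderings (self-pairs once)."""
    w = np.empty(len(pairs))
    for idx, (n, m) in enumerate(pairs):
        p = pi[n] * pi[m] * (1.0 if n == m else 2.0)
        w[idx] = p
    with np.errstate(divide="ignore"):
        return np.log(delta) + np.log(w)


def tree_loglik(
    tree: EventTree,
    data: PanelData,
    params: ModelParams,
    pi: np.ndarray,
    mu: Optional[np.ndarray] = None,
    rho: Optional[np.ndarray] = None,
    doublets: bool = False,
    workspace: Optional[LikelihoodWorkspace] = None,
    attachments: Optional[AttachmentLogLik] = None,
) -> float:
    """Attachment-marginalised log-likelihood of the tree.

    With doublets the per-cell mixture is ``(1-delta) sum_n pi_n L_jn +
    delta sum_{n,n'} pi_n pi_n' L_j(n,n')`` (ordered double sum, evaluated
    over unordered pairs with symmetric weights)."""
    pi = np.asarray(pi, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-8 or np.any(pi < 0):
        raise ValueError("pi must lie on the probability simplex")
    if pi.shape[0] != tree.n_nodes:
        raise ValueError("pi length must match the number of nodes")
    att = attachments or attachment_logliks(
        tree, data, params, mu=mu, rho=rho, doublets=doublets, workspace=workspace
    )
    delta = params.doublet_rate if doublets else 0.0
    with np.errstate(divide="ignore"):
        log_pi = np.log((1.0 - delta) * pi)
    cols = att.singlet_ll + log_pi[None, :]
    if doublets and delta > 0.0:
        logw = pair_log_weights(pi, att.pairs, delta)
        cols = np.concatenate([cols, att.doublet_ll + logw[None, :]], axis=1)
    return float(logsumexp(cols, axis=1).sum())
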