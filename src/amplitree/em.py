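"""Per-tree EM estimation of node weights and per-variant dropout rates.

Given a fixed event tree, the latent variables are the attachment of each
cell (a node, or an unordered node pair when doublets are modelled) and, per
cell and locus, the number of reference/alternative copies that actually
amplified.  The E-step computes attachment responsibilities (Bayes rule over
the per-attachment likelihoods) and dropout-outcome posteriors; the M-step
sets each node weight to its expected cell fraction (flat Dirichlet prior)
and each dropout rate to the maximiser of the expected complete-data log
posterior under a beta prior.

With the default renormalised dropout likelihood the dropout M-step has no
closed form (the renormaliser ``1 - mu^c`` depends on ``mu``); it is solved
by bounded scalar maximisation, guarded so the objective never decreases.
With ``dropout_renormalize=False`` the closed-form MAP update

    mu_i = (alpha - 1 + E[dropped copies]) / (alpha + beta - 2 + E[total copies])

is exact.  Either way the observed-data log posterior is non-decreasing
across iterations, which :func:`fit_em` asserts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log1p
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .data_model import ModelParams, PanelData
from .likelihood import (
    AttachmentLogLik,
    LikelihoodWorkspace,
    attachment_logliks,
    pair_log_weights,
)
from .tree import EventTree, all_genotypes, doublet_genotype

MU_MIN, MU_MAX = 1e-4, 0.5


class EMError(RuntimeError):
    """Raised when EM detects a numerical inconsistency (e.g. a decreasing
    log-posterior trace, signalling an implementation bug)."""


@dataclass
class EMState:
    """Fitted state of the per-tree EM.

    ``responsibilities`` has one column per attachment: the tree's nodes
    first, then (if doublets are enabled) the unordered node pairs listed in
    ``pairs``.  ``log_post`` traces the observed-data log posterior (tree
    log-likelihood plus the beta log-prior of mu) across iterations.
    """

    responsibilities: np.ndarray
    pi: np.ndarray
    mu: np.ndarray
    log_post: list[float] = field(default_factory=list)
    pairs: Optional[list[tuple[int, int]]] = None
    attachments: Optional[AttachmentLogLik] = None

    @property
    def loglik(self) -> float:
        """Tree log-likelihood at the fitted parameters (prior excluded)."""
        return self.log_post[-1] - _mu_log_prior(self.mu, self._alpha, self._beta)

    # set by fit_em
    _alpha: float = 2.0
    _beta: float = 38.0


def _mu_log_prior(mu: np.ndarray, alpha: float, beta: float) -> float:
    return float(((alpha - 1) * np.log(mu) + (beta - 1) * np.log1p(-mu)).sum())


def _attachment_log_weights(
    pi: np.ndarray, pairs: Optional[list[tuple[int, int]]], delta: float
) -> np.ndarray:
    """Log prior weight of every attachment column."""
    with np.errstate(divide="ignore"):
        logw = np.log((1.0 - delta) * pi) if delta > 0 else np.log(pi)
    if pairs is not None and delta > 0:
        logw = np.concatenate([logw, pair_log_weights(pi, pairs, delta)])
    return logw


def e_step(
    tree: EventTree,
    data: PanelData,
    params: ModelParams,
    pi: np.ndarray,
    mu: np.ndarray,
    rho: Optional[np.ndarray] = None,
    doublets: bool = False,
    workspace: Optional[LikelihoodWorkspace] = None,
    attachments: Optional[AttachmentLogLik] = None,
) -> tuple[np.ndarray, AttachmentLogLik, float]:
    """Attachment responsibilities, per-attachment log-likelihoods and the
    observed-data log-likelihood, all at the supplied (pi, mu)."""
    att = attachments or attachment_logliks(
        tree, data, params, mu=mu, rho=rho, doublets=doublets, workspace=workspace
    )
    delta = params.doublet_rate if doublets else 0.0
    logw = _attachment_log_weights(pi, att.pairs, delta)
    cols = att.singlet_ll
    if att.doublet_ll is not None and delta > 0:
        cols = np.concatenate([cols, att.doublet_ll], axis=1)
        joint = cols + logw[None, :]
    else:
        joint = cols + logw[None, : tree.n_nodes]
    norm = logsumexp(joint, axis=1)
    if np.any(~np.isfinite(norm)):
        raise EMError("non-finite attachment posterior (all columns -inf?)")
    resp = np.exp(joint - norm[:, None])
    return resp, att, float(norm.sum())


def _map_dropout_update(
    ndrop: float,
    namp: float,
    mcounts: dict[int, float],
    alpha: float,
    beta: float,
    renormalize: bool,
    mu_prev: float,
) -> float:
    """Maximise the expected complete-data log posterior in one dropout rate.

    ``mcounts`` maps total copy number c to the expected number of
    (cell, attachment) units with that total, used for the renormalisation
    correction ``- sum_c M_c log(1 - mu^c)``.
    """
    a = alpha - 1 + ndrop
    b = beta - 1 + namp
    if not renormalize:
        denom = alpha + beta - 2 + ndrop + namp
        if denom <= 0:
            return mu_prev
        return float(np.clip(a / denom, MU_MIN, MU_MAX))

    def neg_obj(m: float) -> float:
        val = a * np.log(m) + b * np.log1p(-m)
        for c, w in mcounts.items():
            if w > 0:
                val -= w * log1p(-(m ** c))
        return -val

    res = minimize_scalar(
        neg_obj, bounds=(MU_MIN, MU_MAX), method="bounded",
        options={"xatol": 1e-8},
    )
    cand = float(res.x)
    # generalised-EM guard: never accept a value worse than the previous one
    if neg_obj(cand) > neg_obj(np.clip(mu_prev, MU_MIN, MU_MAX)):
        return float(np.clip(mu_prev, MU_MIN, MU_MAX))
    return cand


def m_step(
    responsibilities: np.ndarray,
    tree: EventTree,
    data: PanelData,
    params: ModelParams,
    mu_prev: np.ndarray,
    workspace: LikelihoodWorkspace,
    pairs: Optional[list[tuple[int, int]]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Updated (pi, mu) from the current responsibilities.

    pi: expected fraction of cells per node; each member of a doublet pair is
    credited half a cell (a self-pair credits the full cell to its node).
    mu: MAP update per variant, using attachment-level genotypes (summed
    copy numbers for doublet attachments).
    """
    n_nodes = tree.n_nodes
    n_cells = data.n_cells
    resp = responsibilities
    pi = resp[:, :n_nodes].sum(axis=0)
    if pairs is not None and resp.shape[1] > n_nodes:
        pair_mass = resp[:, n_nodes:].sum(axis=0)
        for idx, (n, m) in enumerate(pairs):
            if n == m:
                pi[n] += pair_mass[idx]
            else:
                pi[n] += 0.5 * pair_mass[idx]
                pi[m] += 0.5 * pair_mass[idx]
    pi = pi / n_cells
    pi = np.clip(pi, 1e-12, None)
    pi = pi / pi.sum()

    genos = all_genotypes(tree, data.n_variants, data.n_regions, data.variant_region)
    att_genos = list(genos)
    if pairs is not None and resp.shape[1] > n_nodes:
        att_genos += [doublet_genotype(genos[n], genos[m]) for n, m in pairs]

    has_depth = workspace._has_depth
    mu = np.array(mu_prev, dtype=float)
    alpha, beta = params.dropout_prior_alpha, params.dropout_prior_beta
    for i in range(data.n_variants):
        ndrop = 0.0
        namp = 0.0
        mcounts: dict[int, float] = {}
        obs = has_depth[:, i].astype(float)
        # attachments sharing a genotype at this locus share the dropout
        # posterior; pool their responsibilities first
        groups: dict[tuple[int, int], np.ndarray] = {}
        for col, g in enumerate(att_genos):
            c_r, c_a = int(g.allele_cn[i, 0]), int(g.allele_cn[i, 1])
            if c_r + c_a == 0:
                continue
            key = (c_r, c_a)
            if key in groups:
                groups[key] = groups[key] + resp[:, col]
            else:
                groups[key] = resp[:, col].copy()
        for (c_r, c_a), pooled in groups.items():
            c = c_r + c_a
            w = pooled * obs  # cells with no reads carry no information
            wsum = float(w.sum())
            if wsum <= 0:
                continue
            logwt, amplified, mat = workspace.allelic_term_stack(
                i, c_r, c_a, float(mu_prev[i])
            )
            joint = mat + logwt[:, None]
            post = np.exp(joint - logsumexp(joint, axis=0)[None, :])
            e_amp = amplified @ post  # (cells,)
            namp += float(w @ e_amp)
            ndrop += float(w @ (c - e_amp))
            mcounts[c] = mcounts.get(c, 0.0) + wsum
        if ndrop + namp <= 0:
            continue  # variant absent / unobserved: keep previous value
        mu[i] = _map_dropout_update(
            ndrop, namp, mcounts, alpha, beta,
            params.dropout_renormalize, float(mu_prev[i]),
        )
    return pi, mu


def fit_em(
    tree: EventTree,
    data: PanelData,
    params: ModelParams,
    max_iter: int = 200,
    tol: float = 1e-4,
    pi0: Optional[np.ndarray] = None,
    mu0: Optional[np.ndarray] = None,
    rho: Optional[np.ndarray] = None,
    doublets: bool = False,
    workspace: Optional[LikelihoodWorkspace] = None,
    monotone_slack: float = 1e-6,
) -> EMState:
    """Alternate E and M steps until the log posterior improves by < tol.

    Initialisation: uniform node weights and dropout rates at the prior
    centre (0.05 by default), unless warm-start values are supplied.
    """
    ws = workspace or LikelihoodWorkspace(data, params)
    n_nodes = tree.n_nodes
    pi = np.full(n_nodes, 1.0 / n_nodes) if pi0 is None else np.asarray(pi0, float)
    pi = np.clip(pi, 1e-12, None)
    pi = pi / pi.sum()
    if mu0 is None:
        mu = np.full(data.n_variants, params.dropout_prior_mean)
    else:
        mu = np.clip(np.asarray(mu0, float), MU_MIN, MU_MAX)
    alpha, beta = params.dropout_prior_alpha, params.dropout_prior_beta

    trace: list[float] = []
    resp = None
    att = None
    pairs = None
    n_iter = max(1, max_iter)
    for it in range(n_iter):
        resp, att, loglik = e_step(
            tree, data, params, pi, mu, rho=rho, doublets=doublets, workspace=ws
        )
        pairs = att.pairs
        lp = loglik + _mu_log_prior(mu, alpha, beta)
        if np.isnan(lp):
            raise EMError("NaN log posterior")
        if trace and lp < trace[-1] - monotone_slack:
            raise EMError(
                f"log posterior decreased: {trace[-1]:.6f} -> {lp:.6f}"
            )
        converged = bool(trace) and (lp - trace[-1] < tol)
        trace.append(lp)
        if converged or it == n_iter - 1:
            break
        pi, mu = m_step(resp, tree, data, params, mu, ws, pairs=pairs)

    state = EMState(
        responsibilities=resp, pi=pi, mu=mu, log_post=trace,
        pairs=pairs, attachments=att,
    )
    state._alpha, state._beta = alpha, beta
    return state
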