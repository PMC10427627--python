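"""Two-phase simulated-annealing search over event trees.

Phase 1 searches CNA-free trees (SNV placements and topology only).  Its
fitted attachments identify root-attached cells as non-neoplastic, from which
the region weights ``rho`` are estimated, and regions whose normalised depth
at some node departs from the root's are selected as candidates for gains
and losses.  Phase 2 restarts from the phase-1 optimum with copy-number
moves enabled: gain/loss proposals are restricted to the candidate regions,
while CNLOH (which leaves read depth untouched and is driven purely by
allelic imbalance) may be proposed on any usable variant-bearing region.

Each proposed tree is scored by a short warm-started EM fit of the node
weights and dropout rates; the annealed Metropolis rule accepts with
probability ``min{1, exp((logpost' - logpost)/T + log Hastings ratio)}``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .data_model import ModelParams, PanelData
from .em import EMState, fit_em
from .likelihood import LikelihoodWorkspace
from .prior import PriorPenalties, tree_log_prior
from .tree import (
    ALT,
    CNLOH,
    GAIN,
    LOSS,
    REF,
    SNV,
    Event,
    EventTree,
    validate_tree,
)

logger = logging.getLogger(__name__)

MOVE_NAMES = (
    "prune_reattach",
    "swap_events",
    "move_snv",
    "split_merge",
    "add_remove_cna",
    "toggle_allele",
)
DEFAULT_MOVE_WEIGHTS = (0.25, 0.1, 0.25, 0.2, 0.15, 0.05)


@dataclass
class InferenceConfig:
    """Search-budget and model-selection settings."""

    n_chains: int = 1
    iterations_phase1: int = 2000
    iterations_phase2: int = 2000
    t_init: float = 8.0
    t_final: float = 1.0
    seed: int = 0
    doublets_enabled: bool = False
    candidate_depth_ratio_threshold: float = 0.2
    min_region_depth_fraction: float = 0.1  # relative to the uniform share
    root_weight_floor: float = 0.01
    penalties: PriorPenalties = field(default_factory=PriorPenalties)
    em_max_iter_search: int = 2
    em_tol_search: float = 0.1
    em_max_iter_final: int = 200
    em_tol_final: float = 1e-4
    move_weights: tuple[float, ...] = DEFAULT_MOVE_WEIGHTS

    def __post_init__(self) -> None:
        if not (self.t_init >= self.t_final > 0):
            raise ValueError("require t_init >= t_final > 0")
        if self.iterations_phase1 <= 0 or self.iterations_phase2 <= 0:
            raise ValueError("iteration counts must be positive")


@dataclass
class InferenceResult:
    best_tree: EventTree
    pi: np.ndarray
    mu: np.ndarray
    log_post: float
    responsibilities: np.ndarray
    candidate_regions: set[int]
    rho: np.ndarray
    diagnostics: dict


# ---------------------------------------------------------------------------
# initial tree
# ---------------------------------------------------------------------------


def prufer_to_parent(seq: Sequence[int], n_nodes: int) -> list[Optional[int]]:
    """Decode a Pruefer sequence into a parent vector rooted at node 0."""
    if n_nodes == 2:
        return [None, 0]
    g = nx.from_prufer_sequence([int(s) for s in seq])
    parent: list[Optional[int]] = [None] * n_nodes
    for child, par in nx.bfs_predecessors(g, 0):
        parent[int(child)] = int(par)
    return parent


def initial_tree(n_variants: int, rng: np.random.Generator,
                 n_nodes: Optional[int] = None) -> EventTree:
    """Random CNA-free starting tree.

    Node count drawn uniformly in [3, 10] (capped at n_variants + 1), the
    topology decoded from a random Pruefer sequence, and every SNV assigned
    to a uniformly random node.
    """
    if n_variants < 1:
        raise ValueError("need at least one variant")
    cap = n_variants + 1
    if n_nodes is None:
        lo, hi = min(3, cap), min(10, cap)
        n_nodes = int(rng.integers(lo, hi + 1))
    n_nodes = max(2, min(n_nodes, cap))
    seq = rng.integers(0, n_nodes, size=max(0, n_nodes - 2))
    parent = prufer_to_parent(seq, n_nodes)
    events: list[list[Event]] = [[] for _ in range(n_nodes)]
    for i in range(n_variants):
        node = int(rng.integers(0, n_nodes))
        events[node].append(Event(SNV, i))
    return EventTree(parent, events)


# ---------------------------------------------------------------------------
# proposal moves
# ---------------------------------------------------------------------------


def _is_valid(tree: EventTree, data: PanelData) -> bool:
    return not validate_tree(
        tree, data.n_variants, data.n_regions, data.variant_region
    )


def _prune_reattach(tree: EventTree, data: PanelData, rng, **kw):
    n = tree.n_nodes
    if n < 3:
        return None
    u = int(rng.integers(1, n))
    sub = tree.subtree(u)
    candidates = [v for v in range(n) if v not in sub]
    if not candidates:
        return None
    v = candidates[int(rng.integers(0, len(candidates)))]
    new = tree.copy()
    new.parent[u] = v
    # the subtree of u is unchanged, so the reverse move has the same number
    # of choices: the proposal is symmetric
    return new, 0.0


def _swap_events(tree: EventTree, data: PanelData, rng, **kw):
    n = tree.n_nodes
    if n < 2:
        return None
    a, b = rng.choice(n, size=2, replace=False)
    new = tree.copy()
    new.events[a], new.events[b] = new.events[b], new.events[a]
    new.canonicalize()
    return new, 0.0


def _move_snv(tree: EventTree, data: PanelData, rng, **kw):
    n = tree.n_nodes
    if n < 2 or data.n_variants == 0:
        return None
    i = int(rng.integers(0, data.n_variants))
    cur = tree.snv_node(i)
    targets = [m for m in range(n) if m != cur]
    dest = targets[int(rng.integers(0, len(targets)))]
    new = tree.copy()
    new.events[cur] = [
        ev for ev in new.events[cur] if not (ev.kind == SNV and ev.target == i)
    ]
    new.events[dest].append(Event(SNV, i))
    new.canonicalize()
    return new, 0.0


def _split_merge(tree: EventTree, data: PanelData, rng, **kw):
    # split a node's events onto a new child, or merge a node into its parent;
    # the Hastings ratio of this dimension-changing pair is approximated as 0
    # (the chain is an annealed optimiser, not an exact sampler)
    n = tree.n_nodes
    do_split = bool(rng.integers(0, 2)) if n > 2 else True
    if do_split:
        splittable = [m for m in range(n) if len(tree.events[m]) >= 1]
        if not splittable:
            return None
        u = splittable[int(rng.integers(0, len(splittable)))]
        evs = list(tree.events[u])
        mask = rng.integers(0, 2, size=len(evs)).astype(bool)
        if mask.all():
            mask[int(rng.integers(0, len(evs)))] = False
        moved = [ev for ev, m in zip(evs, mask) if m]
        if not moved:
            return None
        new = tree.copy()
        new_id = n
        new.parent.append(u)
        new.events.append(moved)
        new.events[u] = [ev for ev, m in zip(evs, mask) if not m]
        for c in tree.children(u):
            if rng.integers(0, 2):
                new.parent[c] = new_id
        new.canonicalize()
        return new, 0.0
    # merge: fold a non-root node into its parent
    u = int(rng.integers(1, n))
    p = tree.parent[u]
    parent: list[Optional[int]] = []
    events: list[list[Event]] = []
    remap = {}
    for m in range(n):
        if m == u:
            continue
        remap[m] = len(remap)
    new_parent = []
    new_events = []
    for m in range(n):
        if m == u:
            continue
        pm = tree.parent[m]
        if pm == u:
            pm = p
        new_parent.append(None if pm is None else remap[pm])
        new_events.append(list(tree.events[m]))
    new_events[remap[p]] = new_events[remap[p]] + list(tree.events[u])
    new = EventTree(new_parent, new_events)
    return new, 0.0


def _cna_add_logq(tree_after: EventTree, event: Event, node: int,
                  n_choices: dict) -> float:
    """log q of drawing this specific add-CNA proposal (kind, region, node,
    allele choices), under the fixed 1/3 kind probability."""
    lq = -np.log(3.0)
    lq -= np.log(n_choices["regions"])
    lq -= np.log(n_choices["nodes"])
    lq -= len(event.alleles) * np.log(2.0)
    return lq


def _add_remove_cna(tree: EventTree, data: PanelData, rng, *,
                    candidate_regions: set[int],
                    usable_regions: set[int], **kw):
    n = tree.n_nodes
    existing = tree.cna_events()
    variant_regions = {int(k) for k in np.unique(data.variant_region)}
    cnloh_regions = sorted(variant_regions & usable_regions)
    gl_regions = sorted(candidate_regions & usable_regions)
    can_add = n > 1 and (gl_regions or cnloh_regions)
    can_remove = bool(existing)
    if not can_add and not can_remove:
        return None
    do_add = bool(rng.integers(0, 2)) if (can_add and can_remove) else can_add
    half = np.log(0.5)

    if do_add:
        kind = (GAIN, LOSS, CNLOH)[int(rng.integers(0, 3))]
        pool = cnloh_regions if kind == CNLOH else gl_regions
        if not pool:
            return None
        k = pool[int(rng.integers(0, len(pool)))]
        node = int(rng.integers(1, n))
        alleles = tuple(
            (i, (REF, ALT)[int(rng.integers(0, 2))])
            for i in data.variants_in_region(k)
        )
        ev = Event(kind, k, alleles)
        new = tree.copy()
        new.events[node].append(ev)
        new.canonicalize()
        n_choices = {"regions": len(pool), "nodes": n - 1}
        lq_fwd = half + _cna_add_logq(new, ev, node, n_choices)
        lq_rev = half - np.log(len(existing) + 1)
        return new, float(lq_rev - lq_fwd)

    idx = int(rng.integers(0, len(existing)))
    node, ev = existing[idx]
    new = tree.copy()
    new.events[node] = [e for e in new.events[node] if e != ev]
    pool = cnloh_regions if ev.kind == CNLOH else gl_regions
    n_choices = {"regions": max(1, len(pool)), "nodes": max(1, n - 1)}
    lq_fwd = half - np.log(len(existing))
    lq_rev = half + _cna_add_logq(tree, ev, node, n_choices)
    return new, float(lq_rev - lq_fwd)


def _toggle_allele(tree: EventTree, data: PanelData, rng, **kw):
    pairs = [
        (node, ev, i)
        for node, ev in tree.cna_events()
        for i, _ in ev.alleles
    ]
    if not pairs:
        return None
    node, ev, i = pairs[int(rng.integers(0, len(pairs)))]
    flipped = tuple(
        (v, (ALT if a == REF else REF) if v == i else a) for v, a in ev.alleles
    )
    new = tree.copy()
    new.events[node] = [
        Event(ev.kind, ev.target, flipped) if e == ev else e
        for e in new.events[node]
    ]
    new.canonicalize()
    return new, 0.0


_MOVES = {
    "prune_reattach": _prune_reattach,
    "swap_events": _swap_events,
    "move_snv": _move_snv,
    "split_merge": _split_merge,
    "add_remove_cna": _add_remove_cna,
    "toggle_allele": _toggle_allele,
}


def propose(
    tree: EventTree,
    data: PanelData,
    rng: np.random.Generator,
    allow_cnas: bool = True,
    candidate_regions: Optional[set[int]] = None,
    usable_regions: Optional[set[int]] = None,
    move_weights: Sequence[float] = DEFAULT_MOVE_WEIGHTS,
    max_tries: int = 20,
) -> tuple[EventTree, float, str]:
    """Draw a valid neighbouring tree.

    Returns (new tree, log Hastings ratio, move name).  Invalid draws are
    resampled up to ``max_tries``, then the move type is redrawn; if
    everything fails the current tree is returned unchanged.
    """
    if candidate_regions is None:
        candidate_regions = set(range(data.n_regions))
    if usable_regions is None:
        usable_regions = {
            k for k in range(data.n_regions) if data.regions[k].usable_for_cna
        }
    names = list(MOVE_NAMES)
    weights = np.asarray(move_weights, dtype=float)
    if not allow_cnas:
        keep = [i for i, nm in enumerate(names)
                if nm not in ("add_remove_cna", "toggle_allele")]
        names = [names[i] for i in keep]
        weights = weights[keep]
    weights = weights / weights.sum()

    for _ in range(10):
        name = names[int(rng.choice(len(names), p=weights))]
        fn = _MOVES[name]
        for _ in range(max_tries):
            out = fn(
                tree, data, rng,
                candidate_regions=candidate_regions,
                usable_regions=usable_regions,
            )
            if out is None:
                break
            new, logq = out
            if _is_valid(new, data):
                return new, logq, name
    return tree.copy(), 0.0, "noop"


# ---------------------------------------------------------------------------
# region weights and candidate regions
# ---------------------------------------------------------------------------


def default_region_weights(data: PanelData) -> np.ndarray:
    """Amplicon-count-proportional prior weights."""
    w = np.array([r.n_amplicons for r in data.regions], dtype=float)
    return w / w.sum()


def estimate_region_weights(
    tree_no_cna: EventTree,
    state: EMState,
    data: PanelData,
    root_weight_floor: float = 0.01,
) -> np.ndarray:
    """rho_k from the cells attached to the root (non-neoplastic cells).

    When fewer than ``root_weight_floor`` of the cells sit at the root, all
    cells are used instead (in a CNA-free tree every genotype is diploid in
    region space, so depth fractions estimate rho regardless of attachment).
    """
    if data.n_cells == 0:
        raise ValueError("no cells")
    q_root = state.responsibilities[:, 0]
    if q_root.sum() < root_weight_floor * data.n_cells:
        q_root = np.ones(data.n_cells)
    num = q_root @ data.region_depth.astype(float)
    den = float(q_root @ data.cell_total.astype(float))
    rho = num / den
    return rho / rho.sum()


def select_candidate_regions(
    tree_no_cna: EventTree,
    state: EMState,
    data: PanelData,
    rho: np.ndarray,
    threshold: float = 0.2,
    min_region_depth_fraction: float = 0.1,
    root_weight_floor: float = 0.01,
) -> set[int]:
    """Regions whose responsibility-weighted normalised depth at some
    sufficiently populated node departs from the root's by more than
    ``threshold`` (ratio outside [1 - t, 1 + t]).

    Regions with relative weight below ``min_region_depth_fraction`` (times
    the uniform share 1/n_regions) or flagged unusable are never selected.
    """
    n_nodes = tree_no_cna.n_nodes
    resp = state.responsibilities[:, :n_nodes]
    depth_frac = data.region_depth / np.maximum(
        data.cell_total[:, None].astype(float), 1.0
    )
    norm = depth_frac / rho[None, :]  # (cells, regions)
    node_mass = resp.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        node_means = (resp.T @ norm) / node_mass[:, None]  # (nodes, regions)
    if node_mass[0] >= root_weight_floor * data.n_cells:
        baseline = node_means[0]
    else:
        baseline = (state.responsibilities[:, :n_nodes].sum(axis=1) @ norm) / data.n_cells
    floor = min_region_depth_fraction / data.n_regions
    selected: set[int] = set()
    for k in range(data.n_regions):
        if rho[k] < floor or not data.regions[k].usable_for_cna:
            continue
        if baseline[k] <= 0:
            continue
        for node in range(1, n_nodes):
            if node_mass[node] < root_weight_floor * data.n_cells:
                continue
            ratio = node_means[node, k] / baseline[k]
            if not (1.0 - threshold <= ratio <= 1.0 + threshold):
                selected.add(k)
                break
    return selected


# ---------------------------------------------------------------------------
# annealing
# ---------------------------------------------------------------------------


def _temperature(it: int, total: int, t_init: float, t_final: float) -> float:
    if total <= 1:
        return t_final
    frac = it / (total - 1)
    return float(t_init * (t_final / t_init) ** frac)


def _tree_complexity(tree: EventTree) -> tuple:
    events = tuple(
        tuple((ev.kind, ev.target, ev.alleles) for ev in evs)
        for evs in tree.events
    )
    return (tree.n_nodes, len(tree.cna_events()), events)


def anneal(
    data: PanelData,
    config: InferenceConfig,
    params: ModelParams,
    rng: np.random.Generator,
    allow_cnas: bool,
    candidate_regions: Optional[set[int]] = None,
    rho: Optional[np.ndarray] = None,
    init_tree: Optional[EventTree] = None,
    iterations: Optional[int] = None,
    workspace: Optional[LikelihoodWorkspace] = None,
) -> tuple[EventTree, EMState, float, dict]:
    """One annealing chain; returns the best-posterior tree ever visited."""
    if rho is None:
        rho = default_region_weights(data)
    if iterations is None:
        iterations = (
            config.iterations_phase2 if allow_cnas else config.iterations_phase1
        )
    ws = workspace or LikelihoodWorkspace(data, params)
    doublets = config.doublets_enabled

    tree = init_tree.copy() if init_tree is not None else initial_tree(
        data.n_variants, rng
    )
    violations = validate_tree(
        tree, data.n_variants, data.n_regions, data.variant_region
    )
    if violations:
        raise ValueError(f"invalid initial tree: {violations}")

    def score(t: EventTree, pi0=None, mu0=None) -> tuple[EMState, float]:
        st = fit_em(
            t, data, params,
            max_iter=config.em_max_iter_search, tol=config.em_tol_search,
            pi0=pi0, mu0=mu0, rho=rho, doublets=doublets, workspace=ws,
        )
        lp = st.log_post[-1] + tree_log_prior(t, data, config.penalties)
        return st, lp

    state, log_post = score(tree)
    best = (tree.copy(), state, log_post, _tree_complexity(tree))
    n_accept = 0
    trace = [log_post]

    for it in range(iterations):
        T = _temperature(it, iterations, config.t_init, config.t_final)
        new, logq, move = propose(
            tree, data, rng,
            allow_cnas=allow_cnas,
            candidate_regions=candidate_regions,
            move_weights=config.move_weights,
        )
        if move == "noop":
            continue
        pi0 = state.pi if new.n_nodes == tree.n_nodes else None
        new_state, new_lp = score(new, pi0=pi0, mu0=state.mu)
        if np.log(rng.uniform()) < (new_lp - log_post) / T + logq:
            tree, state, log_post = new, new_state, new_lp
            n_accept += 1
            cx = _tree_complexity(tree)
            if (log_post > best[2] + 1e-9) or (
                abs(log_post - best[2]) <= 1e-9 and cx < best[3]
            ):
                best = (tree.copy(), state, log_post, cx)
        if (it + 1) % 50 == 0:
            trace.append(log_post)

    best_tree, best_state, best_lp, _ = best
    # final refit at the full EM budget
    final_state = fit_em(
        best_tree, data, params,
        max_iter=config.em_max_iter_final, tol=config.em_tol_final,
        pi0=best_state.pi, mu0=best_state.mu,
        rho=rho, doublets=doublets, workspace=ws,
    )
    best_lp = final_state.log_post[-1] + tree_log_prior(
        best_tree, data, config.penalties
    )
    diagnostics = {
        "acceptance_rate": n_accept / max(1, iterations),
        "log_post_trace": trace,
        "iterations": iterations,
    }
    return best_tree, final_state, best_lp, diagnostics


def infer(
    data: PanelData,
    config: InferenceConfig,
    params: Optional[ModelParams] = None,
) -> InferenceResult:
    """Full two-phase inference.

    Phase 1 (CNA-free) -> region-weight estimation and candidate-region
    selection -> phase 2 (CNAs restricted to candidates) -> final EM refit.
    Deterministic given (data, config.seed).
    """
    params = params or ModelParams()
    rng = np.random.default_rng(config.seed)
    ws = LikelihoodWorkspace(data, params)
    rho0 = default_region_weights(data)

    def best_of_chains(allow_cnas, candidate_regions, rho, init_tree, iterations):
        best = None
        for chain in range(config.n_chains):
            chain_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
            out = anneal(
                data, config, params, chain_rng,
                allow_cnas=allow_cnas,
                candidate_regions=candidate_regions,
                rho=rho, init_tree=init_tree, iterations=iterations,
                workspace=ws,
            )
            if best is None or out[2] > best[2]:
                best = out
        return best

    tree1, state1, lp1, diag1 = best_of_chains(
        False, None, rho0, None, config.iterations_phase1
    )
    rho = estimate_region_weights(
        tree1, state1, data, root_weight_floor=config.root_weight_floor
    )
    candidates = select_candidate_regions(
        tree1, state1, data, rho,
        threshold=config.candidate_depth_ratio_threshold,
        min_region_depth_fraction=config.min_region_depth_fraction,
        root_weight_floor=config.root_weight_floor,
    )
    tree2, state2, lp2, diag2 = best_of_chains(
        True, candidates, rho, tree1, config.iterations_phase2
    )
    logger.info(
        "phase 1 log-post %.2f; %d candidate region(s); phase 2 log-post %.2f",
        lp1, len(candidates), lp2,
    )
    return InferenceResult(
        best_tree=tree2,
        pi=state2.pi,
        mu=state2.mu,
        log_post=lp2,
        responsibilities=state2.responsibilities,
        candidate_regions=candidates,
        rho=rho,
        diagnostics={
            "phase1": diag1, "phase2": diag2,
            "phase1_log_post": lp1, "phase2_log_post": lp2,
            "seed": config.seed,
        },
    )
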