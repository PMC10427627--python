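"""Scoring inferred trees against ground truth, and the exact 2x2 test.

Inferred nodes are matched to true nodes by genotype similarity (Hamming
distance over per-variant allele copy-number pairs plus region copy
numbers); cell-assignment accuracy, SNV placement accuracy and CNA false
positive / false negative rates (stratified by whether the true CNA is
supported by an SNV or LOH at or below its node) are computed through that
mapping.  CNA calls are identified by (region, kind).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import contingency, fisher_exact

from .simulate import GroundTruth
from .tree import CNA_KINDS, CNLOH, LOSS, SNV, EventTree, all_genotypes


@dataclass
class EvalReport:
    cell_assignment_accuracy: float
    cna_fpr: float
    cna_fnr: float
    cna_fnr_supported: Optional[float]
    cna_fnr_unsupported: Optional[float]
    snv_placement_accuracy: float
    node_mapping: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cell_assignment_accuracy": self.cell_assignment_accuracy,
            "cna_fpr": self.cna_fpr,
            "cna_fnr": self.cna_fnr,
            "cna_fnr_supported": self.cna_fnr_supported,
            "cna_fnr_unsupported": self.cna_fnr_unsupported,
            "snv_placement_accuracy": self.snv_placement_accuracy,
            "node_mapping": {str(k): v for k, v in self.node_mapping.items()},
        }


# ---------------------------------------------------------------------------
# node mapping and cell-level metrics
# ---------------------------------------------------------------------------


def map_nodes_by_genotype(
    inferred: EventTree,
    truth: EventTree,
    n_variants: int,
    n_regions: int,
    variant_region,
) -> dict[int, int]:
    """Each inferred node maps to the true node with the most similar
    genotype; ties break toward the smaller true node id."""
    gi = all_genotypes(inferred, n_variants, n_regions, variant_region)
    gt = all_genotypes(truth, n_variants, n_regions, variant_region)
    mapping = {}
    for n, g in enumerate(gi):
        best, best_d = 0, None
        for m, h in enumerate(gt):
            d = int(np.sum(g.allele_cn != h.allele_cn)) + int(
                np.sum(g.region_cn != h.region_cn)
            )
            if best_d is None or d < best_d:
                best, best_d = m, d
        mapping[n] = best
    return mapping


def cell_assignment_accuracy(
    inferred_attachments: np.ndarray,
    truth: GroundTruth,
    node_map: dict[int, int],
) -> float:
    """Fraction of singlet cells whose MAP inferred node maps to their true
    node (doublets are excluded from the metric)."""
    mask = truth.singlet_mask()
    inferred = np.asarray(inferred_attachments)[mask]
    true_nodes = truth.singlet_nodes()
    mapped = np.array([node_map[int(n)] for n in inferred])
    return float(np.mean(mapped == true_nodes))


def map_attachments(responsibilities: np.ndarray, n_nodes: int) -> np.ndarray:
    """MAP node per cell from the responsibility matrix; doublet columns (if
    any) are folded into their first member for reporting purposes."""
    return np.asarray(responsibilities[:, :n_nodes]).argmax(axis=1)


def snv_placement_accuracy(
    inferred: EventTree, truth: EventTree, node_map: dict[int, int]
) -> float:
    """Fraction of SNVs whose inferred node maps to the true node."""
    truth_nodes = {ev.target: n for n, ev in truth.snv_events()}
    hits = 0
    total = 0
    for n, ev in inferred.snv_events():
        total += 1
        if node_map[n] == truth_nodes.get(ev.target, -1):
            hits += 1
    return hits / total if total else 1.0


# ---------------------------------------------------------------------------
# CNA call metrics
# ---------------------------------------------------------------------------


def classify_cna_support(
    tree: EventTree,
    n_variants: int,
    n_regions: int,
    variant_region,
) -> dict[tuple[int, int], bool]:
    """Per-CNA flag: supported iff the CNA's node or any descendant contains
    an SNV event or an LOH-producing event.

    Keys are (node, event index within the node's CNA list order).
    """
    genos = all_genotypes(tree, n_variants, n_regions, variant_region)
    from .tree import root_genotype

    def is_loh(node: int, ev) -> bool:
        if ev.kind == CNLOH:
            return True
        if ev.kind != LOSS:
            return False
        p = tree.parent[node]
        pre = root_genotype(n_variants, n_regions) if p is None else genos[p]
        for i, a in ev.alleles:
            col = 0 if a == "ref" else 1
            if pre.allele_cn[i, col] >= 1 and pre.allele_cn[i, 1 - col] >= 1:
                # losing the last copy of a previously present allele
                if pre.allele_cn[i, col] == 1:
                    return True
        return False

    node_has_support = [False] * tree.n_nodes
    for node in range(tree.n_nodes):
        for ev in tree.events[node]:
            if ev.kind == SNV or (ev.is_cna and is_loh(node, ev)):
                node_has_support[node] = True

    out = {}
    for node, ev in tree.cna_events():
        sub = tree.subtree(node)
        supported = any(node_has_support[m] for m in sub)
        idx = [e for e in tree.events[node] if e.is_cna].index(ev)
        out[(node, idx)] = supported
    return out


def _cna_labels(tree: EventTree) -> set[tuple[int, str]]:
    return {(ev.target, ev.kind) for _, ev in tree.cna_events()}


def cna_calls_fpr_fnr(
    inferred: EventTree,
    truth: EventTree,
    n_regions: int,
    n_variants: int = 0,
    variant_region=None,
) -> tuple[float, float, dict]:
    """FPR and FNR of CNA calls labelled by (region, kind).

    FNR = missed true CNAs / true CNAs; FPR = spurious calls /
    (regions x kinds - true CNAs).  The FNR is additionally stratified by
    whether the true CNA is supported by an SNV or LOH (computed on the true
    tree).
    """
    if variant_region is None:
        variant_region = np.zeros(n_variants, dtype=int)
    true_labels = _cna_labels(truth)
    inf_labels = _cna_labels(inferred)
    n_true = len(true_labels)
    missed = true_labels - inf_labels
    spurious = inf_labels - true_labels
    denom_fp = n_regions * len(CNA_KINDS) - n_true
    fpr = len(spurious) / denom_fp if denom_fp > 0 else 0.0
    fnr = len(missed) / n_true if n_true > 0 else 0.0

    support = classify_cna_support(truth, n_variants, n_regions, variant_region)
    by_label: dict[tuple[int, str], bool] = {}
    for (node, idx), flag in support.items():
        cna_list = [e for e in truth.events[node] if e.is_cna]
        ev = cna_list[idx]
        by_label[(ev.target, ev.kind)] = flag or by_label.get(
            (ev.target, ev.kind), False
        )
    strat = {}
    for name, flag in (("supported", True), ("unsupported", False)):
        labels = {lab for lab, s in by_label.items() if s == flag}
        if labels:
            strat[f"fnr_{name}"] = len(labels & missed) / len(labels)
        else:
            strat[f"fnr_{name}"] = None
    strat["n_true"] = n_true
    strat["n_spurious"] = len(spurious)
    strat["n_missed"] = len(missed)
    return fpr, fnr, strat


def evaluate_inference(
    result_tree: EventTree,
    responsibilities: np.ndarray,
    truth: GroundTruth,
) -> EvalReport:
    """Full evaluation of one inference run against its ground truth."""
    n_variants = len(truth.variants)
    n_regions = len(truth.regions)
    variant_region = np.array([v.region for v in truth.variants])
    node_map = map_nodes_by_genotype(
        result_tree, truth.tree, n_variants, n_regions, variant_region
    )
    map_nodes = map_attachments(responsibilities, result_tree.n_nodes)
    acc = cell_assignment_accuracy(map_nodes, truth, node_map)
    fpr, fnr, strat = cna_calls_fpr_fnr(
        result_tree, truth.tree, n_regions, n_variants, variant_region
    )
    snv_acc = snv_placement_accuracy(result_tree, truth.tree, node_map)
    return EvalReport(
        cell_assignment_accuracy=acc,
        cna_fpr=fpr,
        cna_fnr=fnr,
        cna_fnr_supported=strat["fnr_supported"],
        cna_fnr_unsupported=strat["fnr_unsupported"],
        snv_placement_accuracy=snv_acc,
        node_mapping=node_map,
    )


# ---------------------------------------------------------------------------
# exact 2x2 association
# ---------------------------------------------------------------------------


def exact_2x2_association(table) -> tuple[float, float, float]:
    """One-sided Fisher exact test for positive association in a 2x2 table.

    Returns (one-sided p, conditional-MLE odds ratio, one-sided 95% CI lower
    bound).  The odds ratio is the conditional maximum-likelihood estimate
    under the noncentral hypergeometric model and the CI bound inverts the
    exact test.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a non-negative 2x2 count matrix")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    p = float(fisher_exact(t, alternative="greater")[1])
    res = contingency.odds_ratio(t, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95, alternative="greater")
    return p, float(res.statistic), float(ci.low)
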