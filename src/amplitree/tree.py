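"""Event trees and derived genotypes.

A tumour's somatic history is represented as a rooted tree whose nodes carry
ordered sets of events: SNVs and allele-specific copy-number alterations
(gain, loss, copy-neutral LOH).  Each node implies a genotype obtained by
applying the events on the root-to-node path to the wild-type diploid genome.

Combinatorial constraints:

* an SNV is acquired exactly once in the tree (losses happen implicitly
  through allele-specific copy events, i.e. a Dollo-style model);
* a region carries at most one CNA per lineage (root-to-leaf path);
* a CNA may only affect an allele that is present in the node's pre-event
  genotype;
* region copy numbers are confined to {0, 1, 2, 3}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

SNV = "SNV"
GAIN = "GAIN"
LOSS = "LOSS"
CNLOH = "CNLOH"

CNA_KINDS = (GAIN, LOSS, CNLOH)
EVENT_KINDS = (SNV,) + CNA_KINDS

REF = "ref"
ALT = "alt"

MAX_REGION_CN = 3


class TreeError(ValueError):
    """Raised when an operation is attempted on an invalid tree."""


@dataclass(frozen=True, order=True)
class Event:
    """One somatic event.

    ``target`` is a variant index for SNVs and a region index for CNAs.
    For CNAs on variant-bearing regions, ``alleles`` maps each variant in the
    region to the affected allele: the allele removed (loss), duplicated
    (gain) or replaced by the other allele (CNLOH).  Variant-free regions use
    an empty ``alleles`` tuple.
    """

    kind: str
    target: int
    alleles: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == SNV and self.alleles:
            raise ValueError("SNV events carry no allele choices")
        for _, a in self.alleles:
            if a not in (REF, ALT):
                raise ValueError(f"allele must be 'ref' or 'alt', got {a!r}")

    @property
    def is_cna(self) -> bool:
        return self.kind != SNV

    def allele_of(self, variant: int) -> Optional[str]:
        for v, a in self.alleles:
            if v == variant:
                return a
        return None


def _sort_key(ev: Event) -> tuple:
    # SNVs first, then CNAs; ties broken by target then kind.  This makes
    # co-located "SNV + CNA in the same node" well defined: the point
    # mutation is acquired before the copy event.
    return (ev.is_cna, ev.target, ev.kind, ev.alleles)


@dataclass
class Genotype:
    """Per-node derived state.

    ``region_cn[k]`` is the total copy number of region ``k`` (float to allow
    the averaged copy numbers of doublet genotypes); ``allele_cn[i]`` is the
    (reference, alternative) copy-number pair of variant ``i``.
    """

    region_cn: np.ndarray
    allele_cn: np.ndarray

    def copy(self) -> "Genotype":
        return Genotype(self.region_cn.copy(), self.allele_cn.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genotype):
            return NotImplemented
        return np.array_equal(self.region_cn, other.region_cn) and np.array_equal(
            self.allele_cn, other.allele_cn
        )


def root_genotype(n_variants: int, n_regions: int) -> Genotype:
    """Wild-type diploid state: every region at copy number 2, every variant
    (2, 0).  Variants whose SNV event sits at the root (germline SNPs) become
    (1, 1) at the root once the root's events are applied."""
    region_cn = np.full(n_regions, 2, dtype=np.int64)
    allele_cn = np.zeros((n_variants, 2), dtype=np.int64)
    allele_cn[:, 0] = 2
    return Genotype(region_cn, allele_cn)


@dataclass
class EventTree:
    """Rooted tree of somatic events.  Node 0 is the root."""

    parent: list[Optional[int]]
    events: list[list[Event]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.events:
            self.events = [[] for _ in self.parent]
        self.canonicalize()

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def canonicalize(self) -> None:
        """Sort each node's events into the canonical application order."""
        self.events = [sorted(evs, key=_sort_key) for evs in self.events]

    def copy(self) -> "EventTree":
        return EventTree(list(self.parent), [list(evs) for evs in self.events])

    def children(self, node: int) -> list[int]:
        return [i for i, p in enumerate(self.parent) if p == node]

    def root_path(self, node: int) -> list[int]:
        """Nodes from the root down to ``node`` inclusive."""
        path = []
        cur: Optional[int] = node
        seen = set()
        while cur is not None:
            if cur in seen:
                raise TreeError("parent vector contains a cycle")
            seen.add(cur)
            path.append(cur)
            cur = self.parent[cur]
        return path[::-1]

    def subtree(self, node: int) -> set[int]:
        out = {node}
        stack = [node]
        while stack:
            for c in self.children(stack.pop()):
                out.add(c)
                stack.append(c)
        return out

    def dfs_preorder(self) -> Iterator[int]:
        stack = [0]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(sorted(self.children(n), reverse=True))

    def snv_node(self, variant: int) -> Optional[int]:
        for n, evs in enumerate(self.events):
            for ev in evs:
                if ev.kind == SNV and ev.target == variant:
                    return n
        return None

    def cna_events(self) -> list[tuple[int, Event]]:
        """All (node, event) pairs for copy-number events."""
        return [
            (n, ev)
            for n, evs in enumerate(self.events)
            for ev in evs
            if ev.is_cna
        ]

    def snv_events(self) -> list[tuple[int, Event]]:
        return [
            (n, ev)
            for n, evs in enumerate(self.events)
            for ev in evs
            if ev.kind == SNV
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventTree):
            return NotImplemented
        return self.parent == other.parent and self.events == other.events


def apply_event(
    genotype: Genotype,
    event: Event,
    variant_region: Sequence[int],
) -> None:
    """Apply ``event`` to ``genotype`` in place.

    Raises :class:`TreeError` when the event is inapplicable (affected allele
    absent, copy-number cap exceeded, SNV on a ref-free background...).
    """
    g = genotype
    if event.kind == SNV:
        i = event.target
        if g.allele_cn[i, 0] < 1:
            raise TreeError(f"SNV on variant {i}: no reference copy to mutate")
        g.allele_cn[i, 0] -= 1
        g.allele_cn[i, 1] += 1
        return

    k = event.target
    variants = [i for i, _ in event.alleles]
    if event.kind == GAIN:
        if g.region_cn[k] + 1 > MAX_REGION_CN:
            raise TreeError(f"gain on region {k}: copy number cap exceeded")
        g.region_cn[k] += 1
        for i, a in event.alleles:
            col = 0 if a == REF else 1
            if g.allele_cn[i, col] < 1:
                raise TreeError(
                    f"gain of {a} allele of variant {i}: allele absent"
                )
            g.allele_cn[i, col] += 1
    elif event.kind == LOSS:
        if g.region_cn[k] - 1 < 1:
            raise TreeError(f"loss on region {k}: copy number would reach 0")
        g.region_cn[k] -= 1
        for i, a in event.alleles:
            col = 0 if a == REF else 1
            if g.allele_cn[i, col] < 1:
                raise TreeError(
                    f"loss of {a} allele of variant {i}: allele absent"
                )
            g.allele_cn[i, col] -= 1
    elif event.kind == CNLOH:
        if not event.alleles:
            raise TreeError(
                f"CNLOH on region {k}: no variant in region, event has no "
                "observable effect"
            )
        for i, a in event.alleles:
            col = 0 if a == REF else 1
            other = 1 - col
            if g.allele_cn[i, col] < 1:
                raise TreeError(
                    f"CNLOH replacing {a} allele of variant {i}: allele absent"
                )
            # full replacement: all copies of the affected allele switch to
            # the other allele, total copy number preserved
            g.allele_cn[i, other] += g.allele_cn[i, col]
            g.allele_cn[i, col] = 0
    else:  # pragma: no cover
        raise TreeError(f"unknown event kind {event.kind!r}")


def node_genotype(
    tree: EventTree,
    node: int,
    n_variants: int,
    n_regions: int,
    variant_region: Sequence[int],
) -> Genotype:
    """Genotype implied by the root-to-``node`` event path."""
    g = root_genotype(n_variants, n_regions)
    for n in tree.root_path(node):
        for ev in sorted(tree.events[n], key=_sort_key):
            apply_event(g, ev, variant_region)
    return g


def all_genotypes(
    tree: EventTree,
    n_variants: int,
    n_regions: int,
    variant_region: Sequence[int],
) -> list[Genotype]:
    """Genotypes for all nodes, computed incrementally down the tree."""
    genos: list[Optional[Genotype]] = [None] * tree.n_nodes
    order = list(tree.dfs_preorder())
    for n in order:
        p = tree.parent[n]
        g = root_genotype(n_variants, n_regions) if p is None else genos[p].copy()
        for ev in sorted(tree.events[n], key=_sort_key):
            apply_event(g, ev, variant_region)
        genos[n] = g
    return genos  # type: ignore[return-value]


def doublet_genotype(g1: Genotype, g2: Genotype) -> Genotype:
    """Genotype of a doublet: allele copy numbers add, region copy numbers
    average (so region copy numbers may be non-integer)."""
    return Genotype(
        (g1.region_cn + g2.region_cn) / 2.0,
        g1.allele_cn + g2.allele_cn,
    )


def validate_tree(
    tree: EventTree,
    n_variants: int,
    n_regions: int,
    variant_region: Sequence[int],
) -> list[str]:
    """Check all tree invariants; returns a list of violation messages
    (empty iff the tree is valid)."""
    violations: list[str] = []

    # -- structure
    if tree.n_nodes == 0:
        return ["tree has no nodes"]
    if tree.parent[0] is not None:
        violations.append("node 0 must be the root (parent None)")
    for n, p in enumerate(tree.parent):
        if n == 0:
            continue
        if p is None:
            violations.append(f"node {n}: multiple roots")
        elif not (0 <= p < tree.n_nodes):
            violations.append(f"node {n}: parent {p} out of range")
    # connectivity / acyclicity
    try:
        reached = tree.subtree(0)
    except RecursionError:  # pragma: no cover
        reached = set()
    if len(reached) != tree.n_nodes:
        violations.append("parent vector is not a connected rooted tree")
        return violations

    # -- SNV multiplicity
    placements: dict[int, list[int]] = {}
    for n, ev in tree.snv_events():
        placements.setdefault(ev.target, []).append(n)
    for i, nodes in placements.items():
        if len(nodes) > 1:
            violations.append(
                f"SNV multiplicity: variant {i} placed in nodes {sorted(nodes)}"
            )
        if not (0 <= i < n_variants):
            violations.append(f"SNV on unknown variant {i}")
    for i in range(n_variants):
        if i not in placements:
            violations.append(f"SNV missing: variant {i} not placed in the tree")

    # -- event targets and allele declarations
    for n, ev in tree.cna_events():
        k = ev.target
        if not (0 <= k < n_regions):
            violations.append(f"CNA on unknown region {k}")
            continue
        region_vars = {i for i in range(n_variants) if variant_region[i] == k}
        declared = {i for i, _ in ev.alleles}
        if declared != region_vars:
            violations.append(
                f"CNA on region {k} at node {n}: allele choices declared for "
                f"variants {sorted(declared)}, region contains {sorted(region_vars)}"
            )
        if ev.kind == CNLOH and not region_vars:
            violations.append(
                f"CNA on region {k} at node {n}: CNLOH on a variant-free "
                "region has no observable effect"
            )

    # -- per-lineage CNA uniqueness
    def check_lineage(node: int, seen: dict[int, int]) -> None:
        local = dict(seen)
        for ev in tree.events[node]:
            if ev.is_cna:
                if ev.target in local:
                    violations.append(
                        f"CNA per lineage: region {ev.target} altered at node "
                        f"{local[ev.target]} and again at node {node}"
                    )
                local[ev.target] = node
        for c in tree.children(node):
            check_lineage(c, local)

    check_lineage(0, {})

    # -- allele availability / copy caps, by replaying events down the tree
    def check_genotypes(node: int, geno: Genotype) -> None:
        g = geno.copy()
        for ev in sorted(tree.events[node], key=_sort_key):
            try:
                apply_event(g, ev, variant_region)
            except TreeError as exc:
                violations.append(f"allele absent / cap at node {node}: {exc}")
        for c in tree.children(node):
            check_genotypes(c, g)

    check_genotypes(0, root_genotype(n_variants, n_regions))

    return violations


def relabel_nodes(tree: EventTree, perm: Sequence[int]) -> EventTree:
    """Return a tree with node ``n`` renamed to ``perm[n]`` (perm[0] must be
    0 so the root stays the root)."""
    if perm[0] != 0:
        raise TreeError("root must keep label 0")
    n = tree.n_nodes
    parent: list[Optional[int]] = [None] * n
    events: list[list[Event]] = [[] for _ in range(n)]
    for old in range(n):
        new = perm[old]
        p = tree.parent[old]
        parent[new] = None if p is None else perm[p]
        events[new] = list(tree.events[old])
    return EventTree(parent, events)
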