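"""Tree log-prior: node/CNA penalties and germline-placement penalties.

The prior (up to an additive constant) is

    -p1 * n_muts * n_nodes
    -(1500 + n_cells) * p2 * (n_CNA_LOH + n_CNA_no_LOH / 2)
    -sum_{locus i not at the root} (p3 + p4 * pop_freq(i))

where CNA events of the same kind on genomically contiguous regions within
one node are merged and counted once (large CNAs often span whole
chromosomes), and a merged event counts as LOH if any constituent drives
some allele of some variant to zero copies (or is a CNLOH).  ``p2`` is the
main knob controlling how readily CNAs are added.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data_model import PanelData, RegionMeta
from .tree import CNLOH, EventTree, all_genotypes


@dataclass
class PriorPenalties:
    p1: float = 0.1
    p2: float = 0.01
    p3: float = 3.0
    p4: float = 20.0

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3", "p4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _event_is_loh(event, pre_genotype) -> bool:
    """True if the event drives some previously present allele of some
    variant to zero copies."""
    if event.kind == CNLOH:
        return True
    for i, a in event.alleles:
        col = 0 if a == "ref" else 1
        before = pre_genotype.allele_cn[i, col]
        if event.kind == "LOSS" and before == 1:
            return True
    return False


def count_cna_events(
    tree: EventTree,
    regions: list[RegionMeta],
    n_variants: int,
    variant_region,
) -> tuple[int, int]:
    """(n_CNA_LOH, n_CNA_no_LOH) after merging contiguous same-kind events.

    Contiguity means same chromosome and consecutive ``order_index``; merges
    never span chromosomes or event kinds.
    """
    n_regions = len(regions)
    # genotypes *before* each node's own events = parent genotypes
    genos = all_genotypes(tree, n_variants, n_regions, variant_region)
    from .tree import root_genotype

    n_loh = 0
    n_no_loh = 0
    for node in range(tree.n_nodes):
        p = tree.parent[node]
        pre = root_genotype(n_variants, n_regions) if p is None else genos[p]
        cnas = [ev for ev in tree.events[node] if ev.is_cna]
        # group by (kind, chromosome), sort by genomic order, merge runs
        by_group: dict[tuple[str, str], list] = {}
        for ev in cnas:
            r = regions[ev.target]
            by_group.setdefault((ev.kind, r.chrom), []).append(ev)
        for (_, _), evs in sorted(by_group.items()):
            evs = sorted(evs, key=lambda e: regions[e.target].order_index)
            run: list = []
            prev_order = None
            runs = []
            for ev in evs:
                o = regions[ev.target].order_index
                if prev_order is not None and o == prev_order + 1:
                    run.append(ev)
                else:
                    if run:
                        runs.append(run)
                    run = [ev]
                prev_order = o
            if run:
                runs.append(run)
            for run in runs:
                if any(_event_is_loh(ev, pre) for ev in run):
                    n_loh += 1
                else:
                    n_no_loh += 1
    return n_loh, n_no_loh


def tree_log_prior(
    tree: EventTree,
    data: PanelData,
    penalties: PriorPenalties,
    n_cells: int | None = None,
) -> float:
    """Log-prior of the tree up to an additive constant."""
    if n_cells is None:
        n_cells = data.n_cells
    n_muts = len(tree.snv_events())
    n_nodes = tree.n_nodes
    n_loh, n_no_loh = count_cna_events(
        tree, data.regions, data.n_variants, data.variant_region
    )
    lp = -penalties.p1 * n_muts * n_nodes
    lp -= (1500.0 + n_cells) * penalties.p2 * (n_loh + 0.5 * n_no_loh)
    for node, ev in tree.snv_events():
        if node != 0:
            freq = data.variants[ev.target].pop_freq or 0.0
            lp -= penalties.p3 + penalties.p4 * freq
    return lp
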