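"""Shared fixtures: small hand-built panels and trees."""

import numpy as np
import pytest

from amplitree.data_model import ModelParams, PanelData, RegionMeta, VariantMeta
from amplitree.tree import ALT, CNLOH, GAIN, LOSS, REF, SNV, Event, EventTree


def make_panel(
    n_cells=3,
    n_regions=2,
    n_variants=1,
    variant_region=None,
    rng=None,
    depth=30,
):
    """Small random-but-valid panel for structural tests."""
    rng = rng or np.random.default_rng(0)
    if variant_region is None:
        variant_region = [i % n_regions for i in range(n_variants)]
    region_depth = rng.poisson(depth, size=(n_cells, n_regions)) + 1
    var_depth = np.minimum(
        rng.poisson(depth // 2, size=(n_cells, n_variants)) + 1,
        region_depth[:, variant_region],
    )
    alt = rng.binomial(var_depth, 0.4)
    variants = [
        VariantMeta(id=f"var{i}", region=variant_region[i], chrom="chr1", pos=100 + i)
        for i in range(n_variants)
    ]
    regions = [
        RegionMeta(id=f"gene{k}", chrom="chr1", order_index=k, n_amplicons=2)
        for k in range(n_regions)
    ]
    return PanelData(
        region_depth=region_depth,
        alt_counts=alt,
        var_depth=var_depth,
        cell_ids=[f"c{j}" for j in range(n_cells)],
        variants=variants,
        regions=regions,
    )


@pytest.fixture
def tiny_panel():
    return make_panel(n_cells=3, n_regions=2, n_variants=1)


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def two_node_tree(n_variants=1):
    """Root plus one child carrying all SNVs."""
    return EventTree(
        [None, 0], [[], [Event(SNV, i) for i in range(n_variants)]]
    )


def random_valid_tree(rng, n_variants, n_regions, variant_region, n_nodes=None,
                      p_cna=0.5):
    """Rejection-sample a random valid tree (SNVs everywhere, occasional
    CNAs); used by property tests."""
    from amplitree.inference import prufer_to_parent
    from amplitree.tree import all_genotypes, validate_tree

    n_nodes = n_nodes or int(rng.integers(2, 6))
    while True:
        seq = rng.integers(0, n_nodes, size=max(0, n_nodes - 2))
        parent = prufer_to_parent(seq, n_nodes)
        events = [[] for _ in range(n_nodes)]
        for i in range(n_variants):
            events[int(rng.integers(0, n_nodes))].append(Event(SNV, i))
        tree = EventTree(parent, events)
        # try to add a few CNAs
        n_cna = int(rng.integers(0, 3)) if rng.uniform() < p_cna else 0
        ok = True
        for _ in range(n_cna):
            genos = all_genotypes(tree, n_variants, n_regions, variant_region)
            node = int(rng.integers(1, n_nodes)) if n_nodes > 1 else 0
            k = int(rng.integers(0, n_regions))
            kind = (GAIN, LOSS, CNLOH)[int(rng.integers(0, 3))]
            alleles = []
            feasible = True
            for i in range(n_variants):
                if variant_region[i] != k:
                    continue
                g = genos[node]
                opts = [a for col, a in ((0, REF), (1, ALT))
                        if g.allele_cn[i, col] >= 1]
                if not opts:
                    feasible = False
                    break
                alleles.append((i, opts[int(rng.integers(0, len(opts)))]))
            if not feasible:
                continue
            cand = tree.copy()
            cand.events[node].append(Event(kind, k, tuple(alleles)))
            cand.canonicalize()
            if not validate_tree(cand, n_variants, n_regions, variant_region):
                tree = cand
        if not validate_tree(tree, n_variants, n_regions, variant_region):
            return tree
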