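"""Synthetic targeted single-cell panel data with known ground truth.

The generator mirrors the inference model's generative assumptions and the
characteristic noise structure of microfluidic amplicon panels (Tapestri-
style): clone sizes drawn from a sparse Dirichlet, non-uniform amplicon
efficiencies (log-normal region weights), overdispersed per-region depths
(negative binomial), allele-specific dropout, sequencing error,
beta-binomially overdispersed ALT fractions, optional doublets and optional
block-correlated coverage fluctuations that are independent of the clonal
structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .data_model import PanelData, RegionMeta, VariantMeta
from .inference import prufer_to_parent
from .tree import (
    ALT,
    CNLOH,
    GAIN,
    LOSS,
    REF,
    SNV,
    Event,
    EventTree,
    all_genotypes,
    doublet_genotype,
    validate_tree,
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults follow the reference simulation design for targeted panels:
    3000 cells, 30 regions, 6-node trees, Dirichlet concentration 0.3 for
    the clone sizes (the value estimated from real data), non-uniform
    amplicon coverage.  Doublets and coverage correlations are separate
    stressors, off by default.
    """

    n_cells: int = 3000
    n_regions: int = 30
    n_nodes: int = 6
    n_snvs: int = 7
    n_cnas: int = 3
    node_weight_concentration: float = 0.3
    coverage_mode: str = "nonuniform"  # or "uniform"
    coverage_sigma: float = 1.0  # log-normal spread of amplicon efficiencies
    depth_mean: float = 40.0  # mean reads per region per cell (diploid)
    depth_dispersion: float = 20.0  # inverse dispersion of the total depth
    theta: float = 6.0
    dropout_mean: float = 0.05
    dropout_sd: float = 0.02
    eps: float = 0.01
    omega_hom: float = 50.0
    omega_het: float = 15.0
    doublet_rate: float = 0.0
    coverage_correlation: str = "off"  # or "on"
    correlation_strength: float = 0.3
    fraction_germline_snps: float = 0.3
    cna_support_fraction: float = 0.0  # fraction of CNAs placed without SNV support
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snvs < 1:
            raise ValueError("need at least one SNV")
        if self.n_nodes < 2:
            raise ValueError("need at least two nodes")
        if self.node_weight_concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.coverage_mode not in ("uniform", "nonuniform"):
            raise ValueError("coverage_mode must be 'uniform' or 'nonuniform'")
        if self.coverage_correlation not in ("off", "on"):
            raise ValueError("coverage_correlation must be 'off' or 'on'")


@dataclass
class GroundTruth:
    tree: EventTree
    node_weights: np.ndarray
    attachments: list  # int node id, or (n, n') tuple for doublets
    is_doublet: np.ndarray
    dropout_rates: np.ndarray
    region_weights: np.ndarray
    variants: list[VariantMeta]
    regions: list[RegionMeta]
    correlated_regions: Optional[np.ndarray] = None
    coverage_factor_on: Optional[np.ndarray] = None

    def singlet_mask(self) -> np.ndarray:
        return ~self.is_doublet

    def singlet_nodes(self) -> np.ndarray:
        return np.array(
            [a for a, d in zip(self.attachments, self.is_doublet) if not d],
            dtype=np.int64,
        )


# ---------------------------------------------------------------------------
# panel layout
# ---------------------------------------------------------------------------


def _make_panel(config: SimulationConfig, rng: np.random.Generator):
    """Random gene panel: regions spread over chromosomes with contiguous
    order indices, variants assigned to random regions."""
    n_regions = config.n_regions
    regions: list[RegionMeta] = []
    per_chrom = 3
    for k in range(n_regions):
        chrom = f"chr{1 + k // per_chrom}"
        regions.append(
            RegionMeta(
                id=f"gene{k}",
                chrom=chrom,
                order_index=k % per_chrom,
                n_amplicons=int(rng.integers(1, 4)),
            )
        )
    n_germline = int(round(config.fraction_germline_snps * config.n_snvs))
    n_variants = config.n_snvs + n_germline
    variant_regions = rng.choice(n_regions, size=n_variants, replace=True)
    variants: list[VariantMeta] = []
    for i in range(n_variants):
        k = int(variant_regions[i])
        germline = i >= config.n_snvs
        variants.append(
            VariantMeta(
                id=f"var{i}" if not germline else f"snp{i}",
                region=k,
                chrom=regions[k].chrom,
                pos=int(rng.integers(1, 10_000_000)),
                pop_freq=float(rng.uniform(0.05, 0.5)) if germline else None,
            )
        )
        # variants need an amplicon of their own within the region
        regions[k].n_amplicons = max(
            regions[k].n_amplicons, sum(1 for v in variants if v.region == k)
        )
    return variants, regions


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------


def _supported_nodes(tree: EventTree, variants, variant_region) -> set[int]:
    """Nodes whose own or descendant events include an SNV or an LOH-producing
    event -- a CNA placed there is discoverable from the CNA-free tree."""
    n = tree.n_nodes
    has_local = [False] * n
    for node in range(1, n):
        for ev in tree.events[node]:
            if ev.kind == SNV or ev.kind == CNLOH or (
                ev.kind == LOSS and ev.alleles
            ):
                has_local[node] = True
    supported = set()
    for node in range(1, n):
        if any(has_local[m] for m in tree.subtree(node)):
            supported.add(node)
    return supported


def simulate_tree(
    config: SimulationConfig,
    rng: np.random.Generator,
    variants: Optional[list[VariantMeta]] = None,
    regions: Optional[list[RegionMeta]] = None,
    max_tries: int = 200,
) -> tuple[EventTree, list[VariantMeta], list[RegionMeta]]:
    """Random valid event tree with the configured numbers of SNVs and CNAs.

    Somatic SNVs are spread so every non-root node carries at least one
    event; germline SNPs sit at the root.  CNAs respect per-lineage
    uniqueness, allele availability and (for a configurable fraction) the
    requirement of SNV support (an SNV or LOH at the node or below).
    """
    if variants is None or regions is None:
        variants, regions = _make_panel(config, rng)
    n_nodes = config.n_nodes
    n_somatic = config.n_snvs
    if n_somatic + config.n_cnas < n_nodes - 1:
        raise ValueError(
            "not enough events to give every non-root node at least one"
        )
    variant_region = np.array([v.region for v in variants])
    n_unsupported = int(round(config.cna_support_fraction * config.n_cnas))

    last_err = "no attempt"
    for _ in range(max_tries):
        seq = rng.integers(0, n_nodes, size=max(0, n_nodes - 2))
        parent = prufer_to_parent(seq, n_nodes)
        events: list[list[Event]] = [[] for _ in range(n_nodes)]
        # germline SNPs at the root
        for i, v in enumerate(variants):
            if v.is_candidate_germline:
                events[0].append(Event(SNV, i))
        # somatic SNVs: one per non-root node first, the rest at random
        somatic = [i for i, v in enumerate(variants) if not v.is_candidate_germline]
        rng.shuffle(somatic)
        for j, i in enumerate(somatic):
            if j < n_nodes - 1:
                events[j + 1].append(Event(SNV, i))
            else:
                events[int(rng.integers(1, n_nodes))].append(Event(SNV, i))
        tree = EventTree(parent, events)

        genos = all_genotypes(tree, len(variants), len(regions), variant_region)
        supported = _supported_nodes(tree, variants, variant_region)
        unsupported = set(range(1, n_nodes)) - supported

        ok = True
        used_regions: dict[int, set[int]] = {}
        for c in range(config.n_cnas):
            want_support = c >= n_unsupported
            pool_nodes = sorted(supported if want_support else unsupported)
            placed = False
            for _ in range(50):
                if not pool_nodes:
                    break
                node = pool_nodes[int(rng.integers(0, len(pool_nodes)))]
                kind = (GAIN, LOSS, CNLOH)[int(rng.integers(0, 3))]
                region_pool = [
                    k for k in range(len(regions))
                    if regions[k].usable_for_cna
                    and node not in used_regions.get(k, set())
                ]
                if kind == CNLOH:
                    region_pool = [
                        k for k in region_pool
                        if any(variant_region == k)
                    ]
                if not region_pool:
                    continue
                k = region_pool[int(rng.integers(0, len(region_pool)))]
                g = genos[node]
                alleles = []
                feasible = True
                for i in np.flatnonzero(variant_region == k):
                    opts = []
                    if g.allele_cn[i, 0] >= 1:
                        opts.append(REF)
                    if g.allele_cn[i, 1] >= 1:
                        opts.append(ALT)
                    if not opts:
                        feasible = False
                        break
                    alleles.append((int(i), opts[int(rng.integers(0, len(opts)))]))
                if not feasible:
                    continue
                cand = tree.copy()
                cand.events[node].append(Event(kind, k, tuple(alleles)))
                cand.canonicalize()
                if validate_tree(cand, len(variants), len(regions), variant_region):
                    continue
                # identifiability: every node must keep a distinct genotype
                # (e.g. a CNLOH replacing the ALT allele of a same-node SNV
                # would cancel it, collapsing the node onto its parent)
                cand_genos = all_genotypes(
                    cand, len(variants), len(regions), variant_region
                )
                keys = {
                    (tuple(g.region_cn), g.allele_cn.tobytes())
                    for g in cand_genos
                }
                if len(keys) < cand.n_nodes:
                    continue
                tree = cand
                genos = all_genotypes(
                    tree, len(variants), len(regions), variant_region
                )
                supported = _supported_nodes(tree, variants, variant_region)
                unsupported = set(range(1, n_nodes)) - supported
                for m in tree.subtree(node) | set(tree.root_path(node)):
                    used_regions.setdefault(k, set()).add(m)
                placed = True
                break
            if not placed:
                ok = False
                last_err = f"could not place CNA {c}"
                break
        if not ok:
            continue
        violations = validate_tree(tree, len(variants), len(regions), variant_region)
        if violations:
            last_err = "; ".join(violations)
            continue
        return tree, variants, regions
    raise RuntimeError(f"infeasible event placement: {last_err}")


# ---------------------------------------------------------------------------
# read-count simulation
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Negative binomial with mean/inverse-dispersion parameterisation."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def simulate_cells(
    tree: EventTree,
    config: SimulationConfig,
    rng: np.random.Generator,
    variants: list[VariantMeta],
    regions: list[RegionMeta],
) -> tuple[PanelData, GroundTruth]:
    """Draw read counts for every cell under the generative model."""
    n_cells = config.n_cells
    n_regions = len(regions)
    n_variants = len(variants)
    variant_region = np.array([v.region for v in variants])
    n_nodes = tree.n_nodes

    weights = rng.dirichlet(
        np.full(n_nodes, config.node_weight_concentration)
    )
    genos = all_genotypes(tree, n_variants, n_regions, variant_region)

    # attachments (with doublets)
    is_doublet = rng.uniform(size=n_cells) < config.doublet_rate
    first = rng.choice(n_nodes, size=n_cells, p=weights)
    second = rng.choice(n_nodes, size=n_cells, p=weights)
    attachments: list = []
    cell_genos = []
    for j in range(n_cells):
        if is_doublet[j]:
            attachments.append((int(first[j]), int(second[j])))
            cell_genos.append(doublet_genotype(genos[first[j]], genos[second[j]]))
        else:
            attachments.append(int(first[j]))
            cell_genos.append(genos[first[j]])

    # per-variant dropout rates
    mu = np.clip(
        rng.normal(config.dropout_mean, config.dropout_sd, size=n_variants),
        0.01, 0.5,
    )

    # region weights: amplicon-efficiency model.  In uniform mode every
    # region gets the same weight (fractions exchangeable across regions);
    # in non-uniform mode each amplicon draws its own log-normal efficiency.
    n_amps = np.array([r.n_amplicons for r in regions], dtype=float)
    if config.coverage_mode == "uniform":
        amp_eff = [np.ones(int(a)) / a for a in n_amps]
    else:
        amp_eff = [
            rng.lognormal(0.0, config.coverage_sigma, size=int(a)) for a in n_amps
        ]
    rho = np.array([e.sum() for e in amp_eff])
    rho = rho / rho.sum()

    # optional block-correlated coverage tilt, independent of clones
    tilt = np.ones((n_cells, n_regions))
    correlated_regions = None
    coverage_factor_on = None
    if config.coverage_correlation == "on":
        correlated_regions = np.sort(
            rng.choice(n_regions, size=n_regions // 2, replace=False)
        )
        coverage_factor_on = rng.uniform(size=n_cells) < 0.5
        tilt[np.ix_(coverage_factor_on, correlated_regions)] = (
            1.0 + config.correlation_strength
        )

    # depths
    total = _nb_draw(
        rng,
        np.full(n_cells, config.depth_mean * n_regions),
        config.depth_dispersion,
    ).astype(float)
    total = np.maximum(total, 1.0)
    cn = np.stack([g.region_cn for g in cell_genos])  # (cells, regions) float
    w = cn * rho[None, :] * tilt
    frac = w / w.sum(axis=1, keepdims=True)
    region_depth = _nb_draw(rng, total[:, None] * frac, config.theta)

    # variant depths: multinomial split of the region reads over amplicons;
    # each variant occupies one amplicon of its region
    var_depth = np.zeros((n_cells, n_variants), dtype=np.int64)
    for k in range(n_regions):
        vs = np.flatnonzero(variant_region == k)
        if vs.size == 0:
            continue
        eff = amp_eff[k] / amp_eff[k].sum()
        counts = rng.multinomial(region_depth[:, k], eff)  # (cells, n_amp)
        for slot, i in enumerate(vs):
            var_depth[:, i] = counts[:, slot]

    # ALT counts: dropout + error + beta-binomial
    alt = np.zeros((n_cells, n_variants), dtype=np.int64)
    allele_cn = np.stack([g.allele_cn for g in cell_genos])  # (cells, vars, 2)
    for i in range(n_variants):
        c_r = allele_cn[:, i, 0]
        c_a = allele_cn[:, i, 1]
        k_amp = rng.binomial(c_r, 1.0 - mu[i])
        l_amp = rng.binomial(c_a, 1.0 - mu[i])
        # condition on at least one amplified copy (total dropout excluded)
        redo = (k_amp + l_amp == 0) & (c_r + c_a > 0)
        while redo.any():
            k_amp[redo] = rng.binomial(c_r[redo], 1.0 - mu[i])
            l_amp[redo] = rng.binomial(c_a[redo], 1.0 - mu[i])
            redo = (k_amp + l_amp == 0) & (c_r + c_a > 0)
        tot = np.maximum(k_amp + l_amp, 1)
        f = (l_amp * (1 - config.eps) + k_amp * config.eps) / tot
        omega = np.where(
            (k_amp == 0) | (l_amp == 0), config.omega_hom, config.omega_het
        )
        p = rng.beta(np.maximum(omega * f, 1e-9), np.maximum(omega * (1 - f), 1e-9))
        alt[:, i] = rng.binomial(var_depth[:, i], p)

    data = PanelData(
        region_depth=region_depth.astype(np.int64),
        alt_counts=alt,
        var_depth=var_depth,
        cell_ids=[f"cell{j}" for j in range(n_cells)],
        variants=variants,
        regions=regions,
    )
    truth = GroundTruth(
        tree=tree,
        node_weights=weights,
        attachments=attachments,
        is_doublet=is_doublet,
        dropout_rates=mu,
        region_weights=rho,
        variants=variants,
        regions=regions,
        correlated_regions=correlated_regions,
        coverage_factor_on=coverage_factor_on,
    )
    return data, truth


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[PanelData, GroundTruth]:
    """Tree + cells in one call, seeded from the config."""
    rng = np.random.default_rng(config.seed)
    tree, variants, regions = simulate_tree(config, rng)
    return simulate_cells(tree, config, rng, variants, regions)


# ---------------------------------------------------------------------------
# ground-truth serialisation
# ---------------------------------------------------------------------------


def write_ground_truth(truth: GroundTruth, path) -> None:
    from .data_model import tree_to_dict

    payload = {
        "tree": tree_to_dict(
            truth.tree, truth.node_weights, truth.variants, truth.regions
        ),
        "node_weights": truth.node_weights.tolist(),
        "attachments": [
            list(a) if isinstance(a, tuple) else a for a in truth.attachments
        ],
        "is_doublet": truth.is_doublet.astype(int).tolist(),
        "dropout_rates": truth.dropout_rates.tolist(),
        "region_weights": truth.region_weights.tolist(),
    }
    Path(path).write_text(json.dumps(payload) + "\n")


def read_ground_truth(path, variants, regions) -> GroundTruth:
    from .data_model import tree_from_dict

    payload = json.loads(Path(path).read_text())
    tree, pi = tree_from_dict(payload["tree"])
    return GroundTruth(
        tree=tree,
        node_weights=np.array(payload["node_weights"]),
        attachments=[
            tuple(a) if isinstance(a, list) else int(a)
            for a in payload["attachments"]
        ],
        is_doublet=np.array(payload["is_doublet"], dtype=bool),
        dropout_rates=np.array(payload["dropout_rates"]),
        region_weights=np.array(payload["region_weights"]),
        variants=variants,
        regions=regions,
    )
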