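"""Core data containers and delimited-file I/O.

The canonical input is a set of plain delimited matrices (CSV or TSV,
inferred from the extension): a cells x regions matrix of total read counts,
a cells x variants pair of REF/ALT count matrices (one file, two columns per
variant named ``<variant>:ref`` / ``<variant>:alt``), and variant / region
metadata tables.  Trees are serialised to JSON (lossless) and GraphViz DOT
(for rendering); cell attachments to a delimited table.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .tree import SNV, Event, EventTree

logger = logging.getLogger(__name__)


class PanelDataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class VariantMeta:
    id: str
    region: int
    chrom: str
    pos: int
    pop_freq: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pop_freq is not None and not (0.0 <= self.pop_freq <= 1.0):
            raise PanelDataError(
                f"variant {self.id}: pop_freq {self.pop_freq} outside [0, 1]"
            )

    @property
    def is_candidate_germline(self) -> bool:
        return self.pop_freq is not None


@dataclass
class RegionMeta:
    id: str
    chrom: str
    order_index: int
    n_amplicons: int = 1
    usable_for_cna: bool = True

    def __post_init__(self) -> None:
        if self.n_amplicons < 1:
            raise PanelDataError(
                f"region {self.id}: n_amplicons must be >= 1, got {self.n_amplicons}"
            )


@dataclass
class ModelParams:
    """Noise and nuisance parameters of the read-count model.

    theta           inverse dispersion of the negative-binomial depth model
                    (variance = m + m^2/theta)
    eps             sequencing error rate
    omega_hom/het   beta-binomial concentrations for single-allele and
                    two-allele amplified states
    dropout_rates   per-variant allelic dropout rates mu_i
    dropout_prior_* beta prior on mu_i, parameterised directly as (alpha,
                    beta); defaults (2, 38) give a prior centred on mean
                    0.05 with total strength alpha + beta = 40
    doublet_rate    prior probability delta that a cell is a doublet
    region_weights  probability rho_k for a read to fall in region k in a
                    CNA-free diploid cell
    dropout_renormalize
                    if True (default) the allelic likelihood, whose dropout
                    sum excludes total dropout (k, l) = (0, 0), is
                    renormalised by 1 - mu^(c_r + c_a); if False the literal
                    (unnormalised) sum is used
    """

    theta: float = 6.0
    eps: float = 0.01
    omega_hom: float = 50.0
    omega_het: float = 15.0
    dropout_rates: Optional[np.ndarray] = None
    dropout_prior_alpha: float = 2.0
    dropout_prior_beta: float = 38.0
    doublet_rate: float = 0.05
    region_weights: Optional[np.ndarray] = None
    dropout_renormalize: bool = True

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if not (0.0 < self.eps < 0.5):
            raise ValueError("eps must lie in (0, 0.5)")
        if self.omega_hom <= 0 or self.omega_het <= 0:
            raise ValueError("beta-binomial concentrations must be positive")
        if not (0.0 <= self.doublet_rate < 1.0):
            raise ValueError("doublet_rate must lie in [0, 1)")
        if self.dropout_prior_alpha <= 0 or self.dropout_prior_beta <= 0:
            raise ValueError("dropout prior parameters must be positive")
        if self.region_weights is not None:
            rho = np.asarray(self.region_weights, dtype=float)
            if abs(rho.sum() - 1.0) > 1e-9:
                raise ValueError("region_weights must sum to 1")
            self.region_weights = rho
        if self.dropout_rates is not None:
            mu = np.asarray(self.dropout_rates, dtype=float)
            if np.any(mu <= 0) or np.any(mu >= 1):
                raise ValueError("dropout rates must lie in (0, 1)")
            self.dropout_rates = mu

    @property
    def dropout_prior_mean(self) -> float:
        """Mean of the beta prior on the dropout rates."""
        return self.dropout_prior_alpha / (
            self.dropout_prior_alpha + self.dropout_prior_beta
        )


@dataclass
class PanelData:
    """Per-cell read counts over a targeted panel.

    region_depth  D_kj, integer matrix [n_cells x n_regions]
    alt_counts    A_ij, integer matrix [n_cells x n_variants]
    var_depth     D_ij, integer matrix [n_cells x n_variants]
    """

    region_depth: np.ndarray
    alt_counts: np.ndarray
    var_depth: np.ndarray
    cell_ids: list[str]
    variants: list[VariantMeta]
    regions: list[RegionMeta]
    cell_total: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.region_depth = np.asarray(self.region_depth, dtype=np.int64)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int64)
        self.var_depth = np.asarray(self.var_depth, dtype=np.int64)
        self.validate()
        self.cell_total = self.region_depth.sum(axis=1)

    # -- derived views -----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.region_depth.shape[0]

    @property
    def n_regions(self) -> int:
        return self.region_depth.shape[1]

    @property
    def n_variants(self) -> int:
        return self.var_depth.shape[1]

    @property
    def variant_region(self) -> np.ndarray:
        return np.array([v.region for v in self.variants], dtype=np.int64)

    def variants_in_region(self, k: int) -> list[int]:
        return [i for i, v in enumerate(self.variants) if v.region == k]

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        n_cells, n_regions = self.region_depth.shape
        if len(self.cell_ids) != n_cells:
            raise PanelDataError(
                f"{len(self.cell_ids)} cell ids for {n_cells} depth rows"
            )
        if len(self.regions) != n_regions:
            raise PanelDataError(
                f"{len(self.regions)} region records for {n_regions} columns"
            )
        if self.var_depth.shape != self.alt_counts.shape:
            raise PanelDataError("var_depth and alt_counts shapes differ")
        if self.var_depth.shape[0] != n_cells:
            raise PanelDataError(
                f"variant matrix has {self.var_depth.shape[0]} cells, "
                f"region matrix has {n_cells}"
            )
        if len(self.variants) != self.var_depth.shape[1]:
            raise PanelDataError(
                f"{len(self.variants)} variant records for "
                f"{self.var_depth.shape[1]} columns"
            )
        for mat, name in (
            (self.region_depth, "region_depth"),
            (self.alt_counts, "alt_counts"),
            (self.var_depth, "var_depth"),
        ):
            if np.any(mat < 0):
                j, i = np.argwhere(mat < 0)[0]
                raise PanelDataError(
                    f"negative count in {name} at cell {self.cell_ids[j]}, "
                    f"column {i}"
                )
        bad = np.argwhere(self.alt_counts > self.var_depth)
        if bad.size:
            j, i = bad[0]
            raise PanelDataError(
                f"ALT count exceeds depth for cell {self.cell_ids[j]}, "
                f"variant {self.variants[i].id}"
            )
        for v in self.variants:
            if not (0 <= v.region < n_regions):
                raise PanelDataError(
                    f"variant {v.id} references unknown region index {v.region}"
                )
        seen: dict[tuple[str, int], str] = {}
        for r in self.regions:
            key = (r.chrom, r.order_index)
            if key in seen:
                raise PanelDataError(
                    f"regions {seen[key]} and {r.id} share order_index "
                    f"{r.order_index} on {r.chrom}"
                )
            seen[key] = r.id

    def drop_empty_cells(self) -> "PanelData":
        """Remove cells with zero total reads (their depth likelihood is
        undefined).  Returns self if nothing to drop."""
        keep = self.region_depth.sum(axis=1) > 0
        if keep.all():
            return self
        dropped = [c for c, k in zip(self.cell_ids, keep) if not k]
        logger.warning(
            "dropping %d cell(s) with zero total reads: %s",
            len(dropped),
            ", ".join(dropped[:10]),
        )
        return PanelData(
            region_depth=self.region_depth[keep],
            alt_counts=self.alt_counts[keep],
            var_depth=self.var_depth[keep],
            cell_ids=[c for c, k in zip(self.cell_ids, keep) if k],
            variants=self.variants,
            regions=self.regions,
        )


# ---------------------------------------------------------------------------
# delimited-matrix I/O
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in (".tsv", ".tab", ".txt") else ","


def _read_table(path: Path, index_col: Optional[int] = 0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise PanelDataError(f"file not found: {path}")
    return pd.read_csv(path, sep=_sep_for(path), index_col=index_col)


def _check_integer_matrix(df: pd.DataFrame, name: str) -> np.ndarray:
    arr = df.to_numpy()
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        flt = arr.astype(float)
        if np.any(~np.isfinite(flt)) or np.any(flt != np.round(flt)):
            bad = np.argwhere((~np.isfinite(flt)) | (flt != np.round(flt)))[0]
            raise PanelDataError(
                f"{name}: non-integer count at cell {df.index[bad[0]]}, "
                f"column {df.columns[bad[1]]}"
            )
        arr = flt.astype(np.int64)
    return arr.astype(np.int64)


def load_panel_data(
    region_counts_path,
    variant_counts_path,
    variant_meta_path,
    region_meta_path,
    drop_empty_cells: bool = True,
) -> PanelData:
    """Read and validate the four canonical input files.

    Cells must be identical (same ids, same order not required) between the
    region-count and variant-count matrices; a mismatch is rejected.
    """
    region_df = _read_table(region_counts_path)
    var_df = _read_table(variant_counts_path)

    rcells, vcells = set(region_df.index), set(var_df.index)
    if rcells != vcells:
        missing = sorted(rcells ^ vcells)
        raise PanelDataError(
            "cells differ between region and variant matrices; "
            f"unmatched: {', '.join(str(c) for c in missing[:10])}"
        )
    var_df = var_df.loc[region_df.index]

    # variant columns come in ':ref'/':alt' pairs
    names: list[str] = []
    for col in var_df.columns:
        if col.endswith(":ref"):
            base = col[:-4]
            if f"{base}:alt" not in var_df.columns:
                raise PanelDataError(f"variant {base}: missing ':alt' column")
            names.append(base)
        elif not col.endswith(":alt"):
            raise PanelDataError(
                f"variant count column {col!r} must end in ':ref' or ':alt'"
            )

    vmeta_df = _read_table(variant_meta_path, index_col=None)
    rmeta_df = _read_table(region_meta_path, index_col=None)

    regions = [
        RegionMeta(
            id=str(row["id"]),
            chrom=str(row["chrom"]),
            order_index=int(row["order_index"]),
            n_amplicons=int(row.get("n_amplicons", 1)),
            usable_for_cna=bool(row.get("usable_for_cna", True)),
        )
        for _, row in rmeta_df.iterrows()
    ]
    region_index = {r.id: k for k, r in enumerate(regions)}
    region_cols = [str(c) for c in region_df.columns]
    if set(region_cols) != set(region_index):
        raise PanelDataError(
            "region metadata does not match region count columns: "
            f"{sorted(set(region_cols) ^ set(region_index))}"
        )
    # order columns to match metadata
    region_df = region_df[[r.id for r in regions]]

    variants = []
    for _, row in vmeta_df.iterrows():
        rid = str(row["region"])
        if rid not in region_index:
            raise PanelDataError(
                f"variant {row['id']} references unknown region {rid!r}"
            )
        pf = row.get("pop_freq")
        pf = None if pf is None or (isinstance(pf, float) and math.isnan(pf)) else float(pf)
        variants.append(
            VariantMeta(
                id=str(row["id"]),
                region=region_index[rid],
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                pop_freq=pf,
            )
        )
    meta_names = [v.id for v in variants]
    if set(meta_names) != set(names):
        raise PanelDataError(
            "variant metadata does not match variant count columns: "
            f"{sorted(set(meta_names) ^ set(names))}"
        )

    ref = _check_integer_matrix(var_df[[f"{v}:ref" for v in meta_names]], "REF counts")
    alt = _check_integer_matrix(var_df[[f"{v}:alt" for v in meta_names]], "ALT counts")
    depth = _check_integer_matrix(region_df, "region counts")

    data = PanelData(
        region_depth=depth,
        alt_counts=alt,
        var_depth=ref + alt,
        cell_ids=[str(c) for c in region_df.index],
        variants=variants,
        regions=regions,
    )
    return data.drop_empty_cells() if drop_empty_cells else data


def write_panel_data(data: PanelData, out_dir, prefix: str = "panel") -> dict[str, Path]:
    """Write the four canonical files; inverse of :func:`load_panel_data`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "region_counts": out / f"{prefix}_region_counts.csv",
        "variant_counts": out / f"{prefix}_variant_counts.csv",
        "variant_meta": out / f"{prefix}_variant_meta.csv",
        "region_meta": out / f"{prefix}_region_meta.csv",
    }
    pd.DataFrame(
        data.region_depth,
        index=pd.Index(data.cell_ids, name="cell"),
        columns=[r.id for r in data.regions],
    ).to_csv(paths["region_counts"])
    cols: dict[str, np.ndarray] = {}
    for i, v in enumerate(data.variants):
        cols[f"{v.id}:ref"] = data.var_depth[:, i] - data.alt_counts[:, i]
        cols[f"{v.id}:alt"] = data.alt_counts[:, i]
    pd.DataFrame(cols, index=pd.Index(data.cell_ids, name="cell")).to_csv(
        paths["variant_counts"]
    )
    pd.DataFrame(
        {
            "id": [v.id for v in data.variants],
            "region": [data.regions[v.region].id for v in data.variants],
            "chrom": [v.chrom for v in data.variants],
            "pos": [v.pos for v in data.variants],
            "pop_freq": [v.pop_freq for v in data.variants],
        }
    ).to_csv(paths["variant_meta"], index=False)
    pd.DataFrame(
        {
            "id": [r.id for r in data.regions],
            "chrom": [r.chrom for r in data.regions],
            "order_index": [r.order_index for r in data.regions],
            "n_amplicons": [r.n_amplicons for r in data.regions],
            "usable_for_cna": [r.usable_for_cna for r in data.regions],
        }
    ).to_csv(paths["region_meta"], index=False)
    return paths


# ---------------------------------------------------------------------------
# tree serialisation
# ---------------------------------------------------------------------------


def tree_to_dict(
    tree: EventTree,
    pi: Optional[Sequence[float]] = None,
    variants: Optional[list[VariantMeta]] = None,
    regions: Optional[list[RegionMeta]] = None,
) -> dict:
    def label(ev: Event) -> Optional[str]:
        if ev.kind == SNV:
            return variants[ev.target].id if variants else None
        return regions[ev.target].id if regions else None

    nodes = []
    for n in range(tree.n_nodes):
        events = []
        for ev in tree.events[n]:
            d: dict = {"kind": ev.kind, "target": int(ev.target)}
            if (lab := label(ev)) is not None:
                d["label"] = lab
            if ev.is_cna:
                d["alleles"] = [[int(i), a] for i, a in ev.alleles]
            events.append(d)
        p = tree.parent[n]
        node = {
            "id": n,
            "parent": None if p is None else int(p),
            "events": events,
        }
        if pi is not None:
            node["weight"] = float(pi[n])
        nodes.append(node)
    return {"nodes": nodes}


def tree_from_dict(d: dict) -> tuple[EventTree, Optional[np.ndarray]]:
    nodes = sorted(d["nodes"], key=lambda x: x["id"])
    parent: list[Optional[int]] = []
    events: list[list[Event]] = []
    weights = []
    for node in nodes:
        parent.append(node["parent"])
        evs = []
        for e in node["events"]:
            alleles = tuple(
                (int(i), str(a)) for i, a in e.get("alleles", [])
            )
            evs.append(Event(kind=e["kind"], target=int(e["target"]), alleles=alleles))
        events.append(evs)
        weights.append(node.get("weight"))
    pi = None
    if all(w is not None for w in weights):
        pi = np.array(weights, dtype=float)
    return EventTree(parent, events), pi


def _dot_escape(s: str) -> str:
    return s.replace('"', r"\"")


def tree_to_dot(
    tree: EventTree,
    pi: Optional[Sequence[float]] = None,
    variants: Optional[list[VariantMeta]] = None,
    regions: Optional[list[RegionMeta]] = None,
) -> str:
    lines = ["digraph tree {", "  node [shape=box];"]
    for n in range(tree.n_nodes):
        parts = []
        for ev in tree.events[n]:
            if ev.kind == SNV:
                name = variants[ev.target].id if variants else f"v{ev.target}"
                parts.append(name)
            else:
                name = regions[ev.target].id if regions else f"r{ev.target}"
                parts.append(f"{ev.kind} {name}")
        label = "\\n".join(parts) if parts else ("root" if n == 0 else "")
        if pi is not None:
            label += f"\\n{100 * float(pi[n]):.1f}%"
        lines.append(f'  n{n} [label="{_dot_escape(label)}"];')
    for n, p in enumerate(tree.parent):
        if p is not None:
            lines.append(f"  n{p} -> n{n};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_tree(
    tree: EventTree,
    pi: Optional[Sequence[float]],
    path,
    format: str = "json",
    variants: Optional[list[VariantMeta]] = None,
    regions: Optional[list[RegionMeta]] = None,
) -> None:
    path = Path(path)
    if pi is not None and len(pi) != tree.n_nodes:
        raise ValueError("pi length does not match number of nodes")
    if format == "json":
        path.write_text(
            json.dumps(tree_to_dict(tree, pi, variants, regions), indent=1) + "\n"
        )
    elif format == "dot":
        path.write_text(tree_to_dot(tree, pi, variants, regions))
    else:
        raise ValueError(f"unknown tree format {format!r}")


def load_tree(path) -> tuple[EventTree, Optional[np.ndarray]]:
    return tree_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# attachment (responsibility) serialisation
# ---------------------------------------------------------------------------


def write_assignments(
    responsibilities: np.ndarray,
    path,
    cell_ids: Optional[Sequence[str]] = None,
    attachment_labels: Optional[Sequence[str]] = None,
) -> None:
    """One row per cell: MAP attachment plus the full posterior."""
    resp = np.asarray(responsibilities, dtype=float)
    sums = resp.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        j = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(
            f"responsibility row {j} sums to {sums[j]:.8f}, expected 1"
        )
    n_cells, n_att = resp.shape
    if cell_ids is None:
        cell_ids = [f"cell{j}" for j in range(n_cells)]
    if attachment_labels is None:
        attachment_labels = [f"att{n}" for n in range(n_att)]
    df = pd.DataFrame(resp, index=pd.Index(cell_ids, name="cell"),
                      columns=list(attachment_labels))
    df.insert(0, "map_attachment", [attachment_labels[i] for i in resp.argmax(axis=1)])
    df.to_csv(Path(path))


def read_assignments(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), index_col=0)
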