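"""File formats and the differential-network workflow.

Expression matrices are delimited text with a header of identifiers
(samples-by-genes or genes-by-samples).  Networks travel as TSV edge
lists with a fixed column set; run configuration is embedded as leading
``#`` comment lines so every output records how it was produced.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .data import ExpressionMatrix
from .graphs import WeightedGraph
from .pipeline import _EDGE_COLUMNS, GeneNetwork

__all__ = [
    "read_expression",
    "write_expression",
    "read_edge_list",
    "write_edge_list",
    "write_sif",
    "read_prior_network",
    "write_prior_network",
    "top_fraction_edges",
    "hub_genes",
    "DiffNetReport",
    "differential_network",
]


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if "\t" in line else ","
    return "\t"


def read_expression(path, orientation: str = "samples-by-genes") -> ExpressionMatrix:
    """Read a delimited expression matrix with one header of identifiers.

    ``orientation='genes-by-samples'`` transposes the file.  Missing or
    non-numeric cells raise an error naming the offending row/column.
    """
    path = Path(path)
    if orientation not in ("samples-by-genes", "genes-by-samples"):
        raise ValueError("orientation must be samples-by-genes or genes-by-samples")
    sep = _sniff_sep(path)
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = [c.strip() for c in line.rstrip("\n").split(sep)][1:]
                break
        else:
            raise ValueError(f"empty expression file {path}")
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    if orientation == "samples-by-genes" and len(header) != len(set(header)):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate gene identifiers in {path}: {dupes}")
    if orientation == "genes-by-samples":
        df = df.T
        if df.columns.duplicated().any():
            dupes = sorted(set(df.columns[df.columns.duplicated()]))
            raise ValueError(f"duplicate gene identifiers in {path}: {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = next(zip(*np.where(numeric.isna().to_numpy())))
        raise ValueError(
            f"missing or non-numeric value in {path} at sample {df.index[r]!r}, "
            f"gene {df.columns[c]!r}"
        )
    return ExpressionMatrix.from_dataframe(numeric)


def write_expression(X: ExpressionMatrix, path, sep: str = "\t") -> None:
    X.to_dataframe().to_csv(path, sep=sep, float_format="%.12g")


def _config_header(config: RunConfig | dict | None) -> str:
    if config is None:
        return ""
    items = config.to_dict() if isinstance(config, RunConfig) else dict(config)
    lines = [f"# {k} = {v}" for k, v in items.items() if not k.startswith("_")]
    return "\n".join(lines) + "\n" if lines else ""


def write_edge_list(net: GeneNetwork, path, config: RunConfig | dict | None = None) -> None:
    """TSV edge list with the resolved run configuration as '#' comments."""
    meta = {k: v for k, v in net.metadata.items() if not k.startswith("_")}
    header = _config_header(config) + _config_header(meta)
    buf = _io.StringIO()
    net.edges.to_csv(buf, sep="\t", index=False, float_format="%.12g")
    Path(path).write_text(header + buf.getvalue())


def read_edge_list(path) -> GeneNetwork:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"edge list {path} lacks columns: {missing}")
    df["regulator"] = df["regulator"].astype(str)
    df["target"] = df["target"].astype(str)
    genes = tuple(sorted(set(df["regulator"]) | set(df["target"])))
    return GeneNetwork(edges=df[_EDGE_COLUMNS], gene_ids=genes, metadata={})


def write_sif(net: GeneNetwork, path) -> None:
    """SIF export: regulator activates|represses target, by weight sign."""
    lines = [
        f"{r.regulator}\t{'activates' if r.weight > 0 else 'represses'}\t{r.target}"
        for r in net.edges.itertuples()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_prior_network(path) -> WeightedGraph:
    """Undirected prior network: 3-column edge list or square matrix text."""
    path = Path(path)
    sep = _sniff_sep(path)
    mat = pd.read_csv(path, sep=sep, comment="#", index_col=0)
    is_matrix = (
        mat.shape[0] == mat.shape[1]
        and set(map(str, mat.index)) == set(map(str, mat.columns))
    )
    if is_matrix:
        mat = mat.loc[list(mat.columns)]  # align row order to columns
        return WeightedGraph(
            gene_ids=tuple(map(str, mat.columns)),
            weights=np.abs(mat.to_numpy(dtype=float)),
        )
    df = pd.read_csv(path, sep=sep, comment="#",
                     names=["gene_a", "gene_b", "weight"], header=0)
    genes = sorted(set(df["gene_a"].astype(str)) | set(df["gene_b"].astype(str)))
    idx = {g: i for i, g in enumerate(genes)}
    W = np.zeros((len(genes), len(genes)))
    for r in df.itertuples():
        i, j = idx[str(r.gene_a)], idx[str(r.gene_b)]
        W[i, j] = W[j, i] = abs(float(r.weight))
    return WeightedGraph(gene_ids=tuple(genes), weights=W)


def write_prior_network(g: WeightedGraph, path) -> None:
    rows = []
    ids = g.gene_ids
    W = g.weights
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if W[i, j] != 0:
                rows.append(f"{ids[i]}\t{ids[j]}\t{W[i, j]:.12g}")
    Path(path).write_text("gene_a\tgene_b\tweight\n" + "\n".join(rows) + ("\n" if rows else ""))


def top_fraction_edges(net: GeneNetwork, fraction: float) -> GeneNetwork:
    """Keep the ceil(fraction * E) edges of largest |weight|, ties included."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    E = len(net.edges)
    if E == 0:
        return GeneNetwork(edges=net.edges.copy(), gene_ids=net.gene_ids,
                           metadata=dict(net.metadata))
    k = max(1, min(E, int(np.ceil(fraction * E))))
    weights = net.edges["weight"].abs().to_numpy()
    cutoff = np.sort(weights)[::-1][k - 1]
    keep = weights >= cutoff
    return GeneNetwork(
        edges=net.edges.loc[keep].reset_index(drop=True),
        gene_ids=net.gene_ids,
        metadata={**{k_: v for k_, v in net.metadata.items()}, "top_fraction": fraction},
    )


def hub_genes(net: GeneNetwork, k: int = 10) -> pd.DataFrame:
    """Genes ranked by total degree (in + out) in the selected network."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if len(net.edges) == 0:
        return pd.DataFrame(columns=["gene", "degree"])
    counts = (
        pd.concat([net.edges["regulator"], net.edges["target"]])
        .value_counts()
        .rename_axis("gene")
        .reset_index(name="degree")
    )
    counts = counts.sort_values(["degree", "gene"], ascending=[False, True])
    return counts.head(k).reset_index(drop=True)


@dataclass
class DiffNetReport:
    """Edge-set comparison of two condition-specific networks."""

    common_edges: pd.DataFrame
    a_specific_edges: pd.DataFrame
    b_specific_edges: pd.DataFrame
    n_edges_a: int
    n_edges_b: int
    hub_table: pd.DataFrame

    @property
    def n_common(self) -> int:
        return len(self.common_edges)


def differential_network(net_a: GeneNetwork, net_b: GeneNetwork, hub_k: int = 10) -> DiffNetReport:
    """Partition two networks' edges into common and condition-specific sets.

    Edges are keyed by (regulator, target).  Disjoint gene universes
    trigger a warning but the comparison proceeds on the union.
    """
    import warnings

    if not set(net_a.gene_ids) & set(net_b.gene_ids):
        warnings.warn("networks share no gene identifiers; comparing on the union",
                      stacklevel=2)
    key = ["regulator", "target"]
    a = net_a.edges.set_index(key)
    b = net_b.edges.set_index(key)
    common_idx = a.index.intersection(b.index)
    hubs_a = hub_genes(net_a, hub_k).assign(network="a")
    hubs_b = hub_genes(net_b, hub_k).assign(network="b")
    return DiffNetReport(
        common_edges=a.loc[common_idx].reset_index(),
        a_specific_edges=a.loc[a.index.difference(b.index)].reset_index(),
        b_specific_edges=b.loc[b.index.difference(a.index)].reset_index(),
        n_edges_a=len(a),
        n_edges_b=len(b),
        hub_table=pd.concat([hubs_a, hubs_b], ignore_index=True),
    )
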