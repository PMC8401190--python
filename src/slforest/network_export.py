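"""Directed vulnerability-network construction, filtering and export.

Edges run from the deficient gene (mutated or dysregulated feature) to the
dependent target gene.  Presentation attributes are stored as data only:
``width_weight`` (|PCC|) and ``node_shade_value`` (median dependency).
Multiple (feature_type, method) evidences for a gene pair are kept as
parallel edges.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EDGE_COLUMNS = [
    "source", "target", "feature_type", "method", "pcc", "scaled_importance", "tier",
]
NODE_COLUMNS = ["gene", "median_dependency", "cv", "sd", "range"]


def build_network(pairs: pd.DataFrame, node_stats: pd.DataFrame) -> nx.MultiDiGraph:
    """Assemble a directed multigraph from a self-free pair table.

    ``node_stats`` is indexed by gene; genes absent from it (feature-only
    genes) get nodes with missing statistics.  Duplicate
    (source, target, feature_type, method) rows violate the upstream dedup
    contract and raise.
    """
    g = nx.MultiDiGraph()
    if not pairs.empty:
        if (pairs["target_gene"] == pairs["feature_gene"]).any():
            raise ValueError("pair table contains self-pairs; drop them first")
        key = pairs[["feature_gene", "target_gene", "feature_type", "method"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate edge evidence {dup}; upstream dedup violated")

    genes = set(node_stats.index)
    if not pairs.empty:
        genes |= set(pairs["target_gene"]) | set(pairs["feature_gene"])
    for gene in sorted(genes):
        if gene in node_stats.index:
            row = node_stats.loc[gene]
            g.add_node(
                gene,
                median_dependency=float(row["median_dependency"]),
                cv=float(row["cv"]),
                sd=float(row["sd"]),
                range=float(row["range"]),
                node_shade_value=float(row["median_dependency"]),
                stats_present=True,
            )
        else:
            g.add_node(gene, stats_present=False)

    for _, r in pairs.iterrows():
        g.add_edge(
            r["feature_gene"],
            r["target_gene"],
            feature_type=r["feature_type"],
            method=r["method"],
            pcc=float(r["pcc"]),
            scaled_importance=float(r["scaled_importance"]),
            tier=int(r["tier"]) if "tier" in r and pd.notna(r.get("tier")) else 0,
            width_weight=abs(float(r["pcc"])),
        )
    return g


def filter_network(
    net: nx.MultiDiGraph,
    min_scaled_importance: dict[str, float] | None = None,
    feature_types: set[str] | None = None,
    method: str | None = None,
    direction_filter_enabled: bool = True,
) -> nx.MultiDiGraph:
    """Remove edges failing any active criterion and drop orphaned nodes.

    ``min_scaled_importance`` maps feature_type to its independent
    threshold (edges must meet or exceed it).
    """
    min_scaled_importance = min_scaled_importance or {}
    out = nx.MultiDiGraph()
    out.add_nodes_from(net.nodes(data=True))
    for u, v, k, d in net.edges(keys=True, data=True):
        ft = d["feature_type"]
        if feature_types is not None and ft not in feature_types:
            continue
        if method is not None and d["method"] != method:
            continue
        thr = min_scaled_importance.get(ft)
        if thr is not None and d["scaled_importance"] < thr:
            continue
        if direction_filter_enabled:
            if ft == "mutation" and d["pcc"] <= 0:
                continue
            if ft == "expression" and d["pcc"] >= 0:
                continue
        out.add_edge(u, v, key=k, **d)
    orphans = [n for n in out.nodes if out.degree(n) == 0]
    out.remove_nodes_from(orphans)
    return out


def network_to_tables(net: nx.MultiDiGraph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge and node tables with stable ordering (edges by descending
    scaled importance then lexicographic; nodes lexicographic)."""
    edges = pd.DataFrame(
        [
            {
                "source": u,
                "target": v,
                "feature_type": d["feature_type"],
                "method": d["method"],
                "pcc": d["pcc"],
                "scaled_importance": d["scaled_importance"],
                "tier": d.get("tier", 0),
            }
            for u, v, d in net.edges(data=True)
        ],
        columns=EDGE_COLUMNS,
    )
    if not edges.empty:
        edges = edges.sort_values(
            ["scaled_importance", "source", "target", "feature_type", "method"],
            ascending=[False, True, True, True, True],
        ).reset_index(drop=True)
    nodes = pd.DataFrame(
        [
            {
                "gene": n,
                "median_dependency": d.get("median_dependency", np.nan),
                "cv": d.get("cv", np.nan),
                "sd": d.get("sd", np.nan),
                "range": d.get("range", np.nan),
            }
            for n, d in sorted(net.nodes(data=True))
        ],
        columns=NODE_COLUMNS,
    )
    return edges, nodes


def export_network(net: nx.MultiDiGraph, out_prefix) -> dict[str, Path]:
    """Write ``<prefix>_edges.csv``, ``<prefix>_nodes.csv`` and
    ``<prefix>.graphml``; returns the written paths."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    edges, nodes = network_to_tables(net)
    paths = {
        "edges": out_prefix.parent / f"{out_prefix.name}_edges.csv",
        "nodes": out_prefix.parent / f"{out_prefix.name}_nodes.csv",
        "graphml": out_prefix.parent / f"{out_prefix.name}.graphml",
    }
    try:
        edges.to_csv(paths["edges"], index=False)
        nodes.to_csv(paths["nodes"], index=False)
        clean = nx.MultiDiGraph()
        for n, d in net.nodes(data=True):
            clean.add_node(n, **{k: v for k, v in d.items() if not _is_nan(v)})
        for u, v, k, d in net.edges(keys=True, data=True):
            clean.add_edge(u, v, key=k, **d)
        nx.write_graphml(clean, paths["graphml"])
    except OSError as exc:
        raise OSError(f"failed writing network files under {out_prefix}: {exc}") from exc
    return paths


def _is_nan(v) -> bool:
    return isinstance(v, float) and np.isnan(v)


def read_network(graphml_path) -> nx.MultiDiGraph:
    """Round-trip loader for networks written by :func:`export_network`."""
    g = nx.read_graphml(graphml_path, force_multigraph=True)
    return nx.MultiDiGraph(g)


def method_concordance(
    pairs_a: pd.DataFrame, pairs_b: pd.DataFrame
) -> tuple[int, float | None]:
    """Pearson correlation of scaled importances over the pairs two methods
    share (identity key: target, feature, feature_type).

    Returns (n_common, r); r is None below 3 common pairs.
    """
    key = ["target_gene", "feature_gene", "feature_type"]
    merged = pairs_a.merge(pairs_b, on=key, suffixes=("_a", "_b"))
    n = len(merged)
    if n < 3:
        return n, None
    a = merged["scaled_importance_a"].to_numpy(dtype=float)
    b = merged["scaled_importance_b"].to_numpy(dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return n, None
    return n, float(np.corrcoef(a, b)[0, 1])


def read_interaction_scores(path) -> pd.DataFrame:
    """Read a gene-pair interaction-score TSV (columns gene_a, gene_b,
    combined_score[, experimental_score]) keyed on the unordered pair."""
    t = pd.read_csv(path, sep="\t")
    for col in ("gene_a", "gene_b", "combined_score"):
        if col not in t.columns:
            raise ValueError(f"interaction score table missing column {col!r}")
    t = t.copy()
    t["_key"] = [frozenset((a, b)) for a, b in zip(t["gene_a"], t["gene_b"])]
    return t


def interaction_enrichment(
    groups: dict[str, pd.DataFrame], score_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-group interaction summary against a user-supplied score table.

    For each named group of pairs: the number of pairs, how many have any
    interaction score (unordered gene-pair matching), the fraction, and the
    quartiles of the scores present.
    """
    lookup: dict[frozenset, float] = {}
    if len(score_table):
        lookup = dict(zip(score_table["_key"], score_table["combined_score"]))
    rows = []
    for name, g in groups.items():
        n = len(g)
        if n == 0:
            rows.append(
                {"group": name, "n_pairs": 0, "n_scored": 0, "fraction_scored": 0.0,
                 "q25": None, "median": None, "q75": None}
            )
            continue
        scores = [
            lookup.get(frozenset((t, f)))
            for t, f in zip(g["target_gene"], g["feature_gene"])
        ]
        present = [s for s in scores if s is not None]
        rows.append(
            {
                "group": name,
                "n_pairs": n,
                "n_scored": len(present),
                "fraction_scored": len(present) / n,
                "q25": float(np.percentile(present, 25)) if present else None,
                "median": float(np.median(present)) if present else None,
                "q75": float(np.percentile(present, 75)) if present else None,
            }
        )
    return pd.DataFrame(rows)
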