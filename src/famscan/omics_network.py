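"""Co-expression and gene-metabolite correlation networks; enrichment.

Edges are Pearson correlations with p-values from the exact t transform
t = r sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom.  The
co-expression screen links seed (family) genes to candidate TFs at
r > 0.9 (positive-only by default, matching the usual screening
convention); the metabolite screen links genes to prefiltered
significantly-changed metabolites at |r| > 0.8, p < 0.05.  The merged
tripartite network (family genes, other TFs, functional genes,
metabolites) exports to Cytoscape-ready SIF/GraphML plus node/edge
tables.  Enrichment is a generic upper-tail hypergeometric test over a
user-supplied annotation map with BH correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_stats import expressed_filter

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkEdge:
    source: str
    target: str
    edge_type: str  # tf_coexpr | gene_metabolite | tf_functional
    r: float
    p_value: float


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p from the t transform.

    Raises on vectors shorter than 3 or with zero variance (the
    correlation is then undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("vectors must have equal length >= 3")
    xc, yc = x - x.mean(), y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(xc @ yc) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


@dataclass
class CoexpressionResult:
    edges: list[NetworkEdge]
    n_tfs: int
    n_families: int


def coexpression_screen(
    seed_matrix: pd.DataFrame,
    candidate_matrix: pd.DataFrame,
    candidate_families: Mapping[str, str],
    r_min: float = 0.9,
    min_fpkm: float = 0.5,
    signed: bool = True,
) -> CoexpressionResult:
    """Screen candidate TFs for co-expression with seed genes.

    Both partners must pass the expressed filter; an edge requires
    r > r_min (``signed``, the default) or |r| > r_min.  The summary
    counts distinct TFs with at least one edge and their distinct
    families.
    """
    if list(seed_matrix.columns) != list(candidate_matrix.columns):
        raise ValueError("seed and candidate matrices must share sample columns")
    seeds = expressed_filter(seed_matrix, min_fpkm)
    cands = expressed_filter(candidate_matrix, min_fpkm)
    edges = []
    for seed in seeds:
        x = seed_matrix.loc[seed].values
        if np.std(x) == 0:
            logger.warning("seed %s has constant profile; skipped", seed)
            continue
        for cand in cands:
            y = candidate_matrix.loc[cand].values
            if np.std(y) == 0:
                continue
            r, p = pearson_with_p(x, y)
            passed = r > r_min if signed else abs(r) > r_min
            if passed:
                edges.append(NetworkEdge(seed, cand, "tf_coexpr", r, p))
    tfs = {e.target for e in edges}
    families = {candidate_families.get(t, "unknown") for t in tfs}
    return CoexpressionResult(edges=edges, n_tfs=len(tfs), n_families=len(families))


@dataclass
class MetaboliteAssociationResult:
    edges: list[NetworkEdge]
    metabolites_tested: list[str]
    class_breakdown: pd.DataFrame  # per class: n_metabolites, n_edges


def metabolite_association(
    gene_matrix: pd.DataFrame,
    metabolite_matrix: pd.DataFrame,
    metabolite_meta: pd.DataFrame,
    r_abs_min: float = 0.8,
    p_max: float = 0.05,
    met_fc_min: float = 1.5,
    met_sig: str = "fdr",
    sig_max: float = 0.05,
) -> MetaboliteAssociationResult:
    """Correlate genes with significantly-changed metabolites.

    ``metabolite_meta`` needs columns class, log2fc and p_value and/or
    fdr_q.  Metabolites are prefiltered by log2fc >= met_fc_min and the
    chosen significance column (``met_sig`` in {'p','fdr'}); edges then
    require |r| > r_abs_min and correlation p < p_max.
    """
    if list(gene_matrix.columns) != list(metabolite_matrix.columns):
        raise ValueError("gene and metabolite matrices must share sample columns")
    sig_col = {"p": "p_value", "fdr": "fdr_q"}.get(met_sig)
    if sig_col is None:
        raise ValueError("met_sig must be 'p' or 'fdr'")
    meta = metabolite_meta.loc[metabolite_matrix.index]
    keep = (meta["log2fc"] >= met_fc_min) & (meta[sig_col] < sig_max)
    tested = list(metabolite_matrix.index[keep])
    edges = []
    for gene in gene_matrix.index:
        x = gene_matrix.loc[gene].values
        if np.std(x) == 0:
            logger.warning("gene %s has constant profile; no edges", gene)
            continue
        for met in tested:
            y = metabolite_matrix.loc[met].values
            if np.std(y) == 0:
                continue
            r, p = pearson_with_p(x, y)
            if abs(r) > r_abs_min and p < p_max:
                edges.append(NetworkEdge(gene, met, "gene_metabolite", r, p))
    linked = {e.target for e in edges}
    rows = []
    for cls, sub in meta.loc[tested].groupby("class"):
        rows.append(
            {"class": cls, "n_metabolites": len(sub),
             "n_linked": sum(1 for m in sub.index if m in linked),
             "n_edges": sum(1 for e in edges if meta.loc[e.target, "class"] == cls)}
        )
    breakdown = pd.DataFrame(rows, columns=["class", "n_metabolites", "n_linked", "n_edges"])
    return MetaboliteAssociationResult(
        edges=edges, metabolites_tested=tested, class_breakdown=breakdown
    )


def build_tripartite_network(
    edge_lists: Iterable[Sequence[NetworkEdge]],
    node_roles: Mapping[str, str] | Sequence[Mapping[str, str]],
) -> nx.Graph:
    """Merge edge lists into one graph with node roles.

    Roles are {wrky, tf, functional_gene, metabolite}; ``node_roles``
    may be one mapping or one per edge list — an id declared with
    conflicting roles raises.  Duplicate edges keep the max |r|.
    """
    valid_roles = {"wrky", "tf", "functional_gene", "metabolite"}
    if isinstance(node_roles, Mapping):
        role_maps = [node_roles]
    else:
        role_maps = list(node_roles)
    merged: dict[str, str] = {}
    for mapping in role_maps:
        for node, role in mapping.items():
            if role not in valid_roles:
                raise ValueError(f"node {node}: invalid role {role}")
            if merged.get(node, role) != role:
                raise ValueError(f"conflicting roles for node {node}")
            merged[node] = role
    node_roles = merged
    graph = nx.Graph()
    for edges in edge_lists:
        for e in edges:
            for node in (e.source, e.target):
                if node not in node_roles:
                    raise ValueError(f"node {node} has no declared role")
                if node in graph.nodes and graph.nodes[node]["role"] != node_roles[node]:
                    raise ValueError(f"conflicting roles for node {node}")
                graph.add_node(node, role=node_roles[node])
            if graph.has_edge(e.source, e.target):
                if abs(e.r) <= abs(graph.edges[e.source, e.target]["r"]):
                    continue
            graph.add_edge(
                e.source, e.target, edge_type=e.edge_type, r=e.r, p_value=e.p_value
            )
    return graph


def export_network(graph: nx.Graph, outdir: str | Path, basename: str = "network") -> dict[str, Path]:
    """Write node/edge TSVs plus SIF and GraphML for Cytoscape import."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    nodes = pd.DataFrame(
        [{"id": n, "role": d["role"], "degree": graph.degree[n]}
         for n, d in graph.nodes(data=True)]
    )
    paths["nodes"] = outdir / f"{basename}.nodes.tsv"
    nodes.to_csv(paths["nodes"], sep="\t", index=False)
    edges = pd.DataFrame(
        [{"source": u, "target": v, "edge_type": d["edge_type"], "r": d["r"],
          "p_value": d["p_value"]} for u, v, d in graph.edges(data=True)]
    )
    paths["edges"] = outdir / f"{basename}.edges.tsv"
    edges.to_csv(paths["edges"], sep="\t", index=False)
    paths["sif"] = outdir / f"{basename}.sif"
    with open(paths["sif"], "w") as sif:
        for u, v, d in graph.edges(data=True):
            sif.write(f"{u}\t{d['edge_type']}\t{v}\n")
    paths["graphml"] = outdir / f"{basename}.graphml"
    nx.write_graphml(graph, paths["graphml"])
    return paths


def hypergeometric_enrichment(
    query_set: Iterable[str],
    annotation_map: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of terms in a query gene set.

    For each term with K annotated genes in a universe of N, and k hits
    in a query of n, p = P(X >= k) for X ~ Hypergeom(N, K, n); BH
    correction across terms.  Returns a frame with term, k, K, n, N, p
    and q sorted by p.
    """
    query = set(query_set)
    universe = set(universe)
    if not query:
        raise ValueError("query set must not be empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    term_members: dict[str, set] = {}
    for gene in universe:
        for term in annotation_map.get(gene, ()):
            term_members.setdefault(term, set()).add(gene)
    N, n = len(universe), len(query)
    rows = []
    for term, members in sorted(term_members.items()):
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    frame = pd.DataFrame(rows)
    if not frame.empty:
        _, q, _, _ = multipletests(frame["p"].values, method="fdr_bh")
        frame["q"] = q
        frame = frame.sort_values("p", kind="stable").reset_index(drop=True)
    return frame
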