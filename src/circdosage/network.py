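"""circRNA-miRNA-mRNA (ceRNA) network construction.

CircRNAs can sequester ("sponge") miRNAs, derepressing the miRNAs' mRNA
targets.  The network is a tripartite directed graph: differentially
expressed circRNAs with known catalogue ids -> miRNAs with AGO CLIP-seq
supported binding sites (>= 2 experiments) -> target mRNAs restricted to
differentially expressed genes and expressed PAR genes.  The sponge logic
implies sign consistency along a path: an UP circRNA frees miRNAs and
derepresses its targets, so it explains an UP mRNA (and vice versa); the
sign filter codifies this and can be toggled off.  miRNA expression is
unobserved, so miRNA nodes carry direction "none" and the rule operates on
the circRNA/mRNA endpoints only.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

SPONGE_EDGE = "sponges"
TARGET_EDGE = "targets"


def filter_circ_mirna(edges: pd.DataFrame, min_experiments: int = 2,
                      known_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Keep circRNA-miRNA edges supported by >= min_experiments CLIP experiments.

    ``edges`` has columns known_id, mirna, n_clip_experiments.  If
    ``known_ids`` is given, edges are additionally restricted to circRNAs
    with those catalogue ids (interactions are only queryable for catalogued
    circRNAs).
    """
    if (edges["n_clip_experiments"] < 1).any():
        raise ValueError("n_clip_experiments must be >= 1")
    kept = edges[edges["n_clip_experiments"] >= min_experiments]
    if known_ids is not None:
        kept = kept[kept["known_id"].isin(set(known_ids))]
    return kept.reset_index(drop=True)


def build_network(decs: pd.DataFrame, kept_circ_mirna: pd.DataFrame,
                  mirna_targets: pd.DataFrame, degs: pd.DataFrame,
                  expressed_par_genes: Iterable[str] = ()) -> nx.DiGraph:
    """Assemble the tripartite ceRNA graph.

    ``decs``: differentially expressed circRNAs with columns key, known_id,
    direction (up/down).  ``degs``: differentially expressed genes with
    columns gene_id, direction.  mRNA nodes are restricted to DEGs plus
    expressed PAR genes (direction "none" when not a DEG); miRNAs with no
    retained target are pruned, as are circRNAs left without miRNAs.  An
    empty DEC table yields an empty graph.
    """
    g = nx.DiGraph()
    if len(decs) == 0:
        return g
    decs = decs[decs["known_id"].astype(bool)]
    known_to_key = dict(zip(decs["known_id"], decs["key"]))
    circ_direction = dict(zip(decs["key"], decs["direction"]))
    deg_direction = dict(zip(degs["gene_id"], degs["direction"])) if len(degs) else {}
    allowed_genes = set(deg_direction) | set(expressed_par_genes)

    targets_by_mirna: dict[str, set[str]] = {}
    for _, r in mirna_targets.iterrows():
        targets_by_mirna.setdefault(r["mirna"], set()).add(r["gene_id"])

    for _, e in kept_circ_mirna.iterrows():
        key = known_to_key.get(e["known_id"])
        if key is None:
            continue
        kept_targets = targets_by_mirna.get(e["mirna"], set()) & allowed_genes
        if not kept_targets:
            continue  # isolated miRNA: prune
        g.add_node(key, kind="circRNA", direction=circ_direction[key],
                   known_id=e["known_id"])
        g.add_node(e["mirna"], kind="miRNA", direction="none")
        g.add_edge(key, e["mirna"], interaction=SPONGE_EDGE,
                   n_clip_experiments=int(e["n_clip_experiments"]))
        for gene in sorted(kept_targets):
            direction = deg_direction.get(gene, "none")
            g.add_node(gene, kind="mRNA", direction=direction,
                       is_deg=gene in deg_direction)
            g.add_edge(e["mirna"], gene, interaction=TARGET_EDGE)
    _prune_isolated(g)
    return g


def _prune_isolated(g: nx.DiGraph) -> None:
    """Remove miRNAs without both a circRNA and an mRNA side, then bare ends."""
    changed = True
    while changed:
        changed = False
        for node, data in list(g.nodes(data=True)):
            kind = data["kind"]
            if kind == "miRNA" and (g.in_degree(node) == 0 or g.out_degree(node) == 0):
                g.remove_node(node)
                changed = True
            elif kind == "circRNA" and g.out_degree(node) == 0:
                g.remove_node(node)
                changed = True
            elif kind == "mRNA" and g.in_degree(node) == 0:
                g.remove_node(node)
                changed = True


def paths(g: nx.DiGraph) -> list[tuple[str, str, str]]:
    """All circRNA -> miRNA -> mRNA paths in the network."""
    out = []
    for circ, data in g.nodes(data=True):
        if data["kind"] != "circRNA":
            continue
        for mir in g.successors(circ):
            for gene in g.successors(mir):
                out.append((circ, mir, gene))
    return sorted(out)


def sign_consistency_filter(g: nx.DiGraph) -> nx.DiGraph:
    """Keep circ->miRNA->mRNA paths whose circRNA and mRNA directions agree.

    Sponging derepresses targets, so an up circRNA explains an up target and
    a down circRNA a down target; paths with direction "none" at either
    endpoint are removed.  Nodes left isolated are pruned.  Idempotent.
    """
    kept = nx.DiGraph()
    for circ, mir, gene in paths(g):
        d_circ = g.nodes[circ]["direction"]
        d_gene = g.nodes[gene]["direction"]
        if d_circ not in ("up", "down") or d_circ != d_gene:
            continue
        kept.add_node(circ, **g.nodes[circ])
        kept.add_node(mir, **g.nodes[mir])
        kept.add_node(gene, **g.nodes[gene])
        kept.add_edge(circ, mir, **g.edges[circ, mir])
        kept.add_edge(mir, gene, **g.edges[mir, gene])
    return kept


def enrichment_test(network_genes: Iterable[str], universe: Iterable[str],
                    gene_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of gene sets.

    For each set, p = P(X >= k) with X ~ Hypergeom(N=|universe|, K=|set in
    universe|, n=|network genes|); BH correction across sets.  Sets disjoint
    from the universe are skipped with a warning.
    """
    universe = set(universe)
    selected = set(network_genes)
    if not selected <= universe:
        raise ValueError("network genes must be a subset of the universe")
    n_univ, n_sel = len(universe), len(selected)
    rows = []
    for name, members in gene_sets.items():
        in_univ = set(members) & universe
        if not in_univ:
            warnings.warn(f"gene set {name!r} is disjoint from the universe; skipped",
                          UserWarning, stacklevel=2)
            continue
        k = len(selected & in_univ)
        K = len(in_univ)
        p = float(stats.hypergeom.sf(k - 1, n_univ, K, n_sel))
        # odds ratio of the 2x2 selection table (0.5 continuity only on zero cells)
        a, b = k, n_sel - k
        c, d = K - k, n_univ - K - (n_sel - k)
        odds = (a * d) / (b * c) if b * c > 0 else float("inf")
        rows.append((name, k, K, odds, p))
    out = pd.DataFrame(rows, columns=["gene_set", "overlap", "set_size", "odds", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def export_network(g: nx.DiGraph, outdir: str | Path,
                   basename: str = "cerna") -> dict[str, Path]:
    """Write Cytoscape-ingestible files: SIF, edge-list TSV, node table, GraphML.

    The edge list round-trips through :func:`read_edge_list`.  An empty
    network produces headed but otherwise empty tables (and no SIF lines).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sif = outdir / f"{basename}.sif"
    with sif.open("w") as fh:
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{data['interaction']}\t{v}\n")
    edges = outdir / f"{basename}_edges.tsv"
    edge_rows = [(u, v, d["interaction"], d.get("n_clip_experiments", ""))
                 for u, v, d in sorted(g.edges(data=True))]
    pd.DataFrame(edge_rows, columns=["source", "target", "interaction",
                                     "n_clip_experiments"]
                 ).to_csv(edges, sep="\t", index=False)
    nodes = outdir / f"{basename}_nodes.tsv"
    node_rows = [(n, d["kind"], d["direction"], d.get("known_id", ""))
                 for n, d in sorted(g.nodes(data=True))]
    pd.DataFrame(node_rows, columns=["node", "kind", "direction", "known_id"]
                 ).to_csv(nodes, sep="\t", index=False)
    graphml = outdir / f"{basename}.graphml"
    g2 = nx.DiGraph()
    for n, d in g.nodes(data=True):  # GraphML rejects None attributes
        g2.add_node(n, **{k: v for k, v in d.items() if v is not None})
    for u, v, d in g.edges(data=True):
        g2.add_edge(u, v, **{k: v for k, v in d.items() if v is not None})
    nx.write_graphml(g2, graphml)
    return {"sif": sif, "edges": edges, "nodes": nodes, "graphml": graphml}


def read_edge_list(edges_path: str | Path, nodes_path: str | Path) -> nx.DiGraph:
    """Rebuild a network from the exported edge and node tables."""
    g = nx.DiGraph()
    nodes = pd.read_csv(nodes_path, sep="\t", keep_default_na=False)
    for _, r in nodes.iterrows():
        attrs = {"kind": r["kind"], "direction": r["direction"]}
        if r.get("known_id", ""):
            attrs["known_id"] = r["known_id"]
        g.add_node(r["node"], **attrs)
    edges = pd.read_csv(edges_path, sep="\t", keep_default_na=False)
    for _, r in edges.iterrows():
        attrs = {"interaction": r["interaction"]}
        if r["n_clip_experiments"] != "":
            attrs["n_clip_experiments"] = int(r["n_clip_experiments"])
        g.add_edge(r["source"], r["target"], **attrs)
    return g
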