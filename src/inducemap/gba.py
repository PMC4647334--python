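"""Guilt-by-association linking of extracellular genes to CAZy genes.

Each gene's response is reduced to a signed ternary profile over the
inducers (+1 significant up, -1 significant down, 0 otherwise). A candidate
gene (extracellular, non-CAZy) is associated with a CAZy gene when the two
profiles agree exactly on the CAZy gene's nonzero support set — i.e. the
candidate is regulated in the same direction in every inducer where the
CAZy gene responds. Single-inducer supports are excluded by default
(``min_support=2``). The result is exported as a typed gene-inducer network.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd


def signed_profiles(de: pd.DataFrame) -> pd.DataFrame:
    """Gene x inducer matrix with values in {-1, 0, +1}."""
    directions = de.pivot(index="gene", columns="inducer", values="direction")
    mapped = directions.apply(
        lambda col: col.map({"up": 1, "down": -1}).fillna(0))
    return mapped.astype(np.int8)


def associate(
    cazy_genes: Iterable[str],
    candidate_genes: Iterable[str],
    profiles: pd.DataFrame,
    min_support: int = 2,
) -> pd.DataFrame:
    """Edges (cazy_gene -> candidate) under the exact profile-match rule.

    An edge exists iff the CAZy gene's support set S (its nonzero inducers)
    has ``|S| >= min_support`` and the candidate's profile is nonzero and
    identical to the CAZy gene's on every inducer of S. Self pairs and
    candidates that are themselves CAZy genes are skipped.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    cazy = [g for g in cazy_genes if g in profiles.index]
    cands = [g for g in candidate_genes if g in profiles.index]
    P = profiles.to_numpy()
    pos = {g: i for i, g in enumerate(profiles.index)}
    rows = []
    for c in cazy:
        pc = P[pos[c]]
        support = np.flatnonzero(pc)
        if len(support) < min_support:
            continue
        for g in cands:
            if g == c:
                continue
            pg = P[pos[g]]
            if np.array_equal(pg[support], pc[support]):
                rows.append({"cazy_gene": c, "gene": g,
                             "n_support": int(len(support))})
    return pd.DataFrame(rows, columns=["cazy_gene", "gene", "n_support"])


def build_network(
    edges: pd.DataFrame,
    de: pd.DataFrame,
    genes: Iterable[str] | None = None,
) -> nx.DiGraph:
    """Typed association network of genes and inducers.

    Nodes carry ``kind`` in {``cazy_gene``, ``associated_gene``,
    ``inducer``}; a gene-inducer edge (type ``significant_in``, with the
    regulation sign) exists exactly when the gene is significant in that
    inducer; gene-gene edges (type ``profile_match``) come from ``edges``.
    ``genes`` optionally adds gene nodes beyond those in ``edges``
    (e.g. the full CAZy list of a figure).
    """
    g = nx.DiGraph()
    cazy_nodes = set(edges["cazy_gene"]) if len(edges) else set()
    assoc_nodes = set(edges["gene"]) if len(edges) else set()
    extra = set(genes or ()) - cazy_nodes - assoc_nodes
    for node in sorted(cazy_nodes):
        g.add_node(node, kind="cazy_gene")
    for node in sorted(assoc_nodes):
        g.add_node(node, kind="associated_gene")
    for node in sorted(extra):
        g.add_node(node, kind="cazy_gene")

    sig = de[de["significant"] & de["gene"].isin(set(g.nodes))]
    for _, row in sig.iterrows():
        inducer = str(row["inducer"])
        if inducer not in g:
            g.add_node(inducer, kind="inducer")
        g.add_edge(row["gene"], inducer, type="significant_in",
                   sign=str(row["direction"]))
    if len(edges):
        for _, row in edges.iterrows():
            g.add_edge(row["cazy_gene"], row["gene"], type="profile_match",
                       n_support=int(row["n_support"]))
    return g


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_graphml(network: nx.DiGraph, path: str | Path) -> None:
    nx.write_graphml(network, path)


def read_graphml(path: str | Path) -> nx.DiGraph:
    return nx.read_graphml(path)


def write_sif(network: nx.DiGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v, data in network.edges(data=True):
            fh.write(f"{u}\t{data.get('type', 'edge')}\t{v}\n")


def read_sif(path: str | Path) -> nx.DiGraph:
    g = nx.DiGraph()
    with open(path) as fh:
        for line in fh:
            u, etype, v = line.rstrip("\n").split("\t")
            g.add_edge(u, v, type=etype)
    return g
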