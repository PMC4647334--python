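"""Per-pathway regulation fractions over the metabolic network.

For each (pathway, inducer) pair the fraction of the pathway's gene set
called significantly up- and down-regulated is computed; a pathway-inducer
pair is "highly affected" when at least half the pathway's genes changed
(counting both directions). Genes shared between pathways contribute to each
of them. The fractions double as a clustering input: each pathway yields two
descriptor columns per inducer (up fraction, down fraction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .network import MetabolicNetwork

logger = logging.getLogger(__name__)


@dataclass
class PathwayRegulationMatrix:
    """Fractions of up-/down-regulated genes per (pathway, inducer).

    ``f_up`` and ``f_down`` are pathways x inducers frames in [0, 1] with
    ``f_up + f_down <= 1`` cell-wise; ``sizes`` holds each pathway's gene-set
    size (the denominator, constant across inducers).
    """

    f_up: pd.DataFrame
    f_down: pd.DataFrame
    sizes: pd.Series

    @property
    def f_total(self) -> pd.DataFrame:
        return self.f_up + self.f_down

    def write_tsv(self, path: str | Path) -> None:
        long = pd.concat(
            {"f_up": self.f_up.stack(), "f_down": self.f_down.stack()}, axis=1
        )
        long.index.names = ["pathway", "inducer"]
        long["f_total"] = long["f_up"] + long["f_down"]
        long["n_genes"] = self.sizes.reindex(
            long.index.get_level_values("pathway")).to_numpy()
        long.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PathwayRegulationMatrix":
        long = pd.read_csv(path, sep="\t", index_col=["pathway", "inducer"])
        f_up = long["f_up"].unstack("inducer")
        f_down = long["f_down"].unstack("inducer")
        sizes = long["n_genes"].groupby(level="pathway").first()
        return cls(f_up=f_up, f_down=f_down, sizes=sizes)


def pathway_fractions(
    sig_sets: Mapping[str, tuple[set[str], set[str]]],
    network: MetabolicNetwork,
) -> PathwayRegulationMatrix:
    """Compute ``f_up(p, i) = |pathway(p) ∩ up(i)| / |pathway(p)|`` (and down).

    Pathways with empty gene sets are excluded with a warning.
    """
    pathways = {p: g for p, g in network.pathways.items() if g}
    empty = sorted(set(network.pathways) - set(pathways))
    if empty:
        logger.warning("excluding %d empty pathways: %s", len(empty), empty)
    if not pathways:
        raise ValueError("network has no nonempty pathway gene sets")

    inducers = list(sig_sets)
    names = sorted(pathways)
    f_up = pd.DataFrame(0.0, index=names, columns=inducers)
    f_down = pd.DataFrame(0.0, index=names, columns=inducers)
    sizes = pd.Series({p: len(pathways[p]) for p in names}, name="n_genes")
    for inducer, (up, down) in sig_sets.items():
        for p in names:
            members = pathways[p]
            f_up.loc[p, inducer] = len(members & up) / len(members)
            f_down.loc[p, inducer] = len(members & down) / len(members)
    f_up.index.name = f_down.index.name = "pathway"
    return PathwayRegulationMatrix(f_up=f_up, f_down=f_down, sizes=sizes)


def highly_affected(
    matrix: PathwayRegulationMatrix, threshold: float = 0.5
) -> pd.DataFrame:
    """Pathway-inducer pairs with ``f_up + f_down >= threshold``.

    Sorted by inducer, then total fraction descending (ties by pathway name).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    rows = []
    total = matrix.f_total
    for inducer in total.columns:
        for pathway in total.index:
            ft = total.loc[pathway, inducer]
            if ft >= threshold:
                rows.append({
                    "inducer": inducer,
                    "pathway": pathway,
                    "f_up": matrix.f_up.loc[pathway, inducer],
                    "f_down": matrix.f_down.loc[pathway, inducer],
                    "f_total": ft,
                })
    out = pd.DataFrame(rows, columns=["inducer", "pathway", "f_up",
                                      "f_down", "f_total"])
    if len(out):
        out = out.sort_values(["inducer", "f_total", "pathway"],
                              ascending=[True, False, True],
                              ignore_index=True)
    return out


def build_two_block_matrix(matrix: PathwayRegulationMatrix) -> pd.DataFrame:
    """Inducer x descriptor matrix with two columns per pathway (up, down).

    This is the clustering input: items are inducers, descriptors are
    ``<pathway>|up`` and ``<pathway>|down`` fractions.
    """
    up = matrix.f_up.T.add_suffix("|up")
    down = matrix.f_down.T.add_suffix("|down")
    out = pd.concat([up, down], axis=1)
    out = out[sorted(out.columns)]
    out.index.name = "inducer"
    return out


def export_bipartite(
    affected: pd.DataFrame,
    graphml_path: str | Path | None = None,
    sif_path: str | Path | None = None,
):
    """Inducer-pathway bipartite graph of highly affected pairs.

    Pathway nodes carry ``f_total`` (size cue) and ``direction`` (dominant
    regulation direction) attributes on the connecting edges.
    """
    import networkx as nx

    g = nx.Graph()
    for _, row in affected.iterrows():
        g.add_node(row["inducer"], kind="inducer")
        g.add_node(row["pathway"], kind="pathway")
        direction = "up" if row["f_up"] >= row["f_down"] else "down"
        g.add_edge(row["inducer"], row["pathway"],
                   f_total=float(row["f_total"]), direction=direction)
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
    if sif_path is not None:
        with open(sif_path, "w") as fh:
            for u, v, data in g.edges(data=True):
                fh.write(f"{u}\taffects_{data['direction']}\t{v}\n")
    return g
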