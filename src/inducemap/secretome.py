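"""Secretome and CAZy views of the differential-expression calls.

Three products: (i) the logFC matrix of extracellular genes with a
significant change in at least one inducer (heatmap input), (ii) per-CAZy-
class counts of distinct genes up-/down-regulated by at least one inducer,
and (iii) an induction table with one arrow column per inducer, the
tabular analog of a substrate-induction listing.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .catalog import AnnotationCatalog, CAZY_CLASSES

ARROW_UP = "↑"
ARROW_DOWN = "↓"
ARROW_NONE = "—"


def _logfc_matrix(de: pd.DataFrame) -> pd.DataFrame:
    return de.pivot(index="gene", columns="inducer", values="logFC")


def _direction_matrix(de: pd.DataFrame) -> pd.DataFrame:
    return de.pivot(index="gene", columns="inducer", values="direction")


def extracellular_table(
    de: pd.DataFrame, catalog: AnnotationCatalog
) -> pd.DataFrame:
    """LogFC rows for extracellular genes significant in >= 1 inducer.

    The full logFC row (all inducers, significant or not) is kept so the
    matrix can feed heatmap clustering directly.
    """
    lfc = _logfc_matrix(de)
    sig_any = (de[de["significant"]].groupby("gene").size() > 0)
    keep = [g for g in lfc.index
            if g in catalog.extracellular and sig_any.get(g, False)]
    return lfc.loc[keep]


def cazy_regulation_summary(
    de: pd.DataFrame, catalog: AnnotationCatalog
) -> pd.DataFrame:
    """Distinct-gene regulation counts per CAZy class.

    A gene counts as "up" if up-regulated in >= 1 inducer and "down" if
    down-regulated in >= 1 inducer; a gene doing both increments both
    tallies and the ``both`` overlap column. ``total`` is the number of
    distinct regulated genes.
    """
    sub = de[de["gene"].isin(catalog.cazy)]
    up_genes = set(sub.loc[sub["direction"] == "up", "gene"])
    down_genes = set(sub.loc[sub["direction"] == "down", "gene"])
    rows = []
    for klass in CAZY_CLASSES:
        members = {g for g in catalog.cazy if catalog.cazy_class(g) == klass}
        u = members & up_genes
        d = members & down_genes
        rows.append({"cazy_class": klass, "up": len(u), "down": len(d),
                     "both": len(u & d), "total": len(u | d)})
    return pd.DataFrame(rows).set_index("cazy_class")


def induction_table(
    genes: Sequence[str], de: pd.DataFrame, catalog: AnnotationCatalog
) -> pd.DataFrame:
    """Arrow-per-inducer induction records for the given genes.

    Raises ``KeyError`` listing any genes absent from the DE table; arrows
    mirror the DE directions exactly (up ``↑``, down ``↓``, otherwise ``—``).
    """
    directions = _direction_matrix(de)
    unknown = [g for g in genes if g not in directions.index]
    if unknown:
        raise KeyError(f"genes absent from DE table: {unknown}")
    arrow = {"up": ARROW_UP, "down": ARROW_DOWN, "none": ARROW_NONE}
    body = directions.loc[list(genes)].apply(
        lambda col: col.map(lambda d: arrow.get(d, ARROW_NONE)))
    body.insert(0, "function", [catalog.function.get(g, "") for g in genes])
    body.insert(1, "cazy_family", [catalog.cazy.get(g, "") for g in genes])
    body["extracellular"] = [g in catalog.extracellular for g in genes]
    body["signal_peptide"] = [catalog.signal_peptide.get(g) for g in genes]
    body.index.name = "gene"
    return body


def write_induction_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")


def read_induction_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col="gene", keep_default_na=False)
    frame["extracellular"] = frame["extracellular"].astype(str) == "True"
    frame["signal_peptide"] = pd.to_numeric(frame["signal_peptide"],
                                            errors="coerce")
    return frame


def induction_table_markdown(table: pd.DataFrame) -> str:
    """Text rendering of the induction table for reports."""
    return table.to_markdown()
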