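"""Metabolite -> reaction -> enzyme -> gene -> logFC association tables.

Candidate transcription-factor-binding metabolites (e.g. the strong binders
from a docking triage, consumed here as an input list) are traced through
the metabolic network: every reaction they participate in as substrate or
product contributes one row per associated gene, carrying that gene's
per-inducer logFC with non-significant cells rendered missing ("-"). A
per-metabolite direction-consistency call summarizes whether all observed
responses of the associated genes share one sign.

A packaged reference table of six strong-binder metabolites (sulfite,
sulfate, uroporphyrinogen III, ethanolamine phosphate, D-glyceraldehyde
3-phosphate, taurine) with their reactions, enzymes, genes and printed
logFC values ships with the package and is integrity-checked on load.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .network import MetabolicNetwork, Reaction

META_COLUMNS = ["metabolite", "reaction", "enzyme", "gene"]

_FIXTURE_NAME = "strong_binders_table.tsv"
_FIXTURE_SHA256 = "6d75817230ef9097422451b6c52001a5cdae75b8e0bd96e720ebd3e2d9698a03"


def reactions_of(metabolite: str, network: MetabolicNetwork) -> list[Reaction]:
    """All and only reactions containing the metabolite on either side.

    Reversible reactions match on both sides; an absent metabolite yields an
    empty list with a logged warning, not an error.
    """
    return network.reactions_of(metabolite)


def inducer_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def build_table(
    metabolites: Sequence[str],
    network: MetabolicNetwork,
    de: pd.DataFrame,
) -> pd.DataFrame:
    """One row per (metabolite, reaction, gene) with per-inducer logFC cells.

    Cells are the gene's logFC where the DE call is significant and missing
    (NaN) otherwise. Reactions without a gene association still appear, with
    a missing gene and an all-missing row, so the reaction context of a
    metabolite is never silently dropped.
    """
    inducers = list(dict.fromkeys(de["inducer"]))
    lfc = de.pivot(index="gene", columns="inducer", values="logFC")
    sig = de.pivot(index="gene", columns="inducer", values="significant")
    masked = lfc.where(sig.astype(bool))

    rows = []
    for met in metabolites:
        for rxn in reactions_of(met, network):
            genes: Iterable[str | None] = sorted(rxn.genes) or [None]
            for gene in genes:
                row: dict[str, object] = {
                    "metabolite": met,
                    "reaction": rxn.equation(),
                    "enzyme": rxn.enzyme,
                    "gene": gene,
                }
                for ind in inducers:
                    if gene is not None and gene in masked.index:
                        row[ind] = masked.loc[gene, ind]
                    else:
                        row[ind] = np.nan
                rows.append(row)
    return pd.DataFrame(rows, columns=META_COLUMNS + inducers)


def classify_consistency(table: pd.DataFrame) -> dict[str, str]:
    """Per-metabolite sign consistency of all observed associated-gene logFC.

    ``down_consistent`` iff every non-missing cell of every associated gene
    is negative; ``up_consistent`` analogously positive; ``no_data`` when no
    cell is observed; ``mixed`` otherwise. Invariant to row/column order.
    """
    cols = inducer_columns(table)
    out: dict[str, str] = {}
    for met, sub in table.groupby("metabolite", sort=False):
        cells = sub[cols].to_numpy(float).ravel()
        cells = cells[~np.isnan(cells)]
        if cells.size == 0:
            out[str(met)] = "no_data"
        elif (cells < 0).all():
            out[str(met)] = "down_consistent"
        elif (cells > 0).all():
            out[str(met)] = "up_consistent"
        else:
            out[str(met)] = "mixed"
    return out


def row_stats(table: pd.DataFrame, gene: str) -> tuple[float, float, float, int]:
    """(min, max, mean, n_nonmissing) over a gene's logFC cells."""
    sub = table[table["gene"] == gene]
    if sub.empty:
        raise KeyError(f"gene {gene!r} not present in table")
    cells = sub[inducer_columns(table)].to_numpy(float).ravel()
    cells = cells[~np.isnan(cells)]
    if cells.size == 0:
        return (np.nan, np.nan, np.nan, 0)
    return (float(cells.min()), float(cells.max()),
            float(cells.mean()), int(cells.size))


# --------------------------------------------------------------------------
# serialization ("-" marks a missing cell)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    cols = inducer_columns(table)
    for c in cols:
        out[c] = out[c].map(lambda v: "-" if pd.isna(v) else f"{v:g}")
    out["gene"] = out["gene"].map(lambda g: "-" if pd.isna(g) or g is None else g)
    out["enzyme"] = out["enzyme"].map(
        lambda e: "-" if pd.isna(e) or e is None else e)
    out.to_csv(path, sep="\t", index=False)


def _parse_table(text_rows: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in text_rows.columns if c not in META_COLUMNS]
    out = text_rows.copy()
    for c in cols:
        out[c] = pd.to_numeric(out[c].replace("-", np.nan))
    out["gene"] = out["gene"].replace("-", np.nan)
    out["enzyme"] = out["enzyme"].replace("-", np.nan)
    return out


def read_table(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return _parse_table(raw)


def load_table2_fixture() -> pd.DataFrame:
    """Load the packaged strong-binder association table.

    The file's SHA-256 digest is verified before parsing; a corrupted
    fixture raises ``ValueError``.
    """
    ref = resources.files("inducemap").joinpath(f"data/{_FIXTURE_NAME}")
    payload = ref.read_bytes()
    digest = hashlib.sha256(payload).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise ValueError(
            f"strong-binder fixture corrupted: sha256 {digest} != {_FIXTURE_SHA256}"
        )
    from io import StringIO

    raw = pd.read_csv(StringIO(payload.decode("utf-8")), sep="\t",
                      dtype=str, keep_default_na=False)
    return _parse_table(raw)


def write_consistency(calls: dict[str, str], path: str | Path) -> None:
    pd.Series(calls, name="consistency").to_csv(
        path, sep="\t", index_label="metabolite")
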