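"""GO-term x inducer count matrices and descriptor importance ranking.

A functional fingerprint of each inducer is the count of its significant
genes per GO term; a gene annotated to t terms contributes once to each of
the t rows. The matrix rows can be z-standardized and ranked by a
correlation-based feature-selection (CFS) merit under cross-validation,
scoring each descriptor's individual ability to predict a cluster labeling
of the inducers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class GOCountMatrix:
    """Counts of significant genes per (GO term, inducer).

    ``counts`` is terms x inducers with non-negative integer cells;
    ``ontology`` maps each term to its ontology class; ``coverage`` is the
    per-inducer fraction of significant genes carrying >= 1 GO annotation.
    """

    counts: pd.DataFrame
    ontology: pd.Series
    coverage: pd.Series

    def write_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "ontology_class", self.ontology.reindex(out.index))
        out.to_csv(path, sep="\t", index_label="term")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GOCountMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="term")
        ontology = frame.pop("ontology_class")
        return cls(counts=frame, ontology=ontology,
                   coverage=pd.Series(dtype=float))


def build_go_matrix(
    sig_sets: Mapping[str, tuple[set[str], set[str]]],
    catalog,
) -> GOCountMatrix:
    """Count significant genes per GO term for each inducer.

    ``cell(t, i) = |{g significant in i : t in GO(g)}|``; up- and
    down-regulated genes are pooled, and a multi-term gene is counted once
    per term. Unannotated significant genes lower the coverage fraction but
    do not raise an error.
    """
    terms = catalog.go_terms()
    if not terms:
        raise ValueError("annotation catalog carries no GO terms")
    inducers = list(sig_sets)
    term_ids = sorted(terms)
    counts = pd.DataFrame(0, index=term_ids, columns=inducers, dtype=int)
    coverage = pd.Series(np.nan, index=inducers, dtype=float)
    for inducer, (up, down) in sig_sets.items():
        sig = up | down
        annotated = 0
        for g in sig:
            gene_terms = catalog.go.get(g, [])
            if gene_terms:
                annotated += 1
            for term, _ in gene_terms:
                counts.loc[term, inducer] += 1
        coverage[inducer] = annotated / len(sig) if sig else np.nan
    counts.index.name = "term"
    return GOCountMatrix(
        counts=counts,
        ontology=pd.Series(terms).reindex(term_ids),
        coverage=coverage,
    )


def standardize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Z-score each row (population sd); constant rows map to zeros.

    Returns the standardized matrix and the list of zero-variance rows that
    were flagged. Requires >= 2 columns.
    """
    if matrix.shape[1] < 2:
        raise ValueError("standardization needs >= 2 columns")
    values = matrix.to_numpy(float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population sd
    flagged = [str(r) for r, s in zip(matrix.index, sd.ravel()) if s == 0]
    safe = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / safe
    z[sd.ravel() == 0, :] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns), flagged


def _abs_label_correlation(x: np.ndarray, labels: np.ndarray) -> float:
    """Mean over classes of |Pearson r| between x and the class indicator."""
    if x.std() == 0:
        return 0.0
    rs = []
    for klass in np.unique(labels):
        ind = (labels == klass).astype(float)
        if ind.std() == 0:
            continue
        rs.append(abs(np.corrcoef(x, ind)[0, 1]))
    return float(np.mean(rs)) if rs else 0.0


def cfs_merit(subset: np.ndarray, labels: np.ndarray) -> float:
    """CFS merit ``k * r_cf / sqrt(k + k (k-1) r_ff)`` for a descriptor subset.

    ``r_cf`` is the mean descriptor-label correlation and ``r_ff`` the mean
    pairwise inter-descriptor correlation; for a single descriptor (k = 1)
    the merit reduces to its absolute label correlation.
    """
    k = subset.shape[0]
    r_cf = float(np.mean([_abs_label_correlation(subset[j], labels)
                          for j in range(k)]))
    if k == 1:
        return r_cf
    rff = []
    for a in range(k):
        for b in range(a + 1, k):
            if subset[a].std() == 0 or subset[b].std() == 0:
                rff.append(0.0)
            else:
                rff.append(abs(np.corrcoef(subset[a], subset[b])[0, 1]))
    r_ff = float(np.mean(rff))
    return k * r_cf / np.sqrt(k + k * (k - 1) * r_ff)


def rank_descriptors(
    matrix: pd.DataFrame,
    labels: Mapping[str, int] | pd.Series,
    folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank matrix rows by their cross-validated single-descriptor CFS merit.

    Columns (items) are split into ``folds`` folds (leave-one-out when the
    fold count reaches the column count); each descriptor's merit is its
    CFS merit against the labels computed on the training columns, averaged
    over folds. Ties break lexicographically by row name.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 labeled columns")
    lab = pd.Series(labels).reindex(matrix.columns)
    if lab.isna().any():
        missing = list(lab.index[lab.isna()])
        raise ValueError(f"labels missing for columns: {missing}")
    y = lab.to_numpy()
    n = matrix.shape[1]
    folds = min(folds, n)

    # fold membership is keyed to column names so the ranking is invariant
    # to column permutation under matched labels
    rng = np.random.default_rng(seed)
    names = sorted(str(c) for c in matrix.columns)
    shuffled = [names[i] for i in rng.permutation(n)]
    fold_by_name = {name: i % folds for i, name in enumerate(shuffled)}
    fold_of = np.array([fold_by_name[str(c)] for c in matrix.columns])

    X = matrix.to_numpy(float)
    merits = np.zeros(matrix.shape[0])
    for f in range(folds):
        train = fold_of != f
        if train.sum() < 2:
            continue
        Xt, yt = X[:, train], y[train]
        merits += np.array([cfs_merit(Xt[j:j + 1], yt)
                            for j in range(X.shape[0])])
    merits /= folds

    out = pd.DataFrame({"merit": merits}, index=matrix.index)
    # deterministic rank: descending merit, ties broken by row name
    out = out.loc[sorted(out.index, key=lambda r: (-out.loc[r, "merit"], str(r)))]
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def write_importance(importance: pd.DataFrame, path: str | Path) -> None:
    importance.to_csv(path, sep="\t", index_label="term", float_format="%.6g")
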