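"""Per-inducer differential expression against the glucose reference.

Each inducer condition is compared pairwise with the reference on log2
values: logFC = mean(inducer) - mean(reference), significance from a
two-sample t-test at a raw p < alpha cutoff by default. The pooled
(equal-variance) t is the default statistic — it is exactly calibrated for
the small, homoscedastic replicate groups this design produces — with
Welch's unequal-variance t available via ``statistic="welch"``.
Benjamini-Hochberg adjustment is available behind ``adjust="bh"``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DE_COLUMNS = ["gene", "inducer", "logFC", "p_value", "significant", "direction"]


def condition_of(sample: str) -> str:
    """Condition name encoded in a sample id like ``O-CHE_r2``."""
    cond, _, rep = sample.rpartition("_r")
    if not cond or not rep.isdigit():
        raise ValueError(f"sample id {sample!r} does not encode a replicate")
    return cond


def conditions(expr: pd.DataFrame) -> dict[str, list[str]]:
    """Map condition -> sample columns, preserving column order."""
    out: dict[str, list[str]] = {}
    for col in expr.columns:
        out.setdefault(condition_of(col), []).append(col)
    return out


def _group(expr: pd.DataFrame, condition: str) -> pd.DataFrame:
    cols = conditions(expr).get(condition)
    if not cols:
        raise KeyError(f"condition {condition!r} not present in matrix")
    if len(cols) < 2:
        raise ValueError(f"condition {condition!r} has fewer than 2 replicates")
    return expr[cols]


def pairwise_de(
    expr: pd.DataFrame,
    inducer: str,
    reference: str = "GLU",
    alpha: float = 0.05,
    adjust: str = "none",
    statistic: str = "student",
) -> pd.DataFrame:
    """Compare one inducer against the reference, one row per gene.

    Parameters
    ----------
    expr
        Log2 expression matrix, genes in rows, sample columns named
        ``<condition>_r<replicate>``.
    inducer, reference
        Condition names; both need >= 2 replicates.
    alpha
        Significance cutoff applied to the (possibly adjusted) p-value.
    adjust
        ``"none"`` (raw p, the default reading of a plain p < 0.05 rule) or
        ``"bh"`` for Benjamini-Hochberg.
    statistic
        ``"student"`` (pooled variance, default) or ``"welch"``.

    Returns
    -------
    DataFrame with columns gene, inducer, logFC, p_value, significant,
    direction (``up``/``down``/``none``). Genes with missing values in any
    used sample are dropped with a warning.
    """
    if adjust not in ("none", "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if statistic not in ("student", "welch"):
        raise ValueError(f"unknown statistic {statistic!r}")

    a = _group(expr, inducer)
    b = _group(expr, reference)
    used = pd.concat([a, b], axis=1)
    complete = used.notna().all(axis=1)
    if not complete.all():
        dropped = (~complete).sum()
        logger.warning("dropping %d genes with missing values", dropped)
    x = a.loc[complete].to_numpy(float)
    y = b.loc[complete].to_numpy(float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("expression values must be finite")

    logfc = x.mean(axis=1) - y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(x, y, axis=1, equal_var=(statistic == "student"))

    # degenerate groups: zero variance on both sides is not an error --
    # equal means are maximally unsurprising (p=1), unequal means with no
    # within-group spread are maximally surprising (p -> 0+).
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    both_const = (vx == 0) & (vy == 0)
    p = np.where(both_const & (logfc == 0), 1.0, p)
    p = np.where(both_const & (logfc != 0), np.nextafter(0, 1), p)
    p = np.clip(np.nan_to_num(p, nan=1.0), np.nextafter(0, 1), 1.0)

    p_eff = p if adjust == "none" else multipletests(p, method="fdr_bh")[1]
    significant = p_eff < alpha
    direction = np.where(~significant, "none",
                         np.where(logfc > 0, "up",
                                  np.where(logfc < 0, "down", "none")))
    # a significant call with logFC exactly 0 has no direction; demote it
    significant = significant & (logfc != 0)

    return pd.DataFrame({
        "gene": used.index[complete],
        "inducer": inducer,
        "logFC": logfc,
        "p_value": p,
        "significant": significant,
        "direction": direction,
    }).reset_index(drop=True)


def de_table(
    expr: pd.DataFrame,
    reference: str = "GLU",
    inducers: list[str] | None = None,
    alpha: float = 0.05,
    adjust: str = "none",
    statistic: str = "student",
) -> pd.DataFrame:
    """Run :func:`pairwise_de` for every (or the given) inducer condition."""
    if inducers is None:
        inducers = [c for c in conditions(expr) if c != reference]
    parts = [pairwise_de(expr, ind, reference=reference, alpha=alpha,
                         adjust=adjust, statistic=statistic)
             for ind in inducers]
    return pd.concat(parts, ignore_index=True)


def significant_sets(de: pd.DataFrame) -> dict[str, tuple[set[str], set[str]]]:
    """Per-inducer (up, down) significant gene sets."""
    out: dict[str, tuple[set[str], set[str]]] = {}
    for inducer, sub in de.groupby("inducer", sort=False):
        up = set(sub.loc[sub["direction"] == "up", "gene"])
        down = set(sub.loc[sub["direction"] == "down", "gene"])
        out[str(inducer)] = (up, down)
    return out


def write_de(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_de(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    frame["significant"] = frame["significant"].astype(bool)
    return frame
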