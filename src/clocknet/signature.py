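"""Per-gene expression associations with clock acceleration.

"log2FC" here is the OLS coefficient of log2-scale expression on clock
acceleration standardized within the dataset, with chronological age as a
covariate — i.e., the expression change (in log2 units) per 1 SD of
age-adjusted epigenetic acceleration.  Clocks are then compared by
clustering their gene-wise log2FC vectors and by regressing one clock's
vector on a reference clock's (slope > 1 = stronger expression signal).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "differential_association",
    "cluster_clocks",
    "signal_strength_slope",
    "enrichment_test",
]


def differential_association(
    expr: pd.DataFrame,
    accel: pd.DataFrame,
    samples: pd.DataFrame,
    dataset: str | None = None,
) -> pd.DataFrame:
    """Gene-wise OLS of expression on standardized acceleration plus age.

    ``expr`` is genes x samples; ``accel`` is samples x clocks (raw
    residuals; standardized internally).  Returns a long table with one row
    per (gene, clock): log2fc, se, p, flagged (True when the gene is
    constant, in which case log2fc = 0 and p = 1).
    """
    if isinstance(accel, pd.Series):
        accel = accel.to_frame()
    shared = expr.columns.intersection(accel.index)
    if len(shared) < 10:
        raise ValueError("need at least 10 shared samples")
    Y = expr.loc[:, shared].to_numpy(dtype=float).T  # samples x genes
    age = samples.loc[shared, "age"].to_numpy(dtype=float)
    const = Y.std(axis=0, ddof=1) == 0

    frames = []
    for clock in accel.columns:
        a = accel.loc[shared, clock].to_numpy(dtype=float)
        a = (a - a.mean()) / a.std(ddof=1)
        X = np.column_stack([np.ones(len(shared)), a, age])
        XtX_inv = np.linalg.inv(X.T @ X)
        B = XtX_inv @ X.T @ Y  # 3 x genes
        resid = Y - X @ B
        df = len(shared) - X.shape[1]
        sigma2 = (resid**2).sum(axis=0) / df
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        coef = B[1].copy()
        with np.errstate(invalid="ignore", divide="ignore"):
            t = coef / se
        p = 2.0 * sps.t.sf(np.abs(t), df)
        coef[const] = 0.0
        se[const] = np.nan
        p[const] = 1.0
        frames.append(
            pd.DataFrame(
                {
                    "gene": expr.index,
                    "clock": clock,
                    "dataset": dataset,
                    "log2fc": coef,
                    "se": se,
                    "p": p,
                    "flagged": const,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def log2fc_wide(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate long log2FC tables into a (gene, dataset) x clock matrix."""
    long = pd.concat(tables, ignore_index=True)
    return long.pivot_table(
        index=["dataset", "gene"], columns="clock", values="log2fc", sort=False
    )


def cluster_clocks(
    log2fc: pd.DataFrame | list[pd.DataFrame],
) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Average-linkage clustering of clocks by their log2FC signatures.

    Accepts a wide (gene x clock, or (dataset, gene) x clock) matrix or a
    list of long tables from :func:`differential_association`, which are
    concatenated across datasets.  Distance = 1 - Pearson correlation of
    the clocks' concatenated gene vectors.

    Returns (scipy linkage matrix, clock order, distance matrix).
    """
    if isinstance(log2fc, list):
        log2fc = log2fc_wide(log2fc)
    clocks = list(log2fc.columns)
    if len(clocks) < 2:
        raise ValueError("need at least 2 clocks to cluster")
    V = log2fc.to_numpy(dtype=float)
    ok = ~np.isnan(V).any(axis=1)
    V = V[ok]
    C = np.corrcoef(V.T)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 2.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    dist = pd.DataFrame(D, index=clocks, columns=clocks)
    return Z, clocks, dist


def signal_strength_slope(
    reference: pd.Series, other: pd.Series, alpha: float = 0.05
) -> dict:
    """OLS of one clock's log2FCs on a reference clock's.

    Slope > 1 reads as the other clock carrying stronger gene-expression
    signals than the reference.  Returns slope, intercept, the slope's
    confidence interval, and se/p.
    """
    x = np.asarray(reference, dtype=float)
    y = np.asarray(other, dtype=float)
    if x.shape != y.shape:
        raise ValueError("gene vectors must align")
    if np.ptp(x) == 0:
        raise ValueError("reference log2FCs are constant")
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - 2
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se_slope = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    t = coef[1] / se_slope
    return {
        "slope": float(coef[1]),
        "intercept": float(coef[0]),
        "se": se_slope,
        "ci_low": float(coef[1] - tcrit * se_slope),
        "ci_high": float(coef[1] + tcrit * se_slope),
        "p": float(2.0 * sps.t.sf(abs(t), df)),
        "n": n,
    }


def enrichment_test(
    module_genes,
    gene_sets: dict,
    universe,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test with BH-FDR.

    For each gene set: with a universe of ``N`` genes of which ``K`` are in
    the set, drawing the ``n`` module genes gives an upper-tail p for the
    observed overlap ``k``.  ``q`` is Benjamini-Hochberg across the sets of
    the collection.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module = set(module_genes) & universe
    rows = []
    for name, genes in gene_sets.items():
        genes = set(genes) & universe
        if not genes:
            continue
        k = len(module & genes)
        p = float(sps.hypergeom.sf(k - 1, len(universe), len(genes), len(module)))
        rows.append({"set": name, "k": k, "set_size": len(genes),
                     "module_size": len(module), "universe": len(universe),
                     "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out
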