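"""Robust correlation and covariate-adjusted contrast statistics.

Implements the biweight midcorrelation (bicor) — an outlier-resistant
correlation built from Tukey biweight weights around the median — plus the
pooled / per-tissue age-correlation report and covariate-adjusted condition
contrasts (tumor vs normal, senescence stages, mtDNA depletion) used to
validate clock scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "bicor",
    "correlation_pvalue",
    "age_correlation_report",
    "condition_contrast",
    "ContrastResult",
]


def _biweight_deviations(x: np.ndarray) -> np.ndarray | None:
    """Weighted median deviations d_i; None signals a Pearson fallback."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))  # unscaled MAD, per the 9*mad convention
    if mad == 0:
        return None
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    if np.mean(w == 0) > 0.5:
        return None
    return (x - med) * w


def bicor(x, y) -> float:
    """Biweight midcorrelation of two vectors, in [-1, 1].

    Deviations from the median are downweighted by the Tukey biweight
    ``w_i = (1 - u_i^2)^2`` for ``|u_i| < 1`` with ``u_i = (x_i - med) /
    (9 * mad)`` (mad unscaled), then correlated like Pearson.  Falls back
    to Pearson, with a warning, when more than half of either vector
    receives zero weight (or the mad degenerates to 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    if x.size < 3:
        raise ValueError("bicor needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("bicor is undefined for constant input")
    dx = _biweight_deviations(x)
    dy = _biweight_deviations(y)
    if dx is None or dy is None:
        warnings.warn(
            "more than half of one vector received zero biweight; "
            "falling back to Pearson",
            stacklevel=2,
        )
        return float(np.corrcoef(x, y)[0, 1])
    denom = np.sqrt((dx @ dx) * (dy @ dy))
    if denom == 0:
        raise ValueError("bicor is undefined: all weighted deviations are zero")
    return float(np.clip((dx @ dy) / denom, -1.0, 1.0))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a correlation via the t approximation on n-2 df."""
    if n < 3:
        return float("nan")
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def age_correlation_report(
    scores: pd.DataFrame,
    samples: pd.DataFrame,
    method: str = "pearson",
    tissue_col: str = "tissue",
    min_stratum: int = 3,
) -> pd.DataFrame:
    """Pooled and per-tissue correlations of clock scores with age.

    Returns a long table with columns (clock, stratum, n, r, p); the pooled
    stratum is labelled "pooled".  Strata below ``min_stratum`` samples are
    omitted with a warning.  Pooled correlations can be much weaker than
    every within-tissue correlation when tissues differ in the intercept or
    slope of epigenetic age — the attenuation this report is built to show.
    """
    if isinstance(scores, pd.Series):
        scores = scores.to_frame()
    if method not in ("pearson", "bicor"):
        raise ValueError(f"unknown method {method!r}")
    ages = samples.loc[scores.index, "age"].astype(float)
    strata: list[tuple[str, pd.Index]] = [("pooled", scores.index)]
    if tissue_col in samples.columns:
        for t, idx in samples.loc[scores.index].groupby(tissue_col).groups.items():
            strata.append((str(t), pd.Index(idx)))

    rows = []
    for clock in scores.columns:
        for label, idx in strata:
            if len(idx) < min_stratum:
                warnings.warn(
                    f"stratum {label!r} has {len(idx)} < {min_stratum} samples; omitted",
                    stacklevel=2,
                )
                continue
            s = scores.loc[idx, clock].to_numpy(dtype=float)
            a = ages.loc[idx].to_numpy()
            if method == "pearson":
                r = float(np.corrcoef(a, s)[0, 1])
            else:
                r = bicor(a, s)
            rows.append(
                {
                    "clock": clock,
                    "stratum": label,
                    "n": len(idx),
                    "r": r,
                    "p": correlation_pvalue(r, len(idx)),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ContrastResult:
    """Covariate-adjusted effect of one condition level vs the reference."""

    condition: str
    effect: float
    se: float
    p: float
    n_condition: int
    n_reference: int
    covariates: tuple[str, ...] = ()
    adjusted_means: dict = field(default_factory=dict)


def condition_contrast(
    scores: pd.Series,
    samples: pd.DataFrame,
    condition: str = "condition",
    reference: str = "control",
    covariates: tuple[str, ...] = (),
) -> list[ContrastResult]:
    """OLS contrast of a score across condition levels, adjusting covariates.

    Fits ``score ~ condition indicators + covariates`` (categorical
    covariates such as tissue expand to indicators; numeric ones such as age
    enter linearly) and reports, per non-reference level, the coefficient
    against the reference with its standard error and two-sided t-test p.
    Standard errors of adjusted group means (at covariate means) are
    attached for plotting.

    With no covariates and two balanced groups this reproduces the
    two-sample pooled-variance t test exactly.
    """
    scores = pd.Series(scores).astype(float)
    info = samples.loc[scores.index]
    cond = info[condition].astype(str)
    if reference not in set(cond):
        raise ValueError(f"reference level {reference!r} absent from {condition!r}")
    levels = [l for l in pd.unique(cond) if l != reference]
    counts = cond.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"condition level(s) {small} have fewer than 2 samples")

    cols: list[np.ndarray] = [np.ones(len(scores))]
    names: list[str] = ["(intercept)"]
    for lvl in levels:
        cols.append((cond == lvl).to_numpy(dtype=float))
        names.append(f"{condition}[{lvl}]")
    for cov in covariates:
        v = info[cov]
        if pd.api.types.is_numeric_dtype(v):
            cols.append(v.to_numpy(dtype=float))
            names.append(cov)
        else:
            cats = pd.unique(v.astype(str))
            for c in cats[1:]:
                cols.append((v.astype(str) == c).to_numpy(dtype=float))
                names.append(f"{cov}[{c}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "design matrix is rank-deficient (collinear covariates); "
            f"columns: {names}"
        )
    y = scores.to_numpy()
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = len(y) - X.shape[1]
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se_all = np.sqrt(sigma2 * np.diag(xtx_inv))

    # adjusted group means: intercept + level effect, at mean covariates
    cov_part = 0.0
    for j, name in enumerate(names):
        if j == 0 or name.startswith(f"{condition}["):
            continue
        cov_part += coef[j] * float(np.mean(X[:, j]))

    results = []
    for lvl in levels:
        j = names.index(f"{condition}[{lvl}]")
        t = coef[j] / se_all[j]
        p = float(2.0 * sps.t.sf(abs(t), df))
        # SE of adjusted mean for this level at mean covariates
        contrast = np.zeros(X.shape[1])
        contrast[0] = 1.0
        contrast[j] = 1.0
        for k, name in enumerate(names):
            if k == 0 or name.startswith(f"{condition}["):
                continue
            contrast[k] = float(np.mean(X[:, k]))
        se_mean = float(np.sqrt(sigma2 * contrast @ xtx_inv @ contrast))
        ref_contrast = contrast.copy()
        ref_contrast[j] = 0.0
        se_ref = float(np.sqrt(sigma2 * ref_contrast @ xtx_inv @ ref_contrast))
        results.append(
            ContrastResult(
                condition=lvl,
                effect=float(coef[j]),
                se=float(se_all[j]),
                p=p,
                n_condition=int(counts[lvl]),
                n_reference=int(counts[reference]),
                covariates=tuple(covariates),
                adjusted_means={
                    lvl: (float(contrast @ coef), se_mean),
                    reference: (float(ref_contrast @ coef), se_ref),
                },
            )
        )
    return results
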