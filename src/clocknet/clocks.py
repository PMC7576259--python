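"""Epigenetic clock scoring and age-acceleration residuals.

A clock is a sparse linear predictor over CpG methylation fractions (beta
values): ``LP_s = intercept + sum_j w_j * beta_js``, optionally passed through
the inverse of an age calibration transform so that scores land on a years
scale ("DNAmAge").  Age acceleration is the residual of the score regressed
on chronological age within a fit group (by default the tissue), so positive
acceleration means epigenetically older than expected for that age and
tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClockDefinition",
    "horvath_transform",
    "horvath_inverse",
    "compute_clock_score",
    "score_clocks",
    "age_acceleration",
    "cpg_overlap_census",
]

_CALIBRATIONS = ("identity", "horvath")


@dataclass(frozen=True)
class ClockDefinition:
    """Intercept plus sparse CpG weights, with an optional age calibration.

    Parameters
    ----------
    name : str
        Clock identifier.
    intercept : float
        Additive constant of the linear predictor.
    weights : dict
        Mapping CpG id -> weight.  Must be non-empty; insertion order is
        preserved and meaningful for round-tripping coefficient files.
    calibration : {"identity", "horvath"}
        "identity" leaves the linear predictor untouched; "horvath" applies
        the log-linear age transform used by the pan-tissue clock, with the
        knee at ``adult_age``.
    adult_age : float
        Knee of the horvath calibration, in years.  Ignored for identity.
    """

    name: str
    intercept: float
    weights: dict[str, float]
    calibration: str = "identity"
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError(f"clock {self.name!r}: weights must be non-empty")
        if self.calibration not in _CALIBRATIONS:
            raise ValueError(
                f"clock {self.name!r}: unknown calibration {self.calibration!r}; "
                f"expected one of {_CALIBRATIONS}"
            )
        if self.calibration == "horvath" and not self.adult_age > 0:
            raise ValueError(
                f"clock {self.name!r}: horvath calibration requires adult_age > 0"
            )

    @property
    def cpgs(self) -> list[str]:
        return list(self.weights)

    def invert_calibration(self, lp):
        """Map linear-predictor units to the calibrated score scale."""
        if self.calibration == "identity":
            return lp
        return horvath_inverse(lp, self.adult_age)


def horvath_transform(age, adult_age: float = 20.0):
    """Forward age calibration: log-linear below ``adult_age``, linear above.

    F(age) = ln(age + 1) - ln(adult_age + 1)        for age <= adult_age
           = (age - adult_age) / (adult_age + 1)    otherwise

    Continuous (value 0) at ``age == adult_age``; requires ``age > -1``.
    """
    if not adult_age > 0:
        raise ValueError("adult_age must be > 0")
    age = np.asarray(age, dtype=float)
    if np.any(age <= -1):
        raise ValueError("horvath transform requires age > -1")
    out = np.where(
        age <= adult_age,
        np.log1p(age) - np.log1p(adult_age),
        (age - adult_age) / (adult_age + 1.0),
    )
    return out if out.ndim else float(out)


def horvath_inverse(x, adult_age: float = 20.0):
    """Inverse calibration, mapping linear-predictor units back to years."""
    if not adult_age > 0:
        raise ValueError("adult_age must be > 0")
    x = np.asarray(x, dtype=float)
    out = np.where(
        x <= 0,
        (adult_age + 1.0) * np.exp(x) - 1.0,
        (adult_age + 1.0) * x + adult_age,
    )
    return out if out.ndim else float(out)


def compute_clock_score(
    beta: pd.DataFrame,
    clock: ClockDefinition,
    missing_policy: str = "mean",
) -> pd.Series:
    """Score every sample of a beta matrix with one clock.

    Parameters
    ----------
    beta : DataFrame
        CpGs in rows, samples in columns, methylation fractions in [0, 1]
        (NaN = missing).
    clock : ClockDefinition
    missing_policy : {"error", "zero", "mean"}
        How to treat clock CpGs that are absent from ``beta`` or have NaN
        entries.  "error" refuses and lists the offenders; "zero" scores
        them as beta = 0; "mean" imputes NaN cells with the CpG's mean
        across the dataset's samples, and falls back to beta = 0.5 (with a
        warning) for CpGs with no observed value at all.

    Returns
    -------
    Series indexed by sample id, on the clock's calibrated scale.
    """
    if missing_policy not in ("error", "zero", "mean"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    present = [c for c in clock.weights if c in beta.index]
    if not present:
        raise ValueError(
            f"clock {clock.name!r}: none of its {len(clock.weights)} CpGs "
            "are present in the beta matrix"
        )
    absent = [c for c in clock.weights if c not in beta.index]
    sub = beta.loc[present].astype(float)
    has_nan = sub.isna().to_numpy().any()

    if missing_policy == "error":
        problems = list(absent)
        if has_nan:
            problems += sub.index[sub.isna().any(axis=1)].tolist()
        if problems:
            raise ValueError(
                f"clock {clock.name!r}: missing data for CpGs under policy "
                f"'error': {sorted(set(problems))}"
            )
    elif missing_policy == "zero":
        sub = sub.fillna(0.0)
    else:  # mean impute within dataset
        row_means = sub.mean(axis=1, skipna=True)
        all_missing = row_means.index[row_means.isna()]
        if len(all_missing):
            warnings.warn(
                f"clock {clock.name!r}: CpGs {list(all_missing)} have no "
                "observed values; imputing beta = 0.5",
                stacklevel=2,
            )
            row_means = row_means.fillna(0.5)
        sub = sub.apply(lambda col: col.fillna(row_means))

    w = pd.Series(clock.weights, dtype=float)
    lp = clock.intercept + sub.T.to_numpy() @ w.loc[sub.index].to_numpy()
    scores = clock.invert_calibration(lp)
    return pd.Series(scores, index=beta.columns, name=clock.name)


def score_clocks(
    beta: pd.DataFrame,
    clocks: list[ClockDefinition],
    missing_policy: str = "mean",
) -> pd.DataFrame:
    """Score all clocks; returns samples x clocks DataFrame."""
    return pd.DataFrame(
        {c.name: compute_clock_score(beta, c, missing_policy) for c in clocks}
    )


def age_acceleration(
    scores: pd.DataFrame,
    samples: pd.DataFrame,
    group_by: str | None = "tissue",
) -> pd.DataFrame:
    """Chronological-age-adjusted residuals of clock scores.

    Ordinary least squares of score on age, fit separately within each level
    of ``group_by`` (``None`` pools everything).  Residuals within a fit
    group sum to zero and are uncorrelated with age by construction.

    ``scores`` is samples x clocks; ``samples`` must carry an ``age`` column
    indexed by sample id.  Groups need >= 2 samples and non-constant age.
    """
    if isinstance(scores, pd.Series):
        scores = scores.to_frame()
    ages = samples.loc[scores.index, "age"].astype(float)
    if ages.isna().any():
        raise ValueError("age missing for some scored samples")
    if group_by is None:
        groups = pd.Series("__all__", index=scores.index)
    else:
        groups = samples.loc[scores.index, group_by]

    resid = pd.DataFrame(index=scores.index, columns=scores.columns, dtype=float)
    for g, idx in groups.groupby(groups).groups.items():
        a = ages.loc[idx].to_numpy()
        if len(idx) < 2:
            raise ValueError(f"fit group {g!r} has fewer than 2 samples")
        if np.ptp(a) == 0:
            raise ValueError(f"fit group {g!r} has constant age; cannot adjust")
        X = np.column_stack([np.ones_like(a), a])
        Y = scores.loc[idx].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid.loc[idx] = Y - X @ coef
    return resid


def cpg_overlap_census(
    clocks: list[ClockDefinition],
) -> tuple[pd.Series, dict]:
    """Count, for every CpG used by any clock, how many clocks contain it.

    Returns the per-CpG count (descending, ties by CpG id) and a summary
    with the distinct-CpG total and the number of CpGs at each overlap
    level (level 1 = specific to a single clock).
    """
    if not clocks:
        raise ValueError("need at least one clock")
    counts: dict[str, int] = {}
    for clock in clocks:
        for cpg in clock.weights:
            counts[cpg] = counts.get(cpg, 0) + 1
    census = pd.Series(counts, name="n_clocks").sort_index()
    census = census.sort_values(ascending=False, kind="stable")
    levels = census.value_counts().sort_index()
    summary = {
        "n_clocks": len(clocks),
        "n_distinct_cpgs": int(census.size),
        "cpgs_per_overlap_level": {int(k): int(v) for k, v in levels.items()},
    }
    return census, summary
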