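"""Subclock decomposition and the elastic-net Cox meta-clock.

A subclock is the portion of a clock's score attributable to the CpGs of
one co-methylation module: zero every beta outside the module and compute
the clock exactly as published ("published" mode), or take the
module-restricted linear predictor without intercept or calibration
("linear" mode, which sums — with the intercept — to the full linear
predictor).  The meta-clock is an elastic-net-penalized Cox
proportional-hazards model trained on the sample x subclock matrix against
all-cause mortality; the penalty performs the feature selection that picks
which (clock, module) signals carry the mortality signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.base import BaseEstimator
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .clocks import ClockDefinition, compute_clock_score
from .network import GREY, COLOR_SEQUENCE

__all__ = [
    "decompose_subclocks",
    "MetaClockCox",
    "MetaClockModel",
    "SurvivalFit",
    "train_metaclock",
    "score_metaclock",
    "validate_mortality",
]


def _module_order(labels: list[str]) -> list[str]:
    rank = {c: i for i, c in enumerate(COLOR_SEQUENCE)}
    non_grey = sorted(
        (l for l in labels if l != GREY), key=lambda l: (rank.get(l, len(rank)), l)
    )
    return non_grey + ([GREY] if GREY in labels else [])


def decompose_subclocks(
    beta: pd.DataFrame,
    clocks: list[ClockDefinition],
    partition: pd.Series,
    mode: str = "published",
) -> pd.DataFrame:
    """Sample x (clock, module) subclock scores.

    A (clock, module) subclock exists whenever the clock has at least one
    CpG assigned to that module (grey included); clock CpGs missing from
    the partition are treated as grey with a warning.  ``mode="published"``
    zeroes out-of-module betas and scores the clock with its intercept and
    calibration; ``mode="linear"`` returns the bare module-restricted
    linear predictor, whose sum over modules plus the intercept equals the
    full-clock linear predictor.
    """
    if mode not in ("published", "linear"):
        raise ValueError(f"unknown mode {mode!r}")
    columns: dict[tuple[str, str], pd.Series] = {}
    for clock in clocks:
        cpgs = clock.cpgs
        present = [c for c in cpgs if c in beta.index]
        if not present:
            raise ValueError(
                f"clock {clock.name!r} has zero CpGs in the beta matrix"
            )
        labels = {}
        uncovered = []
        for c in cpgs:
            if c in partition.index:
                labels[c] = partition[c]
            else:
                labels[c] = GREY
                uncovered.append(c)
        if uncovered:
            warnings.warn(
                f"clock {clock.name!r}: {len(uncovered)} CpG(s) not covered "
                "by the partition; treated as grey",
                stacklevel=2,
            )
        modules = _module_order(sorted(set(labels.values())))
        sub = beta.loc[present].astype(float)
        w = pd.Series(clock.weights).loc[present]
        for module in modules:
            members = [c for c in present if labels[c] == module]
            if not any(labels[c] == module for c in cpgs):
                continue
            if mode == "linear":
                if members:
                    lp = sub.loc[members].T.to_numpy() @ w.loc[members].to_numpy()
                else:
                    lp = np.zeros(beta.shape[1])
                columns[(clock.name, module)] = pd.Series(lp, index=beta.columns)
            else:
                masked = sub.copy()
                masked.loc[[c for c in present if labels[c] != module]] = 0.0
                columns[(clock.name, module)] = compute_clock_score(
                    masked, clock, missing_policy="zero"
                )
    out = pd.DataFrame(columns)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["clock", "module"])
    return out


# ---------------------------------------------------------------------------
# Breslow partial likelihood machinery (used for lambda = 0 and CV scoring)


def _as_time_event(y) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(y, pd.DataFrame):
        return y["time"].to_numpy(float), y["event"].to_numpy(int)
    arr = np.asarray(y)
    if arr.dtype.names:  # sksurv structured array: (event, time)
        ev_f, t_f = arr.dtype.names
        return arr[t_f].astype(float), arr[ev_f].astype(int)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0].astype(float), arr[:, 1].astype(int)
    raise ValueError("y must carry time and event")


def breslow_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow log partial likelihood of a linear predictor."""
    order = np.argsort(time, kind="stable")
    t, d, x = time[order], event[order], lp[order]
    e = np.exp(x)
    # suffix sums: risk set of t_i is everyone with t_j >= t_i
    s0 = np.cumsum(e[::-1])[::-1]
    # with ties, all tied subjects share the risk set starting at the first
    first = np.searchsorted(t, t, side="left")
    ll = np.sum(d * (x - np.log(s0[first])))
    return float(ll)


def _newton_cox(
    X: np.ndarray, time: np.ndarray, event: np.ndarray,
    tol: float = 1e-10, max_iter: int = 50,
) -> np.ndarray:
    """Unpenalized Cox fit (Breslow ties) by Newton-Raphson."""
    n, p = X.shape
    beta = np.zeros(p)
    order = np.argsort(time, kind="stable")
    t, d = time[order], event[order]
    Xs = X[order]
    first = np.searchsorted(t, t, side="left")
    for _ in range(max_iter):
        e = np.exp(Xs @ beta)
        s0 = np.cumsum(e[::-1])[::-1]
        s1 = np.cumsum((e[:, None] * Xs)[::-1], axis=0)[::-1]
        s2 = np.cumsum((e[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]))[::-1],
                       axis=0)[::-1]
        mu = s1[first] / s0[first, None]
        grad = (d[:, None] * (Xs - mu)).sum(axis=0)
        V = s2[first] / s0[first, None, None] - mu[:, :, None] * mu[:, None, :]
        H = -(d[:, None, None] * V).sum(axis=0)
        step = np.linalg.solve(H, grad)
        beta = beta - step
        if np.max(np.abs(step)) < tol:
            break
    return beta


@dataclass
class SurvivalFit:
    """Cox fit of survival on a standardized score."""

    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    events: int
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.hr > 0:
            raise ValueError("hazard ratio must be positive")


@dataclass
class MetaClockModel:
    """Serializable meta-clock: standardization + selected coefficients."""

    features: list[tuple[str, str]]  # every training input feature
    means: list[float]
    sds: list[float]
    coefficients: dict[tuple[str, str], float]  # selected features only
    alpha: float  # L1 mixing
    lam: float  # penalty strength at the optimum
    n: int
    events: int
    folds: int
    seed: int
    mode: str = "published"


class MetaClockCox(BaseEstimator):
    """Elastic-net Cox mortality predictor over subclock features.

    Minimizes the negative Breslow log partial likelihood plus
    ``lam * (alpha * ||b||_1 + (1 - alpha) / 2 * ||b||_2^2)`` on features
    standardized to training mean 0 / SD 1.  ``lam="cv"`` picks the penalty
    by k-fold cross-validated partial likelihood (Verweij-van Houwelingen);
    ``lam=0`` is the unpenalized Newton fit.  Exact zeros are reported as
    non-selected.

    Attributes (after fit): ``coef_``, ``feature_names_in_``,
    ``selected_``, ``lambda_``, ``mean_``, ``scale_``, ``cv_path_``.
    """

    def __init__(
        self,
        alpha: float = 0.5,
        lam: float | str = "cv",
        n_folds: int = 5,
        n_lambdas: int = 50,
        lambda_rule: str = "optimal",
        seed: int = 0,
    ):
        self.alpha = alpha
        self.lam = lam
        self.n_folds = n_folds
        self.n_lambdas = n_lambdas
        self.lambda_rule = lambda_rule
        self.seed = seed

    # -- internal ----------------------------------------------------------
    def _standardize(self, X: pd.DataFrame):
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping constant feature(s): {list(X.columns[~keep])[:5]}",
                stacklevel=2,
            )
        return mean[keep], sd[keep], X.loc[:, keep.index[keep]]

    def fit(self, X: pd.DataFrame, y):
        time, event = _as_time_event(y)
        if event.sum() == 0:
            raise ValueError("no events in the training data")
        X = pd.DataFrame(X)
        self.mean_, self.scale_, Xk = self._standardize(X)
        Z = ((Xk - self.mean_) / self.scale_).to_numpy(dtype=float)
        self.feature_names_in_ = list(Xk.columns)
        self.n_, self.n_events_ = len(time), int(event.sum())

        if self.lam == 0:
            beta = _newton_cox(Z, time, event)
            self.lambda_ = 0.0
            self.cv_path_ = None
        elif isinstance(self.lam, (int, float)):
            beta = self._coxnet_at(Z, time, event, float(self.lam))
            self.lambda_ = float(self.lam)
            self.cv_path_ = None
        elif self.lam == "cv":
            beta = self._fit_cv(Z, time, event)
        else:
            raise ValueError(f"lam must be 'cv', 0, or a positive float")
        self.coef_ = pd.Series(beta, index=self.feature_names_in_)
        self.selected_ = [f for f, b in self.coef_.items() if b != 0.0]
        return self

    def _coxnet(self, alphas) -> CoxnetSurvivalAnalysis:
        return CoxnetSurvivalAnalysis(
            l1_ratio=max(self.alpha, 1e-16),
            alphas=alphas,
            normalize=False,
            fit_baseline_model=False,
            max_iter=200000,
        )

    def _coxnet_at(self, Z, time, event, lam: float) -> np.ndarray:
        yv = Surv.from_arrays(event=event.astype(bool), time=time)
        # solve along a short warm-start path ending at lam for stability
        path = np.geomspace(lam * 32, lam, num=8)
        model = self._coxnet(list(path)).fit(Z, yv)
        return model.coef_[:, -1]

    def _fit_cv(self, Z, time, event) -> np.ndarray:
        yv = Surv.from_arrays(event=event.astype(bool), time=time)
        full = CoxnetSurvivalAnalysis(
            l1_ratio=max(self.alpha, 1e-16),
            n_alphas=self.n_lambdas,
            alpha_min_ratio=0.01,
            normalize=False,
            fit_baseline_model=False,
            max_iter=200000,
        ).fit(Z, yv)
        alphas = np.asarray(full.alphas_)

        rng = np.random.default_rng(self.seed)
        folds = np.resize(np.arange(self.n_folds), len(time))
        rng.shuffle(folds)
        # keep at least 2 events per fold
        ev_idx = np.flatnonzero(event)
        for k in range(self.n_folds):
            if event[folds == k].sum() < 2:
                raise ValueError("fewer than 2 events in a CV fold")

        cvpl = np.zeros((self.n_folds, len(alphas)))
        for k in range(self.n_folds):
            tr = folds != k
            mtr = self._coxnet(list(alphas)).fit(Z[tr], yv[tr])
            coefs = mtr.coef_  # p x n_alphas
            for a in range(len(alphas)):
                lp_all = Z @ coefs[:, a]
                ll_all = breslow_loglik(lp_all, time, event)
                ll_tr = breslow_loglik(lp_all[tr], time[tr], event[tr])
                cvpl[k, a] = ll_all - ll_tr
        total = cvpl.sum(axis=0)
        best = int(np.argmax(total))
        if self.lambda_rule == "1se":
            se = cvpl.std(axis=0, ddof=1) * np.sqrt(self.n_folds)
            threshold = total[best] - se[best]
            # alphas_ is decreasing; pick the largest penalty within 1 SE
            candidates = np.flatnonzero(total >= threshold)
            best = int(candidates[0])
        self.lambda_ = float(alphas[best])
        self.cv_path_ = pd.DataFrame(
            {"lambda": alphas, "cv_partial_loglik": total}
        )
        return full.coef_[:, best]

    # -- public ------------------------------------------------------------
    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Linear-predictor score using training standardization."""
        if not hasattr(self, "coef_"):
            raise RuntimeError("fit before predict")
        X = pd.DataFrame(X)
        missing = [f for f in self.feature_names_in_ if f not in X.columns]
        if missing:
            raise ValueError(f"missing model feature(s): {missing[:10]}")
        Z = (X[self.feature_names_in_] - self.mean_) / self.scale_
        return pd.Series(Z.to_numpy() @ self.coef_.to_numpy(), index=X.index,
                         name="metaclock")

    def to_model(self, mode: str = "published") -> MetaClockModel:
        feats = [tuple(f) if isinstance(f, tuple) else (str(f), "")
                 for f in self.feature_names_in_]
        coefs = {
            (tuple(f) if isinstance(f, tuple) else (str(f), "")): float(b)
            for f, b in self.coef_.items() if b != 0.0
        }
        return MetaClockModel(
            features=feats,
            means=[float(v) for v in self.mean_],
            sds=[float(v) for v in self.scale_],
            coefficients=coefs,
            alpha=self.alpha,
            lam=float(self.lambda_),
            n=self.n_,
            events=self.n_events_,
            folds=self.n_folds,
            seed=self.seed,
            mode=mode,
        )


def train_metaclock(
    subclocks: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.5,
    folds: int = 5,
    seed: int = 0,
    lam: float | str = "cv",
) -> MetaClockCox:
    """Fit the meta-clock on a subclock matrix and a survival sample table."""
    info = samples.loc[subclocks.index]
    est = MetaClockCox(alpha=alpha, lam=lam, n_folds=folds, seed=seed)
    return est.fit(subclocks, info[["time", "event"]])


def score_metaclock(model: MetaClockModel, subclocks: pd.DataFrame) -> pd.Series:
    """Score samples with a serialized meta-clock model."""
    cols = list(subclocks.columns)
    missing = [f for f in model.features if f not in cols]
    if missing:
        raise ValueError(f"missing model feature(s): {missing[:10]}")
    score = np.zeros(len(subclocks))
    for f, m, s in zip(model.features, model.means, model.sds):
        b = model.coefficients.get(f, 0.0)
        if b:
            score += b * (subclocks[f].to_numpy(dtype=float) - m) / s
    return pd.Series(score, index=subclocks.index, name="metaclock")


def validate_mortality(
    score: pd.Series,
    samples: pd.DataFrame,
    covariates: tuple[str, ...] = ("age",),
    min_events: int = 10,
) -> SurvivalFit:
    """Standardized hazard ratio of a score in an evaluation sample.

    Cox proportional-hazards fit of (time, event) on the score standardized
    to SD 1 within this sample, with optional covariates (age by default).
    Reports HR per 1 SD with Wald CI and p.
    """
    info = samples.loc[score.index]
    events = int(info["event"].sum())
    if events < min_events:
        raise ValueError(f"only {events} events; need >= {min_events}")
    s = np.asarray(score, dtype=float)
    if s.std(ddof=1) == 0:
        raise ValueError("score is constant; cannot standardize")
    df = pd.DataFrame(
        {"score_z": (s - s.mean()) / s.std(ddof=1)}, index=score.index
    )
    for cov in covariates:
        df[cov] = info[cov].astype(float)
    df["time"] = info["time"].astype(float)
    df["event"] = info["event"].astype(int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # degenerate / separated fits
        raise ValueError(f"Cox fit failed: {exc}") from exc
    summary = cph.summary.loc["score_z"]
    return SurvivalFit(
        hr=float(np.exp(summary["coef"])),
        ci_low=float(np.exp(summary["coef lower 95%"])),
        ci_high=float(np.exp(summary["coef upper 95%"])),
        p=float(summary["p"]),
        n=len(df),
        events=events,
        covariates=tuple(covariates),
    )
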