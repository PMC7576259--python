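"""Consensus weighted correlation-network modules.

Weighted correlation network analysis in the WGCNA tradition: pairwise
feature correlations are soft-thresholded into an adjacency, smoothed by
shared-neighbour structure into a topological overlap matrix (TOM), and
1 - TOM is clustered by average linkage to yield modules.  Consensus modules
across several datasets (e.g., two tissues) come from the elementwise
minimum of quantile-scaled TOMs, so only co-methylation structure present
in every dataset survives.

Conventions: data matrices are features x samples (the beta-matrix layout);
module labels follow the WGCNA colour sequence in decreasing module size,
with "grey" reserved for unassigned features.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .stats import _biweight_deviations, correlation_pvalue

__all__ = [
    "COLOR_SEQUENCE",
    "GREY",
    "correlation_matrix",
    "adjacency",
    "tom_similarity",
    "consensus_tom",
    "pick_soft_threshold",
    "detect_modules",
    "module_eigengene",
    "eigengene_association",
    "ConsensusModuleDetector",
]

GREY = "grey"

# WGCNA's standard colour ordering (grey excluded: it is the unassigned label)
COLOR_SEQUENCE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)


def _module_color(rank: int) -> str:
    if rank < len(COLOR_SEQUENCE):
        return COLOR_SEQUENCE[rank]
    return f"module{rank + 1}"


def correlation_matrix(data: pd.DataFrame, method: str = "bicor") -> pd.DataFrame:
    """Feature-feature correlation of a features x samples matrix.

    ``method="bicor"`` uses biweight midcorrelation with a per-feature
    Pearson fallback (centred values) for features whose MAD degenerates or
    where more than half the weights vanish, matching the pairwise fallback
    rule of the scalar ``bicor``.
    """
    X = data.to_numpy(dtype=float)
    n_feat = X.shape[0]
    if np.any(np.ptp(X, axis=1) == 0):
        bad = data.index[np.ptp(X, axis=1) == 0].tolist()
        raise ValueError(f"constant feature(s): {bad[:5]}{'...' if len(bad) > 5 else ''}")
    if method == "pearson":
        C = np.corrcoef(X)
    elif method == "bicor":
        D = np.empty_like(X)
        n_fallback = 0
        for i in range(n_feat):
            d = _biweight_deviations(X[i])
            if d is None:
                d = X[i] - X[i].mean()
                n_fallback += 1
            D[i] = d
        if n_fallback:
            warnings.warn(
                f"bicor fell back to Pearson for {n_fallback} feature(s)",
                stacklevel=2,
            )
        norms = np.linalg.norm(D, axis=1)
        C = (D / norms[:, None]) @ (D / norms[:, None]).T
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    C = np.clip(C, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=data.index, columns=data.index)


def adjacency(
    data: pd.DataFrame,
    power: float = 6,
    sign_mode: str = "unsigned",
    method: str = "bicor",
) -> pd.DataFrame:
    """Soft-thresholded adjacency from feature correlations.

    unsigned: a_ij = |cor_ij|^p;  signed: a_ij = ((1 + cor_ij) / 2)^p.
    Diagonal forced to 1.
    """
    C = correlation_matrix(data, method=method)
    return adjacency_from_correlation(C, power, sign_mode)


def adjacency_from_correlation(
    cor: pd.DataFrame, power: float = 6, sign_mode: str = "unsigned"
) -> pd.DataFrame:
    if sign_mode == "unsigned":
        A = np.abs(cor.to_numpy()) ** power
    elif sign_mode == "signed":
        A = ((1.0 + cor.to_numpy()) / 2.0) ** power
    else:
        raise ValueError(f"unknown sign mode {sign_mode!r}")
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=cor.index, columns=cor.columns)


def tom_similarity(A: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap of an adjacency matrix.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu; TOM_ii = 1.
    High overlap means i and j share most of their network neighbours even
    if their direct link is modest.
    """
    M = A.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("adjacency must be square and symmetric")
    if M.min() < -1e-12 or M.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    A0 = M.copy()
    np.fill_diagonal(A0, 0.0)
    L = A0 @ A0  # l_ij: the u = i and u = j terms vanish with a zero diagonal
    k = A0.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - A0
    with np.errstate(invalid="ignore", divide="ignore"):
        T = (L + A0) / denom
    T = np.clip(np.nan_to_num(T), 0.0, 1.0)
    np.fill_diagonal(T, 1.0)
    T = (T + T.T) / 2.0
    return pd.DataFrame(T, index=A.index, columns=A.columns)


def consensus_tom(
    toms: list[pd.DataFrame], scale_quantile: float = 0.95
) -> pd.DataFrame:
    """Elementwise minimum of quantile-scaled TOMs.

    Each TOM is multiplied by the scalar that makes its ``scale_quantile``
    of off-diagonal values equal the first input's, then the consensus is
    the elementwise minimum, capped at 1.  Feature sets must match exactly.
    """
    if not toms:
        raise ValueError("need at least one TOM")
    ref = toms[0]
    for t in toms[1:]:
        if not ref.index.equals(t.index):
            diff = ref.index.symmetric_difference(t.index).tolist()
            raise ValueError(f"TOM feature sets differ: {diff[:10]}")
    iu = np.triu_indices(len(ref), k=1)
    ref_q = float(np.quantile(ref.to_numpy()[iu], scale_quantile))
    scaled = []
    for t in toms:
        q = float(np.quantile(t.to_numpy()[iu], scale_quantile))
        factor = ref_q / q if q > 0 else 1.0
        scaled.append(t.to_numpy() * factor)
    cons = np.minimum.reduce(scaled)
    cons = np.clip(cons, 0.0, 1.0)
    np.fill_diagonal(cons, 1.0)
    return pd.DataFrame(cons, index=ref.index, columns=ref.columns)


def pick_soft_threshold(
    data: pd.DataFrame,
    powers: tuple[int, ...] = tuple(range(1, 13)),
    target_r2: float = 0.8,
    sign_mode: str = "unsigned",
    method: str = "bicor",
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft power by the scale-free topology criterion.

    For each candidate power the connectivities ``k_i`` are binned, and
    log10(frequency) is regressed on log10(mean k per bin); the signed fit
    index is ``-sign(slope) * R^2``.  The smallest power reaching
    ``target_r2`` wins; if none does, the power with the highest signed R^2
    is returned with a warning.
    """
    if data.shape[0] < 20 or data.shape[1] < 10:
        raise ValueError("need >= 20 features and >= 10 samples")
    C = correlation_matrix(data, method=method)
    rows = []
    for p in powers:
        A = adjacency_from_correlation(C, p, sign_mode).to_numpy()
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=1)
        if np.ptp(k) == 0:
            raise ValueError("degenerate data: all connectivities equal")
        edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
        which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
        freq = np.bincount(which, minlength=n_bins).astype(float)
        mean_k = np.array(
            [k[which == b].mean() if freq[b] else np.nan for b in range(n_bins)]
        )
        ok = (freq > 0) & (mean_k > 0)
        if ok.sum() < 3:
            r2 = np.nan
        else:
            lx, ly = np.log10(mean_k[ok]), np.log10(freq[ok])
            slope, intercept = np.polyfit(lx, ly, 1)
            resid = ly - (slope * lx + intercept)
            sst = ((ly - ly.mean()) ** 2).sum()
            r2 = -np.sign(slope) * (1 - resid @ resid / sst) if sst > 0 else np.nan
        rows.append({"power": p, "signed_r2": r2, "mean_k": float(k.mean())})
    fit = pd.DataFrame(rows)
    reaching = fit[fit["signed_r2"] >= target_r2]
    if len(reaching):
        chosen = int(reaching["power"].iloc[0])
    elif fit["signed_r2"].isna().all():
        # near-0/1 correlation structure: the fit index is uninformative and
        # the partition is invariant to the power, so take the smallest
        chosen = int(fit["power"].iloc[0])
        warnings.warn(
            "scale-free fit undefined (too few connectivity bins); "
            f"using smallest power {chosen}",
            stacklevel=2,
        )
    else:
        chosen = int(fit.loc[fit["signed_r2"].idxmax(), "power"])
        warnings.warn(
            f"no candidate power reached signed R^2 >= {target_r2}; "
            f"using power {chosen} (max R^2)",
            stacklevel=2,
        )
    return chosen, fit


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 10,
    cut_height_fraction: float = 0.99,
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    The dendrogram is cut at ``cut_height_fraction`` of the maximum merge
    height; branches of at least ``min_module_size`` features become
    modules, labelled by descending size from the WGCNA colour list (ties
    broken by the lowest member feature index); all other features are
    labelled grey.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if len(tom) < 2:
        raise ValueError("need at least 2 features")
    D = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    max_h = Z[:, 2].max()
    cut = cut_height_fraction * max_h
    raw = hierarchy.fcluster(Z, t=cut, criterion="distance")

    feature_pos = {f: i for i, f in enumerate(tom.index)}
    clusters: dict[int, list] = {}
    for f, c in zip(tom.index, raw):
        clusters.setdefault(int(c), []).append(f)
    eligible = [
        (len(members), min(feature_pos[m] for m in members), members)
        for members in clusters.values()
        if len(members) >= min_module_size
    ]
    eligible.sort(key=lambda t: (-t[0], t[1]))
    labels = pd.Series(GREY, index=tom.index, name="module")
    for rank, (_, _, members) in enumerate(eligible):
        labels.loc[members] = _module_color(rank)
    return labels


def module_eigengene(
    data: pd.DataFrame, partition: pd.Series
) -> pd.DataFrame:
    """First principal component per module, one value per sample.

    Features are standardised across samples, the module submatrix is
    decomposed by SVD, and the leading right singular vector — scaled to
    unit variance and sign-oriented so its correlation with the module's
    mean standardised profile is non-negative — is the eigengene.  Grey is
    skipped; modules with no feature present in ``data`` are skipped with a
    warning.
    """
    eig = {}
    for label in _ordered_modules(partition):
        members = partition.index[partition == label]
        present = members.intersection(data.index)
        if len(present) == 0:
            warnings.warn(f"module {label!r}: no features in data; skipped",
                          stacklevel=2)
            continue
        sub = data.loc[present].to_numpy(dtype=float)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        Z = (sub - mu) / sd
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        e = vt[0]
        mean_profile = Z.mean(axis=0)
        if np.dot(e, mean_profile) < 0:
            e = -e
        e = e / e.std(ddof=1)
        eig[label] = e
    return pd.DataFrame(eig, index=data.columns)


def _ordered_modules(partition: pd.Series) -> list[str]:
    sizes = partition[partition != GREY].value_counts()
    order = {c: i for i, c in enumerate(COLOR_SEQUENCE)}
    return sorted(sizes.index, key=lambda l: (order.get(l, len(order)), l))


def eigengene_association(
    eigengenes: pd.DataFrame,
    acceleration: pd.DataFrame,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Partial correlation of eigengenes with clock accelerations given age.

    Both the eigengene and the acceleration are regressed on age; the
    residuals are Pearson-correlated, with a two-sided p on n - 3 degrees
    of freedom.  Returns a long table (module, clock, r, p, n).
    """
    if isinstance(acceleration, pd.Series):
        acceleration = acceleration.to_frame()
    shared = eigengenes.index.intersection(acceleration.index)
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    age = samples.loc[shared, "age"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(shared)), age])

    def _age_resid(v: np.ndarray) -> np.ndarray:
        coef, *_ = np.linalg.lstsq(X, v, rcond=None)
        return v - X @ coef

    rows = []
    for module in eigengenes.columns:
        em = _age_resid(eigengenes.loc[shared, module].to_numpy(dtype=float))
        for clock in acceleration.columns:
            am = _age_resid(acceleration.loc[shared, clock].to_numpy(dtype=float))
            r = float(np.corrcoef(em, am)[0, 1])
            # partial correlation: one covariate costs one df
            n_eff = len(shared) - 1
            rows.append(
                {"module": module, "clock": clock, "r": r,
                 "p": correlation_pvalue(r, n_eff), "n": len(shared)}
            )
    return pd.DataFrame(rows)


class ConsensusModuleDetector(BaseEstimator):
    """Detect consensus correlation modules across one or more datasets.

    scikit-learn-style estimator: ``fit`` takes a list of features x samples
    DataFrames (or a single DataFrame) sharing a feature set, builds
    per-dataset TOMs, forms the consensus TOM, and clusters it.

    Parameters
    ----------
    power : int or "auto"
        Soft-threshold power; "auto" runs the scale-free criterion on the
        first dataset.
    sign_mode : {"unsigned", "signed"}
    correlation : {"bicor", "pearson"}
    min_module_size : int
    cut_height_fraction : float
        Static cut as a fraction of the maximum dendrogram merge height.
    scale_quantile : float
        Quantile used to scale TOMs before the consensus minimum.
    target_r2 : float
        Scale-free fit target for ``power="auto"``.

    Attributes
    ----------
    power_ : int                chosen soft power
    tom_ : DataFrame            consensus TOM
    labels_ : Series            feature -> module colour ("grey" = unassigned)
    module_sizes_ : Series      size per non-grey module
    """

    def __init__(
        self,
        power: int | str = 6,
        sign_mode: str = "unsigned",
        correlation: str = "bicor",
        min_module_size: int = 10,
        cut_height_fraction: float = 0.99,
        scale_quantile: float = 0.95,
        target_r2: float = 0.8,
        candidate_powers: tuple[int, ...] = tuple(range(1, 13)),
    ):
        self.power = power
        self.sign_mode = sign_mode
        self.correlation = correlation
        self.min_module_size = min_module_size
        self.cut_height_fraction = cut_height_fraction
        self.scale_quantile = scale_quantile
        self.target_r2 = target_r2
        self.candidate_powers = candidate_powers

    def fit(self, X, y=None):
        datasets = [X] if isinstance(X, pd.DataFrame) else list(X)
        if not datasets:
            raise ValueError("need at least one dataset")
        ref_index = datasets[0].index
        for d in datasets[1:]:
            if not ref_index.equals(d.index):
                raise ValueError("datasets must share an identical feature set")
        if self.power == "auto":
            self.power_, self.power_fit_ = pick_soft_threshold(
                datasets[0],
                powers=self.candidate_powers,
                target_r2=self.target_r2,
                sign_mode=self.sign_mode,
                method=self.correlation,
            )
        else:
            self.power_ = int(self.power)
        toms = [
            tom_similarity(
                adjacency(d, self.power_, self.sign_mode, self.correlation)
            )
            for d in datasets
        ]
        self.tom_ = consensus_tom(toms, self.scale_quantile) if len(toms) > 1 else toms[0]
        self.labels_ = detect_modules(
            self.tom_, self.min_module_size, self.cut_height_fraction
        )
        self.module_sizes_ = self.labels_[self.labels_ != GREY].value_counts()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Eigengenes of the fitted modules in a features x samples matrix."""
        if not hasattr(self, "labels_"):
            raise RuntimeError("fit before transform")
        return module_eigengene(X, self.labels_)
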