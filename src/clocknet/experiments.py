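"""Designed end-to-end experiments on planted-truth synthetic data.

Each function runs one self-contained study — generate data with known
ground truth, run the relevant pipeline stages, measure recovery — and
returns plain numbers.  They double as the package's validation battery:
module recovery, elastic-net Cox feature selection, meta-clock dominance
over single clocks, and covariate-adjusted contrast calibration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .clocks import score_clocks
from .metaclock import MetaClockCox, decompose_subclocks, train_metaclock, validate_mortality
from .network import GREY, ConsensusModuleDetector
from .simulate import ClockSpec, ModuleSpec, default_design, simulate_methylation, simulate_clocks, simulate_survival
from .stats import condition_contrast

__all__ = [
    "module_recovery_experiment",
    "coxnet_selection_trial",
    "metaclock_dominance_trial",
    "contrast_recovery_trial",
]


def module_recovery_experiment(
    seed: int = 1,
    power: int = 6,
    min_module_size: int = 10,
    cut_height_fraction: float = 0.99,
    tissue_specific_block: bool = True,
) -> dict:
    """Consensus module detection against the planted partition.

    Runs the default two-tissue design (5 shared modules x 60 CpGs + 200
    noise CpGs, 200 samples per tissue), optionally adding a sixth module
    planted in only one tissue.  Reports the adjusted Rand index of the
    consensus partition against truth on the shared features, and the
    fraction of the tissue-specific block left grey by the consensus.
    """
    design = default_design(seed=seed)
    if tissue_specific_block:
        import dataclasses

        design = dataclasses.replace(
            design,
            modules=design.modules
            + (ModuleSpec("Mspecific", 60, age_effect=0.3, tissues=("blood",)),),
        )
    betas, samples, truth = simulate_methylation(design)
    det = ConsensusModuleDetector(
        power=power,
        min_module_size=min_module_size,
        cut_height_fraction=cut_height_fraction,
    ).fit([betas[t] for t in sorted(betas)])

    shared_labels = {m.label for m in design.modules if m.tissues is None} | {GREY}
    shared = truth.partition.index[truth.partition.isin(shared_labels)]
    ari = adjusted_rand_score(
        truth.partition.loc[shared].to_numpy(), det.labels_.loc[shared].to_numpy()
    )
    out = {
        "ari": float(ari),
        "n_modules": int(det.module_sizes_.size),
        "module_sizes": {str(k): int(v) for k, v in det.module_sizes_.items()},
    }
    if tissue_specific_block:
        spec_cpgs = truth.partition.index[truth.partition == "Mspecific"]
        out["tissue_specific_grey_fraction"] = float(
            (det.labels_.loc[spec_cpgs] == GREY).mean()
        )
    return out


def coxnet_selection_trial(
    seed: int,
    n: int = 1500,
    n_features: int = 20,
    n_causal: int = 2,
    log_hr: float = 0.4,
    alpha: float = 0.5,
    lambda_rule: str = "1se",
) -> dict:
    """Feature recovery of the elastic-net Cox on a sparse hazard.

    Standard-normal features; the first ``n_causal`` carry ``log_hr`` per
    SD; exponential event times with uniform censoring.  Reports whether
    all causal features were selected with the correct sign, and the
    number of null features selected.
    """
    rng = np.random.default_rng([100, seed])
    X = rng.standard_normal((n, n_features))
    lp = log_hr * X[:, :n_causal].sum(axis=1)
    T = -np.log(rng.uniform(size=n)) / (0.07 * np.exp(lp))
    C = rng.uniform(0, np.quantile(T, 0.99) * 1.2, size=n)
    time, event = np.minimum(T, C), (T <= C).astype(int)
    Xdf = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)])
    est = MetaClockCox(alpha=alpha, lam="cv", lambda_rule=lambda_rule,
                       seed=seed).fit(Xdf, np.column_stack([time, event]))
    causal = [f"f{i}" for i in range(n_causal)]
    selected = set(est.selected_)
    return {
        "causal_selected": all(c in selected for c in causal),
        "signs_correct": all(est.coef_[c] > 0 for c in causal if c in selected),
        "false_positives": len(selected - set(causal)),
        "lambda": float(est.lambda_),
    }


def metaclock_dominance_trial(
    seed: int,
    n_per_tissue: int = 750,
    n_train: int = 1000,
    gamma: float = 0.7,
    n_clocks: int = 5,
    cpgs_per_module: int = 8,
) -> dict:
    """Full-pipeline comparison of the meta-clock against single clocks.

    The mortality signal lives in one module (M1); every synthetic clock
    mixes M1 CpGs with CpGs from the four null modules, diluting the
    signal.  Consensus modules are detected, subclocks decomposed, the
    meta-clock trained on ``n_train`` samples, and standardized
    age-adjusted hazard ratios compared on the held-out samples.
    """
    design = default_design(
        seed=seed,
        n_samples_per_tissue=n_per_tissue,
        causal_modules={"M1": gamma},
        censoring_fraction=0.3,
    )
    betas, samples, truth = simulate_methylation(design)
    samples = simulate_survival(truth, samples, design)
    specs = [
        ClockSpec(
            f"clock{k + 1}",
            cpgs_per_module={m.label: cpgs_per_module for m in design.modules},
        )
        for k in range(n_clocks)
    ]
    clocks = simulate_clocks(truth, specs, betas, samples, seed=seed)
    det = ConsensusModuleDetector(power=6).fit([betas[t] for t in sorted(betas)])
    beta_all = pd.concat([betas[t] for t in sorted(betas)], axis=1)[samples.index]
    sub = decompose_subclocks(beta_all, clocks, det.labels_)

    rng = np.random.default_rng(seed)
    idx = rng.permutation(samples.index.to_numpy())
    train_idx, val_idx = idx[:n_train], idx[n_train:]
    est = train_metaclock(sub.loc[train_idx], samples, seed=seed)
    hr_meta = validate_mortality(est.predict(sub.loc[val_idx]), samples).hr
    scores = score_clocks(beta_all, clocks)
    hr_clocks = {
        c: validate_mortality(scores.loc[val_idx, c], samples).hr
        for c in scores.columns
    }
    return {
        "hr_metaclock": float(hr_meta),
        "hr_single_clocks": {k: float(v) for k, v in hr_clocks.items()},
        "dominates": bool(all(hr_meta > v for v in hr_clocks.values())),
        "n_selected": len(est.selected_),
        "n_subclocks": sub.shape[1],
    }


def contrast_recovery_trial(
    seed: int,
    n: int = 200,
    shift: float = 0.5,
) -> dict:
    """Tumor-shift recovery under tissue and age confounding.

    Scores carry a tissue offset and an age trend; tumor status is more
    likely in one tissue and at older ages (genuine confounding), and adds
    ``shift`` score units.  The covariate-adjusted contrast should recover
    the shift; with ``shift = 0`` its p-value is a draw from the null.
    """
    rng = np.random.default_rng([200, seed])
    age = rng.uniform(20, 90, size=n)
    tissue = np.where(rng.uniform(size=n) < 0.5, "colon", "breast")
    p_tumor = 0.25 + 0.3 * (tissue == "breast") + 0.3 * (age - 20) / 70
    tumor = rng.uniform(size=n) < p_tumor
    score = (
        0.1 * age + 3.0 * (tissue == "breast") + shift * tumor
        + rng.normal(0, 1.0, size=n)
    )
    idx = pd.Index([f"s{i}" for i in range(n)])
    samples = pd.DataFrame(
        {
            "age": age,
            "tissue": tissue,
            "condition": np.where(tumor, "tumor", "normal"),
        },
        index=idx,
    )
    res = condition_contrast(
        pd.Series(score, index=idx), samples,
        condition="condition", reference="normal",
        covariates=("tissue", "age"),
    )[0]
    return {
        "estimate": res.effect,
        "se": res.se,
        "p": res.p,
        "ci_covers": abs(res.effect - shift) <= 1.96 * res.se,
    }
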