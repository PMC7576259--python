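"""Synthetic multi-tissue methylation, expression, and survival data.

Generates datasets with planted modular structure so the whole pipeline —
clock scoring, consensus module detection, subclock decomposition, the
elastic-net Cox meta-clock, and the validation statistics — can be exercised
end to end with known ground truth.

Generative model
----------------
Each co-methylation module ``m`` has a per-sample latent factor

    f_m(s) = a_m * (slope_t * age_s + intercept_t) / 10 + eta_ms

where ``a_m`` is the module's age effect per decade on the logit scale,
``(intercept_t, slope_t)`` are the tissue's epigenetic-age offset and rate,
and ``eta_ms`` is Gaussian factor noise.  CpG ``j`` in module ``m`` is

    logit(beta_js) = logit(mu_j) + lambda_j * f_m(s) + eps_js

mapped through the inverse logit, so beta stays strictly inside (0, 1);
noise CpGs have ``lambda_j = 0``.  Condition shifts (tumor, senescence
stages, mtDNA depletion) add a chosen multiple of a factor's SD to that
factor before any beta or expression value is generated.  Survival times
follow an exponential proportional-hazards model on standardized factors of
the causal modules, with independent uniform censoring calibrated to a
target censoring fraction.  Expression modules are linear read-outs of
linked methylation-module factors on a log2-like scale.

Everything is deterministic given ``design.seed``; each generation stage
draws from its own child stream so adding a stage never perturbs another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clocks import ClockDefinition, horvath_transform
from .network import GREY

__all__ = [
    "TissueSpec",
    "ModuleSpec",
    "ClockSpec",
    "SimulationDesign",
    "SimulationTruth",
    "default_design",
    "simulate_methylation",
    "simulate_clocks",
    "simulate_survival",
    "simulate_expression_and_conditions",
    "simulate_all",
]


@dataclass(frozen=True)
class TissueSpec:
    """A tissue with its own epigenetic-age intercept (years) and slope."""

    name: str
    intercept: float = 0.0
    slope: float = 1.0


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-methylation module.

    ``age_effect`` is the factor's change per decade of (tissue-adjusted)
    age on the logit scale; 0 makes the module age-null.  ``loading_spread``
    is the SD of per-CpG loadings around 1; a fraction ``flip_fraction`` of
    loadings have their sign flipped so age trends are of mixed sign.
    ``tissues=None`` plants the module in every tissue; otherwise CpGs
    behave as pure noise outside the listed tissues.
    """

    label: str
    n_cpgs: int = 60
    age_effect: float = 0.3
    loading_spread: float = 0.2
    flip_fraction: float = 0.3
    tissues: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_cpgs < 1:
            raise ValueError(f"module {self.label!r}: n_cpgs must be >= 1")


@dataclass(frozen=True)
class ClockSpec:
    """Recipe for one synthetic clock.

    ``cpgs_per_module`` says how many CpGs to draw from each named module;
    ``n_noise_cpgs`` adds CpGs drawn from the noise pool.  ``sign``
    "positive" draws half-normal weights, "mixed" draws normal weights.
    The intercept is calibrated so the mean training score equals the mean
    training age (on the calibration scale).
    """

    name: str
    cpgs_per_module: dict[str, int] = field(default_factory=dict)
    n_noise_cpgs: int = 0
    weight_scale: float = 1.0
    sign: str = "positive"
    calibration: str = "identity"
    adult_age: float = 20.0


@dataclass(frozen=True)
class SimulationDesign:
    """Full specification of a synthetic multi-omic study."""

    tissues: tuple[TissueSpec, ...]
    modules: tuple[ModuleSpec, ...]
    n_samples_per_tissue: int = 200
    n_noise_cpgs: int = 200
    noise_sd: float = 0.5
    factor_noise_sd: float = 1.0
    age_range: tuple[float, float] = (20.0, 90.0)
    causal_modules: dict[str, float] = field(default_factory=dict)
    condition_shifts: dict[str, tuple[str, float]] = field(default_factory=dict)
    condition_samples: dict[str, int] = field(default_factory=dict)
    reference_condition: str = "control"
    expression_link: dict[str, tuple[str, float]] = field(default_factory=dict)
    genes_per_expression_module: int = 40
    n_noise_genes: int = 100
    expression_noise_sd: float = 1.0
    censoring_fraction: float = 0.3
    baseline_hazard: float = 0.0693  # median survival ~10 time units at lp=0
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [m.label for m in self.modules]
        if len(set(labels)) != len(labels):
            raise ValueError("module labels must be unique")
        unknown = set(self.causal_modules) - set(labels)
        if unknown:
            raise ValueError(f"causal_modules not in design: {sorted(unknown)}")
        for cond, (mod, _) in self.condition_shifts.items():
            if mod not in labels:
                raise ValueError(
                    f"condition {cond!r} shifts unknown module {mod!r}"
                )
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring fraction must be in [0, 1)")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass
class SimulationTruth:
    """Planted ground truth: the answer key for every pipeline stage."""

    partition: pd.Series  # CpG -> module label, noise CpGs grey
    factors: pd.DataFrame  # samples x modules (post condition-shift)
    factor_sd: pd.Series  # SD of each factor before shifts
    loadings: pd.Series  # CpG -> lambda_j (0 for noise CpGs)
    baselines: pd.Series  # CpG -> mu_j on the beta scale
    causal_effects: dict[str, float]  # module -> log-hazard per SD
    conditions: pd.Series | None  # sample -> condition label


def default_design(seed: int = 1, **overrides) -> SimulationDesign:
    """The reference study: 5 modules x 60 CpGs + 200 noise CpGs, two
    tissues x 200 samples, age effects of mixed sign including one null
    module."""
    design = SimulationDesign(
        tissues=(
            TissueSpec("blood", intercept=0.0, slope=1.0),
            TissueSpec("brain", intercept=8.0, slope=0.6),
        ),
        modules=(
            ModuleSpec("M1", 60, age_effect=0.40),
            ModuleSpec("M2", 60, age_effect=-0.30),
            ModuleSpec("M3", 60, age_effect=0.25),
            ModuleSpec("M4", 60, age_effect=0.0),
            ModuleSpec("M5", 60, age_effect=0.35),
        ),
        n_samples_per_tissue=200,
        n_noise_cpgs=200,
        seed=seed,
    )
    return replace(design, **overrides) if overrides else design


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_methylation(
    design: SimulationDesign,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, SimulationTruth]:
    """Generate per-tissue beta matrices, the sample table, and the truth.

    Condition labels (if the design declares any) are assigned here, and
    their factor shifts are applied before betas are generated, so every
    downstream data modality sees the same shifted factors.
    """
    rng = design.rng(stage=1)
    n_per = design.n_samples_per_tissue
    tissues = list(design.tissues)
    n_total = n_per * len(tissues)

    sample_ids = [f"s{idx:04d}" for idx in range(n_total)]
    tissue_col = np.repeat([t.name for t in tissues], n_per)
    ages = rng.uniform(*design.age_range, size=n_total)

    samples = pd.DataFrame(
        {"age": ages, "tissue": tissue_col}, index=pd.Index(sample_ids, name="sample_id")
    )

    # condition assignment: random within the whole cohort (age-matched in
    # expectation); remaining samples take the reference label
    conditions = None
    if design.condition_samples:
        labels = np.array([design.reference_condition] * n_total, dtype=object)
        order = rng.permutation(n_total)
        pos = 0
        for cond, n_cond in design.condition_samples.items():
            if pos + n_cond > n_total:
                raise ValueError("condition sample counts exceed cohort size")
            labels[order[pos : pos + n_cond]] = cond
            pos += n_cond
        conditions = pd.Series(labels, index=samples.index, name="condition")
        samples["condition"] = conditions

    # latent module factors
    t_int = np.repeat([t.intercept for t in tissues], n_per)
    t_slope = np.repeat([t.slope for t in tissues], n_per)
    epi_age = t_slope * ages + t_int
    factors = {}
    factor_sd = {}
    for mod in design.modules:
        eta = rng.normal(0.0, design.factor_noise_sd, size=n_total)
        f = mod.age_effect * epi_age / 10.0 + eta
        sd = float(np.std(f, ddof=1)) or 1.0
        factor_sd[mod.label] = sd
        factors[mod.label] = f
    factors = pd.DataFrame(factors, index=samples.index)
    factor_sd = pd.Series(factor_sd)

    # condition shifts, in SD units of the unshifted factor
    if conditions is not None:
        for cond, (mod, shift) in design.condition_shifts.items():
            mask = (conditions == cond).to_numpy()
            factors.loc[mask, mod] += shift * factor_sd[mod]

    # per-CpG loadings and baselines
    cpg_ids, labels, lam, mu = [], [], [], []
    for mod in design.modules:
        for j in range(mod.n_cpgs):
            cpg_ids.append(f"cg_{mod.label}_{j:04d}")
            labels.append(mod.label)
            l = 1.0 + mod.loading_spread * rng.standard_normal()
            if rng.random() < mod.flip_fraction:
                l = -l
            lam.append(l)
            mu.append(rng.uniform(0.2, 0.8))
    for j in range(design.n_noise_cpgs):
        cpg_ids.append(f"cg_noise_{j:04d}")
        labels.append(GREY)
        lam.append(0.0)
        mu.append(rng.uniform(0.2, 0.8))
    partition = pd.Series(labels, index=pd.Index(cpg_ids, name="cpg"), name="module")
    loadings = pd.Series(lam, index=partition.index, name="loading")
    baselines = pd.Series(mu, index=partition.index, name="baseline")

    module_of = partition.to_dict()
    mod_tissues = {m.label: m.tissues for m in design.modules}

    betas = {}
    for t_idx, tis in enumerate(tissues):
        cols = samples.index[samples["tissue"] == tis.name]
        F = factors.loc[cols]
        eps = rng.normal(0.0, design.noise_sd, size=(len(cpg_ids), len(cols)))
        logit_mu = _logit(baselines.to_numpy())[:, None]
        signal = np.zeros_like(eps)
        for i, cpg in enumerate(cpg_ids):
            m = module_of[cpg]
            if m == GREY:
                continue
            allowed = mod_tissues[m]
            if allowed is not None and tis.name not in allowed:
                continue  # module absent from this tissue: CpG is noise here
            signal[i] = loadings.iloc[i] * F[m].to_numpy()
        B = _expit(logit_mu + signal + eps)
        B = np.clip(B, 1e-12, 1 - 1e-12)
        betas[tis.name] = pd.DataFrame(B, index=partition.index, columns=cols)

    truth = SimulationTruth(
        partition=partition,
        factors=factors,
        factor_sd=factor_sd,
        loadings=loadings,
        baselines=baselines,
        causal_effects=dict(design.causal_modules),
        conditions=conditions,
    )
    return betas, samples, truth


def simulate_clocks(
    truth: SimulationTruth,
    specs: list[ClockSpec],
    betas: dict[str, pd.DataFrame],
    samples: pd.DataFrame,
    seed: int = 0,
) -> list[ClockDefinition]:
    """Build sparse synthetic clocks drawing CpGs from planted modules.

    The intercept of each clock is set so that the mean score over all
    simulated samples equals the mean age (after mapping ages through the
    clock's calibration), mimicking a clock trained on this cohort.
    """
    rng = np.random.default_rng([seed, 2])
    beta_all = pd.concat([betas[t] for t in sorted(betas)], axis=1)
    beta_all = beta_all.loc[:, samples.index]
    ages = samples["age"].to_numpy(dtype=float)

    by_module: dict[str, list[str]] = {}
    for cpg, m in truth.partition.items():
        by_module.setdefault(m, []).append(cpg)

    clocks = []
    for spec in specs:
        chosen: list[str] = []
        for mod, n in spec.cpgs_per_module.items():
            pool = by_module.get(mod, [])
            if n > len(pool):
                raise ValueError(
                    f"clock {spec.name!r}: requested {n} CpGs from module "
                    f"{mod!r} but only {len(pool)} exist"
                )
            chosen += list(rng.choice(pool, size=n, replace=False))
        if spec.n_noise_cpgs:
            pool = by_module.get(GREY, [])
            if spec.n_noise_cpgs > len(pool):
                raise ValueError(
                    f"clock {spec.name!r}: requested {spec.n_noise_cpgs} noise "
                    f"CpGs but only {len(pool)} exist"
                )
            chosen += list(rng.choice(pool, size=spec.n_noise_cpgs, replace=False))
        if spec.sign == "positive":
            w = np.abs(rng.normal(0.0, spec.weight_scale, size=len(chosen)))
        elif spec.sign == "mixed":
            w = rng.normal(0.0, spec.weight_scale, size=len(chosen))
        else:
            raise ValueError(f"unknown sign rule {spec.sign!r}")
        # align weight sign with the CpG's loading so module CpGs pull the
        # score the same way the factor moves
        for i, cpg in enumerate(chosen):
            lam = truth.loadings[cpg]
            if lam != 0 and spec.sign == "positive":
                w[i] *= np.sign(lam)
        lp = beta_all.loc[chosen].T.to_numpy() @ w
        if spec.calibration == "horvath":
            target = horvath_transform(ages, spec.adult_age).mean()
        else:
            target = ages.mean()
        intercept = float(target - lp.mean())
        clocks.append(
            ClockDefinition(
                name=spec.name,
                intercept=intercept,
                weights=dict(zip(chosen, w.astype(float))),
                calibration=spec.calibration,
                adult_age=spec.adult_age,
            )
        )
    return clocks


def simulate_survival(
    truth: SimulationTruth,
    samples: pd.DataFrame,
    design: SimulationDesign,
) -> pd.DataFrame:
    """Attach (time, event) columns driven by the causal module factors.

    Event times are exponential with hazard ``h0 * exp(sum_m gamma_m *
    z_m(s))`` over standardized factors of the causal modules.  Censoring
    times are independent uniform on (0, c]; the scale ``c`` is found by
    bisection so the realized censoring fraction matches the design target.
    """
    rng = design.rng(stage=3)
    n = len(samples)
    lp = np.zeros(n)
    for mod, gamma in design.causal_modules.items():
        f = truth.factors.loc[samples.index, mod].to_numpy()
        z = (f - f.mean()) / f.std(ddof=1)
        lp += gamma * z
    u = rng.uniform(size=n)
    T = -np.log(u) / (design.baseline_hazard * np.exp(lp))

    out = samples.copy()
    if design.censoring_fraction == 0:
        out["time"] = T
        out["event"] = 1
        return out

    u2 = rng.uniform(size=n)

    def realized_censoring(c: float) -> float:
        return float(np.mean(T > c * u2))

    lo, hi = 1e-9, float(T.max()) * 10
    # censoring fraction decreases in c; bisect to the target
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if realized_censoring(mid) > design.censoring_fraction:
            lo = mid
        else:
            hi = mid
    C = 0.5 * (lo + hi) * u2
    event = (T <= C).astype(int)
    if event.sum() == 0:
        warnings.warn("all samples censored; survival data carry no events",
                      stacklevel=2)
    out["time"] = np.minimum(T, C)
    out["event"] = event
    return out


def simulate_expression_and_conditions(
    truth: SimulationTruth,
    samples: pd.DataFrame,
    design: SimulationDesign,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-tissue expression matrices linked to methylation-module factors.

    Gene ``g`` in an expression module linked to methylation module ``m``
    with coefficient ``c`` reads ``x_gs = c_g * f_m(s) + noise`` on a
    log2-like scale, with per-gene coefficients ``c_g`` spread around ``c``.
    The returned sample table carries the condition labels (already planted
    during methylation generation); declaring a shift for a condition that
    no sample carries is a hard error.
    """
    for cond in design.condition_shifts:
        if "condition" not in samples.columns or cond not in set(samples["condition"]):
            raise ValueError(f"condition {cond!r} absent from the sample table")
    rng = design.rng(stage=4)

    gene_ids, gene_coef, gene_module = [], [], []
    for em, (mm, c) in design.expression_link.items():
        if mm not in truth.factors.columns:
            raise ValueError(f"expression module {em!r} links unknown module {mm!r}")
        for g in range(design.genes_per_expression_module):
            gene_ids.append(f"g_{em}_{g:04d}")
            gene_coef.append(c * (1.0 + 0.2 * rng.standard_normal()))
            gene_module.append(mm)
    for g in range(design.n_noise_genes):
        gene_ids.append(f"g_noise_{g:04d}")
        gene_coef.append(0.0)
        gene_module.append(None)

    exprs = {}
    for tis in design.tissues:
        cols = samples.index[samples["tissue"] == tis.name]
        X = rng.normal(0.0, design.expression_noise_sd,
                       size=(len(gene_ids), len(cols)))
        for i, (c, mm) in enumerate(zip(gene_coef, gene_module)):
            if mm is not None:
                X[i] += c * truth.factors.loc[cols, mm].to_numpy()
        exprs[tis.name] = pd.DataFrame(
            X, index=pd.Index(gene_ids, name="gene"), columns=cols
        )
    return exprs, samples.copy()


def simulate_all(design: SimulationDesign, clock_specs: list[ClockSpec] | None = None):
    """Run every generation stage; returns a dict of all artifacts."""
    betas, samples, truth = simulate_methylation(design)
    out = {"betas": betas, "samples": samples, "truth": truth, "design": design}
    if design.causal_modules:
        out["samples"] = simulate_survival(truth, samples, design)
    if design.expression_link or design.condition_shifts:
        exprs, out["samples"] = simulate_expression_and_conditions(
            truth, out["samples"], design
        )
        out["expression"] = exprs
    if clock_specs:
        out["clocks"] = simulate_clocks(truth, clock_specs, betas, out["samples"],
                                        seed=design.seed)
    return out
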