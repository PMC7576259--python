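# clocknet

Epigenetic clocks — sparse linear predictors over CpG methylation beta
values — each capture a different slice of biological aging, and their
scores often correlate only weakly with one another.  `clocknet` is a
pipeline for dissecting *why*: it scores any collection of clocks on
methylation data, finds consensus co-methylation modules across tissues,
decomposes each clock into module-level **subclocks**, and recombines those
subclocks into a single mortality-trained **meta-clock** via elastic-net Cox
regression.  It is aimed at epigenomics researchers comparing aging
biomarkers, and ships a synthetic-data generator with planted ground truth
so every stage is testable without access to restricted cohort data.

## The model in brief

A clock scores sample *s* as
`DNAmAge_s = F⁻¹(intercept + Σ_j w_j β_js)`, where `β_js ∈ [0,1]` is
methylation at CpG *j* and `F` is an optional log-linear age calibration
with a knee at `adult_age`.  **Age acceleration** is the residual of the
score regressed on chronological age within a tissue.

Modules come from weighted correlation network analysis: adjacency
`a_ij = |cor_ij|^p` (biweight midcorrelation by default), smoothed into the
topological overlap matrix
`TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`, with consensus across
datasets taken as the elementwise minimum of quantile-scaled TOMs;
`1 − TOM` is clustered by average linkage with a static height cut, and
branches below the minimum size fall into the unassigned "grey" label.

The **subclock** for (clock *c*, module *m*) zeroes every beta outside *m*
and recomputes *c* exactly as published, isolating the part of the clock's
signal carried by that module.  The **meta-clock** is an elastic-net
penalized Cox proportional-hazards fit over standardized subclocks against
all-cause mortality; the penalty
`λ(α‖b‖₁ + (1−α)/2 ‖b‖₂²)` performs feature selection, with λ chosen by
cross-validated partial likelihood.

## Worked example

```python
import pandas as pd
import clocknet as cn

# plant a study: 5 co-methylation modules shared by blood and brain,
# mortality driven by module M1
design = cn.default_design(seed=0, n_samples_per_tissue=750,
                           causal_modules={"M1": 0.7},
                           censoring_fraction=0.3)
betas, samples, truth = cn.simulate_methylation(design)
samples = cn.simulate_survival(truth, samples, design)

# five synthetic clocks, each mixing the causal module with null modules
specs = [cn.ClockSpec(f"clock{k+1}",
                      cpgs_per_module={m.label: 8 for m in design.modules})
         for k in range(5)]
clocks = cn.simulate_clocks(truth, specs, betas, samples, seed=0)

# consensus modules across the two tissues
det = cn.ConsensusModuleDetector(power=6).fit([betas["blood"], betas["brain"]])
print("consensus modules:", dict(det.module_sizes_))

# decompose clocks into subclocks and train the meta-clock
beta_all = pd.concat([betas["blood"], betas["brain"]], axis=1)[samples.index]
sub = cn.decompose_subclocks(beta_all, clocks, det.labels_)
train, val = samples.index[:1000], samples.index[1000:]
est = cn.train_metaclock(sub.loc[train], samples, seed=0)
print(f"selected {len(est.selected_)} of {sub.shape[1]} subclocks")

# validate: standardized, age-adjusted hazard ratios on held-out samples
fit = cn.validate_mortality(est.predict(sub.loc[val]), samples)
print(f"meta-clock HR per SD: {fit.hr:.2f} "
      f"[{fit.ci_low:.2f}, {fit.ci_high:.2f}], p = {fit.p:.1e}")
```

prints

```
consensus modules: {'turquoise': 60, 'blue': 60, 'brown': 60, 'yellow': 60, 'green': 60}
selected 11 of 25 subclocks
meta-clock HR per SD: 2.08 [1.75, 2.46], p = 3.9e-17
```

All five planted modules are recovered exactly; the penalized Cox fit keeps
11 of the 25 (clock, module) subclocks; and the meta-clock predicts
mortality on held-out samples with a hazard ratio of 2.08 per standard
deviation — roughly double that of the best single clock (1.08–1.13 on the
same validation split), because each single clock dilutes the causal module
with four null ones while the subclock decomposition lets the Cox penalty
isolate it.

The same pipeline is available from the shell via the `clocknet` console
script (`simulate`, `score`, `modules`, `subclocks`, `train`, `validate`,
`report` subcommands; run `clocknet --help`).

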