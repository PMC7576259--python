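import numpy as np
import pandas as pd
import pytest

import clocknet as cn


@pytest.fixture(scope="session")
def default_sim():
    """Default planted two-tissue study (5 modules x 60 CpGs + 200 noise)."""
    design = cn.default_design(seed=1, causal_modules={"M1": 0.5})
    betas, samples, truth = cn.simulate_methylation(design)
    samples = cn.simulate_survival(truth, samples, design)
    return {"design": design, "betas": betas, "samples": samples, "truth": truth}


@pytest.fixture(scope="session")
def beta_all(default_sim):
    b = default_sim["betas"]
    return pd.concat([b[t] for t in sorted(b)], axis=1)[
        default_sim["samples"].index
    ]


@pytest.fixture
def tiny_beta():
    return pd.DataFrame(
        {"s1": [0.2, 0.6, 0.9], "s2": [0.1, 0.5, 0.4]},
        index=["cg1", "cg2", "cg3"],
    )


@pytest.fixture
def three_cpg_clock():
    return cn.ClockDefinition(
        "toy", intercept=1.0, weights={"cg1": 0.5, "cg2": -1.0, "cg3": 2.0}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)
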