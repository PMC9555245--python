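import numpy as np
import pytest
from hypothesis import settings

from bootce import (EconParams, GridSpec, TrialGenConfig, generate_trial,
                    mean_difference_test, run_grid)

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def calibrated_dataset():
    """The default 710-patient trial, moment-matched to an LDL diff of -5."""
    return generate_trial(TrialGenConfig())


@pytest.fixture(scope="session")
def calibrated_results(calibrated_dataset):
    """Full default grid: sizes 100..700, 500 bootstrap replicates each."""
    return run_grid(calibrated_dataset, GridSpec(), econ=EconParams())


@pytest.fixture(scope="session")
def null_pvalues():
    """Welch p-values for a truly null outcome across 500 fresh trials.

    Each replicate generates an independent 100-patient trial with all
    between-arm effects set to zero and tests the (stochastic, not
    moment-matched) SBP outcome.
    """
    pvals = []
    for rep in range(500):
        cfg = TrialGenConfig(
            n_total=100, effect_ldl=0.0, effect_sbp=0.0, effect_bmi=0.0,
            smoking_risk_ratio=1.0, seed=10_000 + rep,
        )
        est = mean_difference_test(generate_trial(cfg), "sbp")
        pvals.append(est.p_value)
    return np.asarray(pvals)
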