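import numpy as np
import pytest

from cychyp import gen_cell_line_experiment, gen_cohort, Signature


@pytest.fixture(scope="session")
def small_experiment():
    """6 cell lines, 300 probes, 30 planted differential probesets."""
    return gen_cell_line_experiment(n_lines=6, n_probes=300, n_planted=30,
                                    effect_size=1.0, noise_sd=0.5, seed=7)


@pytest.fixture(scope="session")
def planted_cohorts():
    """Training + validation cohorts driven by a latent activity (HR 2/SD)."""
    probes = [f"S{i:03d}" for i in range(30)]
    train, truth = gen_cohort(200, probes, hr_per_sd=2.0, censor_rate=0.3,
                              seed=101, background_probes=100,
                              clinical_link=True)
    valid, _ = gen_cohort(250, probes, hr_per_sd=2.0, censor_rate=0.3,
                          seed=102, background_probes=100, clinical_link=True)
    return Signature(probes, "SYN_CLIN"), train, valid, truth


def random_survival_data(rng, n=40, p_censor=0.35):
    """Small random censored dataset for oracle-equivalence checks."""
    time = rng.exponential(5.0, size=n).round(2)  # rounding forces ties
    event = (rng.random(n) > p_censor).astype(int)
    score = rng.normal(size=n).round(1)
    return score, time, event
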