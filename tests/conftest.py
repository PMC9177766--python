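"""Shared fixtures: small seeded synthetic cohorts and a fitted bundle.

Everything is generated programmatically at test time; session scope keeps
the expensive artifacts to one build per run.
"""

import warnings

import numpy as np
import pytest

import riskdist as rd


@pytest.fixture(scope="session")
def small_world():
    """Fully-observed 3,000-case, 20-hospital cohort with its ground truth."""
    cfg = rd.GeneratorConfig(n_cases=3000, n_hospitals=20, seed=7)
    cohort, true_risks, model = rd.generate_cohort(cfg)
    return {"config": cfg, "cohort": cohort, "true_risks": true_risks,
            "true_model": model}


@pytest.fixture(scope="session")
def observed_cohort(small_world):
    """The same cohort after missingness injection (study rates)."""
    return rd.inject_missingness(small_world["cohort"], small_world["config"])


@pytest.fixture(scope="session")
def big_world():
    """20,000-case cohort at the full 186-hospital structure."""
    cfg = rd.GeneratorConfig(n_cases=20000, n_hospitals=186, seed=11)
    cohort, true_risks, model = rd.generate_cohort(cfg)
    return {"config": cfg, "cohort": cohort, "true_risks": true_risks,
            "true_model": model}


@pytest.fixture(scope="session")
def small_bundle(observed_cohort):
    """A fitted model bundle at reduced imputation counts (m=2, k=2)."""
    cfg = rd.RunConfig(seed=5, imputation={"m_mice": 2, "k_lab": 2})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rd.run_fit(cfg, cohort=observed_cohort.copy())


@pytest.fixture(scope="session")
def medium_bundle():
    """A bundle at a scale where imputation noise is visible against the
    coefficient posterior (12,000 training cases, 60 hospitals)."""
    gen = rd.GeneratorConfig(n_cases=12000, n_hospitals=60, seed=21)
    cohort, _, _ = rd.generate_cohort(gen)
    observed = rd.inject_missingness(cohort, gen)
    cfg = rd.RunConfig(seed=22, imputation={"m_mice": 3, "k_lab": 2})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rd.run_fit(cfg, cohort=observed)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
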