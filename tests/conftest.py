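import numpy as np
import pandas as pd
import pytest

from survsig import ClinicalRecord, Cohort, SimulationConfig, simulate_cohort


def make_cohort(X, times, events, name="toy", genes=None, samples=None, subtypes=None):
    """Build a Cohort from raw arrays (genes x samples)."""
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{i}" for i in range(X.shape[0])]
    samples = samples or [f"s{i}" for i in range(X.shape[1])]
    subtypes = subtypes or [None] * len(samples)
    expr = pd.DataFrame(X, index=genes, columns=samples)
    clinical = [
        ClinicalRecord(s, float(t), int(e), sub)
        for s, t, e, sub in zip(samples, times, events, subtypes)
    ]
    return Cohort(name, expr, clinical)


@pytest.fixture
def toy_cohort():
    rng = np.random.default_rng(42)
    X = rng.normal(7, 1, size=(5, 12))
    t = rng.exponential(5, 12)
    e = rng.integers(0, 2, 12)
    e[0] = 1
    return make_cohort(X, t, e)


@pytest.fixture(scope="session")
def planted_cohort():
    """One simulated cohort with strong planted structure, shared by tests."""
    cfg = SimulationConfig(n_genes=120, n_planted=10, effect_size=0.5,
                           group_shift=1.5, n_samples_per_cohort=(120,), seed=7)
    cohort, truth = simulate_cohort(cfg, 0)
    return cohort, truth
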