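import numpy as np
import pytest

from upscreen import ICMetric, ModelRecord, ParameterEstimate, SimConfig, run_experiment
from upscreen.fixtures import (florican_models, journal_totals, review_records,
                               warbler_models)


@pytest.fixture
def warblers():
    """The seven-model warbler colonization set with published estimates."""
    return warbler_models()


@pytest.fixture
def floricans():
    return florican_models()


@pytest.fixture
def review():
    return review_records(), journal_totals()


@pytest.fixture(scope="session")
def reference_sim():
    """The reference simulation: gaussian, n=500, one true effect (beta=1),
    one true-zero covariate, 2000 replicates.  Shared across tests because
    the operating characteristics and the distributional check both read
    from the same run."""
    return run_experiment(SimConfig(n=500, family="gaussian",
                                    true_terms={"x1": 1.0}, null_terms=("z1",),
                                    replicates=2000, seed=0))


def random_model_set(rng: np.random.Generator, max_models: int = 10,
                     universe: tuple[str, ...] = ("a", "b", "c", "d", "e")):
    """A random candidate model set with plausible logliks, K and (sometimes)
    estimates; used against the naive screening oracle."""
    n_models = rng.integers(1, max_models + 1)
    models, seen = [], set()
    for i in range(n_models):
        terms = frozenset(t for t in universe if rng.random() < 0.5)
        if terms in seen:
            continue
        seen.add(terms)
        # base fit improves loosely with size; jitter keeps IC gaps realistic
        loglik = -100.0 + 0.8 * len(terms) + rng.normal(0, 1.5)
        K = len(terms) + 1 + int(rng.random() < 0.3)  # sometimes a scale/extra level
        estimates = {}
        for t in terms:
            if rng.random() < 0.7:
                est = rng.normal(0, 0.5)
                half = abs(rng.normal(0, 0.6)) + 0.05
                estimates[t] = ParameterEstimate(est, est - half, est + half)
        models.append(ModelRecord(model_id=f"m{i}", terms=terms, K=K,
                                  loglik=loglik, estimates=estimates))
    return models
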