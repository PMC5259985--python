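import numpy as np
import pytest

from topicmotif import GAParams, PlantSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def planted():
    """The default planted-motif dataset: 6 x 200 bp, 12 copies of an
    8-mer, one substitution each."""
    return generate(PlantSpec(seed=0))


def study_params(seed: int = 0, **overrides) -> GAParams:
    """GA configuration used for the scaled-down planted-motif studies."""
    kw = dict(
        k_min=6, k_max=10, c_min=2, N=20, n=120, generations=15,
        mutation_rate=0.1, max_solutions=10, K=2, seed=seed,
    )
    kw.update(overrides)
    return GAParams(**kw)


def tiny_params(seed: int = 0, **overrides) -> GAParams:
    """Small, fast GA configuration for loop-invariant tests."""
    kw = dict(
        k_min=6, k_max=8, c_min=1, N=10, n=12, generations=10,
        mutation_rate=0.1, max_solutions=10, K=2, seed=seed,
    )
    kw.update(overrides)
    return GAParams(**kw)


def tiny_dataset(seed: int = 0):
    """3 x 120 bp with 6 planted instances (exercises the within-document
    perplexity split used when fewer than four documents are available)."""
    return generate(
        PlantSpec(
            num_sequences=3, seq_length=120, instances_total=6,
            mutations_per_instance=1, seed=seed,
        )
    )
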