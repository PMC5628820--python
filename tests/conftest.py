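import numpy as np
import pandas as pd
import pytest

import phenostrat as ps


def make_matrix(values: dict, labels=None, samples=None) -> ps.PhenotypeMatrix:
    """Build a small PhenotypeMatrix from {feature: list-of-levels}."""
    df = pd.DataFrame(values)
    if samples is None:
        samples = [f"s{i}" for i in range(len(df))]
    df.index = pd.Index(samples, name="sample_id")
    lab = None if labels is None else pd.Series(list(labels), index=df.index)
    return ps.PhenotypeMatrix(df, lab)


@pytest.fixture(scope="session")
def small_spec() -> ps.CohortSpec:
    """A reduced cohort for fast unit tests; same structure as the default."""
    return ps.CohortSpec(
        n_per_class=(30, 25, 20),
        n_nonextreme={("Vata", "Pitta"): 12, ("Pitta", "Kapha"): 10, ("Vata", "Kapha"): 10},
        n_features=40,
        n_informative=24,
        n_blocks=6,
        signal_strength=0.85,
        block_coupling=0.5,
        missing_rate=0.03,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_model(small_spec) -> ps.CohortModel:
    return ps.CohortModel(small_spec)


@pytest.fixture(scope="session")
def small_clean(small_model, small_spec) -> ps.PhenotypeMatrix:
    raw = ps.inject_missing(small_model.generate_extreme(), small_spec.missing_rate,
                            seed=small_spec.seed)
    clean, _ = ps.preprocess_pipeline(raw)
    return clean


@pytest.fixture(scope="session")
def small_dissim(small_clean) -> ps.DissimilarityMatrix:
    return ps.fit_unsupervised_forest(small_clean, ps.ForestConfig(ntree=1500, seed=7))


def informative_ids(spec: ps.CohortSpec) -> set:
    return set(spec.feature_ids[: spec.n_informative])


def random_dissimilarity(n: int, rng: np.random.Generator) -> ps.DissimilarityMatrix:
    a = rng.random((n, n))
    d = (a + a.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return ps.DissimilarityMatrix([f"s{i}" for i in range(n)], d)
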