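import numpy as np
import pytest

import persistnet as pn


@pytest.fixture(scope="session")
def default_fixture():
    """The default 3-cohort planted fixture (seed 7) shared across tests."""
    cfg = pn.SynthConfig(seed=7)
    expressions, traits, truth = pn.generate_cohorts(cfg)
    return cfg, expressions, traits, truth


@pytest.fixture(scope="session")
def normalized_cohorts(default_fixture):
    _, expressions, traits, truth = default_fixture
    return [pn.median_normalize(x) for x in expressions], traits, truth


@pytest.fixture(scope="session")
def detected_modules(normalized_cohorts):
    """Module detection on the reference cohort of the default fixture."""
    Xn, traits, truth = normalized_cohorts
    tom = pn.topological_overlap(pn.adjacency_from_expression(Xn[0], beta=4))
    dend = pn.build_dendrogram(tom)
    assignment = pn.cut_modules(dend, Xn[0].feature_ids, X=Xn[0])
    assignment = pn.merge_modules(Xn[0], assignment)
    return assignment


def random_expression(n_features, n_samples, seed=0, cohort="sim"):
    rng = np.random.default_rng(seed)
    return pn.ExpressionMatrix(
        [f"F{i:03d}" for i in range(n_features)],
        [f"s{j:03d}" for j in range(n_samples)],
        rng.standard_normal((n_features, n_samples)),
        cohort=cohort,
    )
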