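import numpy as np
import pandas as pd
import pytest

from mirpath.diffexp import ExpressionStudy
from mirpath.simulate import generate_planted_bundle


def make_study(values, groups_per_sample, feature_ids=None):
    """Build an ExpressionStudy from a plain array and group labels."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    feats = feature_ids or [f"f{i}" for i in range(n)]
    samples = [f"s{j}" for j in range(m)]
    return ExpressionStudy(
        pd.DataFrame(values, index=feats, columns=samples),
        pd.Series(groups_per_sample, index=samples),
    )


@pytest.fixture
def two_group_study():
    """Deterministic 4-feature, 3+3-replicate study."""
    rng = np.random.default_rng(42)
    base = rng.normal(7, 1, size=(4, 1))
    vals = base + rng.normal(0, 0.3, size=(4, 6))
    vals[0, 3:] += 2.0  # one clearly shifted feature
    return make_study(vals, ["A"] * 3 + ["B"] * 3)


@pytest.fixture(scope="session")
def bundle():
    """Planted-truth synthetic bundle shared by the slower tests."""
    return generate_planted_bundle(seed=3)
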