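import numpy as np
import pytest

from metabrisk.profiles import exclude_metabolites, normalize_total_area
from metabrisk.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort_effect2():
    """Preprocessed synthetic cohort at study conditions: default group sizes,
    effect size 2, 20% PC-like RODM samples, fixed seed."""
    cfg = CohortConfig(seed=7, effect_size=2.0, rodm_pc_fraction=0.2)
    matrix, truth = generate_cohort(cfg)
    matrix = normalize_total_area(
        exclude_metabolites(matrix, ["Glycerol", "Propylene glycol"])
    )
    return matrix, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort for fast structural tests."""
    cfg = CohortConfig(
        group_sizes={"HC": 10, "DM2": 10, "PC I+II": 8, "PC III": 8, "PC IV": 8, "RODM": 12},
        seed=3,
    )
    return generate_cohort(cfg)


@pytest.fixture
def separable_xy():
    """Two Gaussian clusters separated by ~10 sd along the first metabolite."""
    rng = np.random.default_rng(0)
    x = rng.normal(size=(40, 10))
    y = np.array(["A"] * 20 + ["B"] * 20)
    x[:20, 0] -= 5.0
    x[20:, 0] += 5.0
    return x, y


class CentroidSpec:
    """Fast deterministic nearest-centroid model spec for validation tests."""

    def fit(self, x, y):
        import pandas as pd

        classes = pd.unique(y)
        mus = {c: x[y == c].mean(axis=0) for c in classes}
        outer = self

        class _Fitted:
            def predict(self, xt):
                d = np.stack([((xt - mus[c]) ** 2).sum(axis=1) for c in classes])
                return np.asarray(classes)[np.argmin(d, axis=0)]

        return _Fitted()


@pytest.fixture
def centroid_spec():
    return CentroidSpec()
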