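import numpy as np
import pytest

from jnkscreen.descriptors import Standardizer
from jnkscreen.feature_selection import select_features
from jnkscreen.qsar import EnsembleQSARClassifier
from jnkscreen.synthetic_data import SynthSpec, synth_qsar_dataset

# Reduced-size study fixture: same structure as the full 1138/285 × 208
# composition, scaled down so unit tests stay fast. The full composition is
# exercised in the acceptance suite.
SMALL_SPEC = dict(n_active=240, n_inactive=60, n_features=60, n_constant=6,
                  n_duplicated=10, n_independent=12, effect_size=1.0, seed=11)


@pytest.fixture(scope="session")
def small_qsar():
    return synth_qsar_dataset(SynthSpec(**SMALL_SPEC))


@pytest.fixture(scope="session")
def small_selected(small_qsar):
    """Standardized + three-stage-selected matrix of the small fixture."""
    std = Standardizer().fit(small_qsar.matrix)
    matrix, report = select_features(std.transform(small_qsar.matrix),
                                     small_qsar.labels, seed=11)
    return matrix.to_frame(), small_qsar.labels, report


@pytest.fixture(scope="session")
def fitted_ensemble(small_selected):
    X, y, _ = small_selected
    return EnsembleQSARClassifier(meta_folds=3, random_state=11).fit(X, y)


# Scaled-down pipeline configuration shared by orchestration tests.
SMALL_PIPELINE_CONFIG = {
    "seed": 17,
    "synthetic": {
        "qsar": {"n_active": 160, "n_inactive": 40, "n_features": 40,
                 "n_constant": 4, "n_duplicated": 6, "n_independent": 8,
                 "effect_size": 1.0},
        "library": {"n": 300, "fraction_dual_high": 0.15,
                    "admet_pass_fraction": 0.2,
                    "energy_range_kcal": [-9.5, -6.0]},
        "dose_response": {"ic50_um": [12.0, 60.0], "hill": 1.0,
                          "ratio_noise_sd": 0.02},
    },
    "qsar": {"meta_folds": 3},
    "evaluation": {"folds": 3},
    "stages": {"ic50": True},
}


@pytest.fixture()
def small_pipeline_config():
    import copy
    return copy.deepcopy(SMALL_PIPELINE_CONFIG)


@pytest.fixture()
def separable():
    """Linearly separable two-class data (a perfect separator exists)."""
    rng = np.random.default_rng(5)
    y = np.array([0, 1] * 30)
    X = rng.normal(size=(60, 4))
    X[:, 0] += 8.0 * y
    return X, y
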