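import numpy as np
import pytest

from cd_disorder import (
    CDSpectrum,
    ClassifierSpec,
    FeatureMatrix,
    Label,
    LabeledSpectrumSet,
    SyntheticConfig,
    Units,
    generate_set,
)


@pytest.fixture
def tiny_spectrum():
    """Two-point spectrum used for interpolation/unit arithmetic."""
    return CDSpectrum(
        "tiny", np.array([200.0, 201.0]), np.array([-6.0, -5.0]), Units.DELTA_EPSILON
    )


def make_spectrum(pid, lo=175.0, hi=250.0, value_fn=None, units=Units.DELTA_EPSILON):
    wl = np.arange(lo, hi + 0.5)
    if value_fn is None:
        values = -5.0 * np.exp(-0.5 * ((wl - 200.0) / 9.0) ** 2)
    else:
        values = np.array([value_fn(w) for w in wl], dtype=float)
    return CDSpectrum(pid, wl, values, units)


@pytest.fixture
def four_entry_set():
    """2 ordered + 2 disordered spectra with distinct wavelength coverage."""
    return LabeledSpectrumSet(
        [
            (make_spectrum("ord1", 175, 260), Label.ORDERED),
            (make_spectrum("ord2", 198, 260), Label.ORDERED),
            (make_spectrum("dis1", 175, 250), Label.DISORDERED),
            (make_spectrum("dis2", 200, 250), Label.DISORDERED),
        ]
    )


def feature_matrix(X, y, prefix="p"):
    """Build a FeatureMatrix from arrays of features and 0/1 labels."""
    X = np.asarray(X, dtype=float)
    labels = tuple(Label.DISORDERED if c else Label.ORDERED for c in y)
    ids = tuple(f"{prefix}{i}" for i in range(len(labels)))
    return FeatureMatrix(X, labels, ids)


@pytest.fixture(scope="session")
def default_synthetic_set():
    return generate_set(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def knn_cosine_spec():
    return ClassifierSpec.default("knn_cosine")
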