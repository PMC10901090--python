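import numpy as np
import pytest

import gutflux as gf


@pytest.fixture(scope="session")
def regime_k() -> gf.RateConstants:
    return gf.PAPER_REGIME_K


@pytest.fixture(scope="session")
def dose() -> gf.TracerDose:
    return gf.TracerDose()


@pytest.fixture(scope="session")
def subject() -> gf.SubjectProfile:
    return gf.SubjectProfile(subject="average", body_weight_kg=75.0)


@pytest.fixture(scope="session")
def times() -> np.ndarray:
    return np.arange(0.0, 211.0, 15.0)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Single-subject noiseless curves generated at the regime truth."""
    cfg = gf.GeneratorConfig(seed=11, n_subjects=1, subject_cv=0.0, noise_frac=0.0)
    return cfg, gf.generate_enrichment_curves(cfg)


@pytest.fixture(scope="session")
def average_dataset():
    """Default eight-subject noisy dataset and its across-subject average."""
    cfg = gf.GeneratorConfig(seed=1)
    ds = gf.generate_enrichment_curves(cfg)
    return cfg, ds, ds.average()
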