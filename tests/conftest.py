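import numpy as np
import pytest

import saltspec as ss


@pytest.fixture(scope="session")
def small_config():
    """Tiny but structurally complete scene: 6+6 pots, 4 views, 3 periods."""
    return ss.SceneConfig(n_pots_control=6, n_pots_salt=6, frame_size=48, seed=1)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return ss.generate_dataset(small_config)


@pytest.fixture(scope="session")
def corrected_pair(small_dataset):
    """One corrected sample record and its F740 mask."""
    record = small_dataset.sample("C001", 0, 5)
    corrected = ss.correct_sample(record, small_dataset.references)
    mask = ss.segment_plant(corrected.bands["F740"])
    return corrected, mask


@pytest.fixture(scope="session")
def small_feature_table(small_dataset):
    from saltspec.pipeline import compute_feature_table

    return compute_feature_table(small_dataset)


def make_band(pixels, label="F740", **kw):
    return ss.BandImage(np.asarray(pixels, dtype=float), label, **kw)


@pytest.fixture
def flat_refs():
    """Noise-free unit-field references for exercising Eq.-style correction."""
    shape = (8, 8)
    white = {}
    dark = {}
    for label in ("F740", "F690", "F520"):
        white[label] = ss.BandImage(np.full(shape, 110.0), label, role="reference")
        dark[label] = ss.BandImage(np.full(shape, 10.0), label, role="dark")
    return ss.ReferenceSet(white=white, dark=dark)
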