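import numpy as np
import pytest

import cocoonsort as cs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pm_batch():
    """Small Pure Mysore batch shared by feature/pipeline tests."""
    records, truth = cs.generate_batch(cs.PURE_MYSORE, 6, 6, seed=42)
    return records, truth


@pytest.fixture(scope="session")
def clean_silhouette_region():
    """Noiseless, fiberless rendered silhouette segmented into one region."""
    img = cs.render_silhouette(center=(32, 32), scale=10.0, waist=0.05, angle=0.6)
    mask = cs.binarize(img, cs.otsu_threshold(img))
    return cs.extract_components(mask)[0]
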