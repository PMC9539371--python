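import numpy as np
import pytest

from swdspare import (
    FeatureCache,
    SynthConfig,
    WindowConfig,
    extract_window_pairs,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Compact labeled cohort (40 SWDs, 8 patients) for classifier tests."""
    cfg = SynthConfig(n_patients=8, n_spared_swd=24, n_impaired_swd=16, seed=3)
    recordings, events = generate_dataset(cfg)
    return cfg, recordings, events


@pytest.fixture(scope="session")
def small_cache(small_cohort):
    _, recordings, events = small_cohort
    pairs = extract_window_pairs(recordings, events, WindowConfig())
    return FeatureCache(pairs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
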