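import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_separable():
    """Linearly separable two-feature toy set (n = 200)."""
    rng = np.random.default_rng(11)
    X = rng.normal(size=(200, 2))
    y = (X[:, 0] > 0).astype(int)
    return X, y


@pytest.fixture(scope="session")
def small_synthetic():
    """A small generated library with ground truth (n = 150)."""
    from dilipred.synthetic import GeneratorConfig, generate

    cfg = GeneratorConfig(n=150, seed=5)
    records, truths = generate(cfg)
    return cfg, records, truths


@pytest.fixture(scope="session")
def featurized_small(small_synthetic):
    """Raw feature matrix + bitmaps + labels for the small library."""
    from dilipred import featurize as ft
    from dilipred.synthetic import records_to_frame

    _, records, truths = small_synthetic
    df = records_to_frame(records)
    kept, X_raw, bitmaps, desc = ft.featurize_frame(df)
    y = (kept["raw_class"] == "DILI positive").astype(int).to_numpy()
    return kept, X_raw, bitmaps, y
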