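import numpy as np
import pandas as pd
import pytest

from bchgee import classify, datagen, zip_lca


@pytest.fixture(scope="session")
def small_config() -> datagen.ScenarioConfig:
    """High-separation scenario at a size suitable for unit tests."""
    return datagen.make_scenario(entropy="high", effect_size=0.25,
                                 n_schools=200, children_range=(5, 10),
                                 seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    panel, children, paths = datagen.simulate_dataset(small_config)
    return panel, children, paths


@pytest.fixture(scope="session")
def fitted_pipeline(small_config, small_dataset):
    """Step 1 + Step 2 outputs on the small high-separation dataset."""
    panel, children, paths = small_dataset
    model = zip_lca.fit_zip_lca(panel, small_config.L, n_starts=3,
                                tol=1e-8, seed=0)
    post = classify.posterior_probs(model, panel)
    assign = classify.modal_assign(post)
    D = classify.classification_error(post, assign)
    weights = classify.bch_weights(D, assign)
    return {"model": model, "post": post, "assign": assign, "D": D,
            "weights": weights}


@pytest.fixture()
def identity_weights():
    """Factory for perfect-classification (D = I) weight objects."""

    def make(assign: pd.DataFrame, L: int) -> classify.BchWeights:
        return classify.bch_weights(np.eye(L), assign)

    return make
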