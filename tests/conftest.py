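import numpy as np
import pandas as pd
import pytest

from woeqsar import SyntheticConfig, generate_panel, split_train_test
from woeqsar.dataset import ModelingDataset


@pytest.fixture(scope="session")
def small_panel():
    """A compact compound panel exercising every integration path."""
    cfg = SyntheticConfig(n_compounds=250, seed=7)
    return generate_panel(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_panel):
    """Split ModelingDataset built from the small panel's true labels."""
    fp, _, truth = small_panel
    X = fp.to_frame()
    X.index = X.index.astype(str)
    Y = pd.DataFrame({ep: truth.labels[ep] for ep in ("Y1", "Y2", "Y3")},
                     index=X.index)
    return split_train_test(ModelingDataset(X=X, Y=Y), ratio=0.8, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
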