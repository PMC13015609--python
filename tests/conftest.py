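import numpy as np
import pytest

import uqtriage as uq


def feature_matrix(frame):
    fcols = sorted((c for c in frame.columns if c.startswith("f") and c[1:].isdigit()),
                   key=lambda c: int(c[1:]))
    X = frame[fcols].to_numpy(dtype=float)
    y = (frame["label"] == "High-Risk").to_numpy(dtype=int)
    return X, y


@pytest.fixture(scope="session")
def default_cohort():
    """Study-scale cohort: 170 cases, 7 centers, default difficulty."""
    return uq.generate_cohort(uq.SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def default_frame(default_cohort):
    return uq.cohort_to_frame(default_cohort)


@pytest.fixture(scope="session")
def fitted(default_frame):
    """Branches fitted on the default cohort, with mid-grid fusion params."""
    X, y = feature_matrix(default_frame)
    models = uq.fit_branches(X, y, seed=0)
    return models, uq.FusionParams(t=0.8, k=0.5), X, y
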