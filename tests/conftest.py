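import numpy as np
import pandas as pd
import pytest

from devmir.io import ExpressionMatrix
from devmir.simulate import SyntheticConfig, generate_dataset, _sample_sheet
from devmir.stages import DEFAULT_STAGES


@pytest.fixture
def make_matrix():
    """Factory for small expression matrices over the default 12-stage design."""

    def _make(values: np.ndarray, feature_ids=None, kind="gene", n_reps=3, stages=None):
        stages = list(stages or DEFAULT_STAGES)
        sheet = _sample_sheet(stages, n_reps, "s")
        values = np.asarray(values, dtype=float)
        if feature_ids is None:
            feature_ids = [f"f{i}" for i in range(values.shape[0])]
        frame = pd.DataFrame(
            values, index=pd.Index(feature_ids, name="feature_id"),
            columns=list(sheet["sample_id"]),
        )
        return ExpressionMatrix(frame, sheet, kind, stages=stages)

    return _make


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_genes=120,
        n_mirnas=40,
        n_planted_repressors=8,
        targets_per_repressor=3,
        decoy_interactions=150,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)
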