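import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cellgate import FeatureMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(values, feature_ids=None, cell_ids=None, modality_tag="rna"):
    values = np.asarray(values, dtype=float)
    n_cells, n_features = values.shape
    if feature_ids is None:
        feature_ids = [f"g{j}" for j in range(n_features)]
    if cell_ids is None:
        cell_ids = [f"c{i}" for i in range(n_cells)]
    return FeatureMatrix(
        values=values,
        feature_ids=np.asarray(feature_ids, dtype=object),
        cell_ids=np.asarray(cell_ids, dtype=object),
        modality_tag=modality_tag,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
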