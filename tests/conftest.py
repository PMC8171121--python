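import numpy as np
import pandas as pd
import pytest

from cncpipe.io_formats import ExpressionBundle, GroupDesign
from cncpipe.synthetic_data import SimulationConfig, generate


def make_bundle(values, sample_ids=None, feature_ids=None, flags=None, scale="linear"):
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    feature_ids = feature_ids or [f"f{i + 1}" for i in range(n_feat)]
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(n_samp)]
    vdf = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    if flags is None:
        fdf = pd.DataFrame("P", index=feature_ids, columns=sample_ids)
    else:
        fdf = pd.DataFrame(flags, index=feature_ids, columns=sample_ids)
    return ExpressionBundle(vdf, fdf, scale=scale)


@pytest.fixture
def small_bundle():
    return make_bundle([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [5.0, 5.0, 5.0, 5.0]])


@pytest.fixture
def four_v_four_design():
    groups = {f"case_{i}": "case" for i in range(1, 5)}
    groups.update({f"ctrl_{i}": "control" for i in range(1, 5)})
    return GroupDesign(groups)


@pytest.fixture(scope="session")
def sim():
    """One default synthetic bundle shared across the session."""
    return generate(SimulationConfig(seed=20240917))
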