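import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mirseed.containers import CtMatrix

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


def make_ct(values: np.ndarray, groups=None, diameters=None) -> CtMatrix:
    """Small CtMatrix from a raw array for hand fixtures."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    feats = [f"f{i}" for i in range(n_feat)]
    samps = [f"s{j}" for j in range(n_samp)]
    meta = pd.DataFrame(index=pd.Index(samps, name="sample_id"))
    meta["group"] = list(groups) if groups is not None else "x"
    if diameters is not None:
        meta["diameter"] = list(diameters)
    return CtMatrix(pd.DataFrame(values, index=feats, columns=samps), meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
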