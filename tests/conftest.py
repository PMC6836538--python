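import numpy as np
import pandas as pd
import pytest

from dese import TissueSummary


def make_summary(mean: np.ndarray, se: np.ndarray | float = 1.0, tissues=None) -> TissueSummary:
    """TissueSummary from raw arrays, for direct tests of the measures."""
    mean = np.atleast_2d(np.asarray(mean, dtype=float))
    if np.isscalar(se):
        se = np.full_like(mean, float(se))
    else:
        se = np.atleast_2d(np.asarray(se, dtype=float))
    n_feat, n_tis = mean.shape
    if tissues is None:
        tissues = [f"T{i + 1:02d}" for i in range(n_tis)]
    features = [f"g{i + 1}" for i in range(n_feat)]
    return TissueSummary(
        mean=pd.DataFrame(mean, index=features, columns=tissues),
        se=pd.DataFrame(se, index=features, columns=tissues),
        n_samples=pd.Series(10, index=tissues),
    )


@pytest.fixture
def toy_gct(tmp_path):
    """3 features x 2 samples GCT file."""
    text = (
        "#1.2\n"
        "3\t2\n"
        "Name\tDescription\ts1\ts2\n"
        "gA\tGENEA\t1.5\t2.5\n"
        "gB\tGENEB\t0.0\t7.0\n"
        "gC\tGENEC\t3.25\t0.75\n"
    )
    path = tmp_path / "toy.gct"
    path.write_text(text)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
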