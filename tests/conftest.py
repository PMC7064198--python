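import numpy as np
import pytest

from towge.residualize import ResidualSet


def make_residual_set(y_res, S_res, kept_idx=None, design=None):
    """Assemble a ResidualSet directly from arrays (for statistic-level
    tests that do not need a real adjustment design)."""
    y_res = np.asarray(y_res, dtype=float)
    S_res = np.asarray(S_res, dtype=float)
    if S_res.ndim == 1:
        S_res = S_res[:, None]
    n, p = S_res.shape
    if kept_idx is None:
        kept_idx = np.arange(p)
    if design is None:
        design = np.ones((n, 1))
    return ResidualSet(
        y_res=y_res,
        S_res=S_res,
        kept_idx=np.asarray(kept_idx, dtype=int),
        dropped_idx=np.array([], dtype=int),
        design_rank=int(np.linalg.matrix_rank(design)),
        design=design,
        y_raw=y_res.copy(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
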