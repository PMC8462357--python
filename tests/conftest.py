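import numpy as np
import pytest

from tsktl import build_mmd_matrix, fit_tsk_fs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tl_instance(rng, n=None, m=None, K=None, d=None):
    """A random small transfer problem in design space, with its MMD matrix."""
    n = n or int(rng.integers(6, 21))
    m = m or int(rng.integers(6, 21))
    K = K or int(rng.integers(1, 4))
    d = d or int(rng.integers(1, 5))
    p_dim = K * (d + 1)
    Xs = rng.standard_normal((p_dim, n))
    Xt = rng.standard_normal((p_dim, m))
    ys = rng.choice([-1.0, 1.0], n)
    yt = rng.choice([-1.0, 1.0], m)
    # guarantee both classes present on both sides so no MMD term degenerates
    ys[:2] = [1.0, -1.0]
    yt[:2] = [1.0, -1.0]
    spec = build_mmd_matrix(ys, yt)
    return {
        "Xs": Xs,
        "Xt": Xt,
        "Xall": np.hstack([Xs, Xt]),
        "ys": ys,
        "yt": yt,
        "M": spec.M,
        "spec": spec,
        "p0": fit_tsk_fs(Xs, ys, 1.0),
        "p_dim": p_dim,
    }
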