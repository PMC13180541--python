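import numpy as np
import pytest


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def finite_difference_grads(f, xs, eps: float = 1e-6):
    """Central-difference gradients of scalar-weighted output w.r.t. each input.

    Returns (analytic, numeric) gradient lists using a fixed random output
    weighting, for comparing against the autodiff engine.
    """
    from lesiondetr import nn
    from lesiondetr.nn.tensor import Tensor

    local = np.random.default_rng(999)
    params = [nn.Parameter(x.copy()) for x in xs]
    out = f(*params)
    g_out = local.standard_normal(out.shape)
    out.backward(g_out)
    analytic = [p.grad for p in params]
    numeric = []
    for k, x in enumerate(xs):
        num = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            fp = f(*[Tensor(xp if j == k else xs[j]) for j in range(len(xs))]).data
            fm = f(*[Tensor(xm if j == k else xs[j]) for j in range(len(xs))]).data
            num[i] = ((fp - fm) / (2 * eps) * g_out).sum()
        numeric.append(num)
    return analytic, numeric
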