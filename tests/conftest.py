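import numpy as np
import pytest

import t2gwg as tg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def t2gwe_111():
    """Unit-parameter exponential-baseline model: closed forms are simple."""
    return tg.t2gwe(1.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def t2gwe_table():
    """The simulation-study parameter point (alpha, beta, gamma) = (2.5, 0.8, 1.3)."""
    return tg.t2gwe(2.5, 0.8, 1.3)


@pytest.fixture(scope="session")
def model_zoo():
    """One model per baseline, at generic non-unit parameters."""
    return [
        tg.t2gwe(2.5, 0.8, 1.3),
        tg.t2gwu(0.7, 0.45, 3.0),
        tg.t2gwp(1.4, 1.1, 0.8, 2.2),
    ]


def central_diff(f, x, h):
    return (f(x + h) - f(x - h)) / (2.0 * h)


@pytest.fixture(scope="session")
def fd_grad():
    """Central finite-difference gradient of a scalar function of a vector."""

    def _grad(f, p, rel_step=1e-6):
        p = np.asarray(p, dtype=float)
        g = np.zeros_like(p)
        for j in range(len(p)):
            h = rel_step * max(abs(p[j]), 1e-3)
            e = np.zeros_like(p)
            e[j] = h
            g[j] = (f(p + e) - f(p - e)) / (2.0 * h)
        return g

    return _grad
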