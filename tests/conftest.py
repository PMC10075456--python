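import numpy as np
import pytest

from nmmfit import (
    ALPHA_SUBJECT_PARAMS,
    LileyParameters,
    ParameterBounds,
    SimulationConfig,
)


@pytest.fixture(scope="session")
def typical_params() -> LileyParameters:
    """Table-typical parameter values (package defaults)."""
    return LileyParameters()


@pytest.fixture(scope="session")
def alpha_params() -> LileyParameters:
    """The packaged synthetic alpha-subject ground truth."""
    return ALPHA_SUBJECT_PARAMS


@pytest.fixture(scope="session")
def bounds() -> ParameterBounds:
    return ParameterBounds.physiological()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def whvg_oracle(x):
    """Definition-level weighted horizontal visibility graph.

    For every pair i < j, checks directly that all intermediate samples lie
    strictly below both endpoints.  Quadratic, vectorised over j for speed;
    independent of the stack-based builder.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    edges = set()
    for i in range(n - 1):
        edges.add((i, i + 1, x[i + 1] - x[i]))
        if i + 2 > n - 1:
            continue
        # cummax[k] = max(x[i+1 .. i+1+k]) blocks (i, j) when >= min endpoints
        cummax = np.maximum.accumulate(x[i + 1:n - 1])
        js = np.arange(i + 2, n)
        blocked = cummax[:len(js)] >= np.minimum(x[i], x[js])
        for j in js[~blocked]:
            edges.add((i, int(j), x[j] - x[i]))
    return edges
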