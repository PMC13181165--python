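import numpy as np
import pytest

from gapmine.incidence import IncidenceMatrix


def make_incidence(values, mask=None, weighted=True) -> IncidenceMatrix:
    """Build a small IncidenceMatrix from array-likes (NaN = missing)."""
    A = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isfinite(A)
    mask = np.asarray(mask, dtype=bool)
    m, n = A.shape
    return IncidenceMatrix(
        A=A,
        mask=mask,
        row_names=[f"r{i}" for i in range(m)],
        col_names=[f"c{j}" for j in range(n)],
        weighted=weighted,
    )


@pytest.fixture
def mk():
    return make_incidence


@pytest.fixture
def rng():
    return np.random.default_rng(0)
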