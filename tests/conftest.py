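"""Shared fixtures: axes, synthetic basis sets, and the brute-force oracle."""

from itertools import combinations

import numpy as np
import pytest

from hyperunmix import (
    EmissionBands,
    ExcitationAxis,
    HyperStack,
    canonical_basis,
    normalize_basis,
)


@pytest.fixture(scope="session")
def axis() -> ExcitationAxis:
    return ExcitationAxis.default()


@pytest.fixture(scope="session")
def bands() -> EmissionBands:
    return EmissionBands.default()


@pytest.fixture(scope="session")
def basis():
    """Packaged synthetic four-tissue basis set (unnormalized)."""
    return canonical_basis()


@pytest.fixture(scope="session")
def norm_basis(basis):
    """The same set normalized per component to blue-band maximum 1."""
    return basis.map(normalize_basis)


@pytest.fixture
def small_stack(axis, bands):
    """Deterministic 8x8 stack with data[r, c, i, b] = 1 + r + c + i + 10 b."""
    r, c = np.mgrid[0:8, 0:8]
    i = np.arange(len(axis))
    b = np.arange(len(bands))
    data = (
        1.0
        + r[:, :, None, None]
        + c[:, :, None, None]
        + i[None, None, :, None]
        + 10.0 * b[None, None, None, :]
    )
    return HyperStack(data=data, excitation=axis, emission=bands, meta={"id": "fixture"})


def brute_force_nnls(A: np.ndarray, b: np.ndarray):
    """Independent NNLS oracle: exhaustive active-set enumeration.

    Solves unconstrained least squares on every support subset of the k
    columns (plus x = 0), keeps the feasible candidates, and returns the one
    with the smallest squared residual.  Exact for k small; used to verify
    the production solver, never to replace it.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    m, k = A.shape
    best_x = np.zeros(k)
    best_r2 = float(b @ b)
    for size in range(1, k + 1):
        for support in combinations(range(k), size):
            xs, *_ = np.linalg.lstsq(A[:, support], b, rcond=None)
            if (xs < -1e-12).any():
                continue
            x = np.zeros(k)
            x[list(support)] = np.clip(xs, 0.0, None)
            r = b - A @ x
            r2 = float(r @ r)
            if r2 < best_r2 - 1e-12:
                best_r2, best_x = r2, x
    return best_x, best_r2
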