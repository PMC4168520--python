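"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.linalg import solve_discrete_lyapunov

from neuromkl.kernels import combine
from neuromkl.simplemkl import svm_dual_solve


def simplex_grid(M: int, step: float = 0.01) -> np.ndarray:
    """All points of the probability simplex on a regular grid."""
    vals = np.arange(0.0, 1.0 + step / 2, step)
    if M == 1:
        return np.array([[1.0]])
    if M == 2:
        return np.array([[a, 1.0 - a] for a in vals])
    if M == 3:
        pts = [
            (a, b, 1.0 - a - b)
            for a in vals
            for b in vals
            if a + b <= 1.0 + 1e-12
        ]
        return np.clip(np.array(pts), 0.0, None)
    raise ValueError("grid oracle supports M <= 3")


def grid_search_objective(bank, y, C, step: float = 0.01) -> float:
    """Exhaustive minimum of the MKL objective over the simplex grid.

    Independent of the reduced-gradient path: enumerates weight vectors
    and solves the inner QP exactly at each one.
    """
    best = np.inf
    alpha = None
    for d in simplex_grid(bank.M, step):
        dual = svm_dual_solve(combine(bank, d), y, C, alpha0=alpha)
        alpha = dual.alpha  # warm start the neighbouring grid point
        if dual.objective < best:
            best = dual.objective
    return best


def var1_causality_oracle(a11: float, a12: float, a22: float, p: int) -> float:
    """Population F_{2->1} for the VAR(1) x1 = a11 x1 + a12 x2 + e1,
    x2 = a22 x2 + e2 (unit noise), restricted model of order p.

    Closed form via the Lyapunov equation for the stationary covariance
    and Yule-Walker for the restricted AR(p) innovation variance.
    """
    A = np.array([[a11, a12], [0.0, a22]])
    G0 = solve_discrete_lyapunov(A, np.eye(2))

    def gamma(k: int) -> float:
        return float((np.linalg.matrix_power(A, k) @ G0)[0, 0])

    r = np.array([gamma(k) for k in range(1, p + 1)])
    R = np.array([[gamma(abs(i - j)) for j in range(p)] for i in range(p)])
    sigma_restricted = gamma(0) - r @ np.linalg.solve(R, r)
    return float(np.log(sigma_restricted))  # full-model variance is 1


def simulate_var1(a11, a12, a22, n, seed, burn_in=500):
    rng = np.random.default_rng(seed)
    total = n + burn_in
    A = np.array([[a11, a12], [0.0, a22]])
    x = np.zeros((total, 2))
    e = rng.standard_normal((total, 2))
    for i in range(1, total):
        x[i] = A @ x[i - 1] + e[i]
    return x[burn_in:]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def separable_2class():
    """Well-separated 2-class Gaussian blobs."""
    g = np.random.default_rng(11)
    X = np.vstack([g.normal(-2.0, 0.8, (25, 3)), g.normal(2.0, 0.8, (25, 3))])
    y = np.array([-1] * 25 + [1] * 25)
    return X, y
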