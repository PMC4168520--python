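"""Binary multiple-kernel-learning SVM trained by reduced-gradient descent.

The classifier learns simultaneously an SVM and a convex combination of
Gram matrices ``K(d) = sum_m d_m K_m`` with ``sum_m d_m = 1, d_m >= 0``.
Training alternates two steps:

1. for fixed weights ``d``, solve the standard soft-margin SVM dual

       max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K(d)_ij
       s.t.   sum_i a_i y_i = 0,  0 <= a_i <= C

   (an SMO working-set solver, :func:`svm_dual_solve`);

2. for fixed dual variables, take a reduced-gradient step on ``d``
   restricted to the simplex, with partial derivatives

       dJ/dd_m = -1/2 sum_ij a_i a_j y_i y_j K_m(x_i, x_j),

   a descent direction that keeps ``sum d = 1`` (zeroed on inactive
   coordinates whose derivative would pull them negative), and a
   backtracking line search from the largest feasible step.

The outer loop terminates on the duality gap

    max_m a'G_m a - sum_m d_m a'G_m a <= eps,   G_m = diag(y) K_m diag(y),

i.e. when no single kernel's quadratic form exceeds the combined one by
more than the tolerance.  The decision function of the fitted model is

    f(x) = sgn( sum_sv a_i y_i sum_m d_m K_m(x, x_i) + b ).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kernels import KernelBank, KernelSpec, build_bank

__all__ = [
    "SolverSettings",
    "SVMDualSolution",
    "MKLModel",
    "svm_dual_solve",
    "objective_and_gradient",
    "descent_direction",
    "line_search_update",
    "duality_gap",
    "fit",
    "decision_function",
    "predict",
    "save_model",
    "load_model",
]


@dataclass
class SolverSettings:
    """Tunable solver parameters.

    C : soft-margin penalty (box constraint on the dual variables).
    gap_tol : relative duality-gap tolerance (fraction of the combined
        quadratic form); ``gap_abs_tol`` is the absolute fallback used
        when the combined form is tiny.
    standardize : z-score features with training statistics before
        kernel evaluation.
    normalize_kernels : scale each Gram to unit mean diagonal.
    """

    C: float = 100.0
    gap_tol: float = 0.01
    gap_abs_tol: float = 1e-4
    max_outer_iters: int = 200
    inner_tol: float = 1e-8
    standardize: bool = True
    normalize_kernels: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError("C must be positive")
        if not self.gap_tol > 0:
            raise ValueError("gap_tol must be positive")


@dataclass
class SVMDualSolution:
    """Optimal dual variables of the soft-margin SVM for a fixed kernel."""

    alpha: np.ndarray
    b: float
    sv_index: np.ndarray
    C: float
    objective: float


@dataclass
class MKLModel:
    """Fitted binary MKL-SVM."""

    d: np.ndarray
    dual: SVMDualSolution
    bank: KernelBank
    y_train: np.ndarray
    gap: float
    J: float
    converged: bool
    n_outer_iters: int
    J_history: list = field(default_factory=list)
    gap_history: list = field(default_factory=list)
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None
    classes: tuple = (-1, 1)


# ---------------------------------------------------------------------------
# Inner solver: SMO with second-order working-set selection
# ---------------------------------------------------------------------------

def svm_dual_solve(
    K: np.ndarray,
    y: np.ndarray,
    C: float,
    tol: float = 1e-8,
    max_iter: int = 200_000,
    alpha0: np.ndarray | None = None,
) -> SVMDualSolution:
    """Solve the soft-margin SVM dual for a fixed Gram matrix.

    Sequential minimal optimisation over maximal-violating pairs with a
    second-order (greatest objective decrease) choice of the second index,
    run until the maximal KKT violation falls below ``tol``.  ``alpha0``
    warm-starts the solve; it must already satisfy the box and equality
    constraints (e.g. the solution for a nearby kernel).
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"K must be square, got shape {K.shape}")
    y = np.asarray(y, dtype=float).ravel()
    n = K.shape[0]
    if y.shape[0] != n:
        raise ValueError("label length does not match kernel size")
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ValueError("labels must be in {-1, +1}")
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class; need both classes")

    Q = K * np.outer(y, y)
    diagQ = np.diag(Q).copy()
    if alpha0 is not None and alpha0.shape == (n,):
        alpha = np.clip(np.asarray(alpha0, dtype=float), 0.0, C)
        grad = Q @ alpha - 1.0
    else:
        alpha = np.zeros(n)
        grad = -np.ones(n)  # gradient of 1/2 a'Qa - 1'a

    TAU = 1e-12
    for _ in range(max_iter):
        # I_up: can increase a_i y_i; I_low: can decrease.
        up = ((y > 0) & (alpha < C - 1e-14)) | ((y < 0) & (alpha > 1e-14))
        low = ((y > 0) & (alpha > 1e-14)) | ((y < 0) & (alpha < C - 1e-14))
        if not up.any() or not low.any():
            break
        yg = -y * grad
        i = int(np.flatnonzero(up)[np.argmax(yg[up])])
        m_up = yg[i]
        M_low = np.min(yg[low])
        if m_up - M_low < tol:
            break
        # second-order selection of j among violating I_low indices
        cand = np.flatnonzero(low & (yg < m_up - TAU))
        if cand.size == 0:
            break
        b_ij = m_up - yg[cand]
        a_ij = diagQ[i] + diagQ[cand] - 2.0 * y[i] * y[cand] * Q[i, cand]
        a_ij = np.where(a_ij > TAU, a_ij, TAU)
        j = int(cand[np.argmin(-(b_ij * b_ij) / a_ij)])

        # analytic update of the pair (i, j)
        a = max(diagQ[i] + diagQ[j] - 2.0 * y[i] * y[j] * Q[i, j], TAU)
        delta = (m_up - yg[j]) / a
        # move along a_i y_i += delta, a_j y_j -= delta, then clip to box
        old_ai, old_aj = alpha[i], alpha[j]
        ai = old_ai + y[i] * delta
        aj = old_aj - y[j] * delta
        # clip preserving the equality constraint
        s = y[i] * old_ai + y[j] * old_aj
        ai = min(max(ai, 0.0), C)
        aj = y[j] * (s - y[i] * ai)
        if aj < 0.0 or aj > C:
            aj = min(max(aj, 0.0), C)
            ai = y[i] * (s - y[j] * aj)
            ai = min(max(ai, 0.0), C)
        alpha[i], alpha[j] = ai, aj
        grad += Q[:, i] * (ai - old_ai) + Q[:, j] * (aj - old_aj)
    else:
        warnings.warn("SMO reached max_iter without meeting tolerance")

    # bias from margin support vectors (0 < a < C); fall back to midpoint
    yg = -y * grad
    free = (alpha > 1e-10) & (alpha < C - 1e-10)
    if free.any():
        b = float(np.mean(yg[free]))
    else:
        up = ((y > 0) & (alpha < C - 1e-14)) | ((y < 0) & (alpha > 1e-14))
        lo = ((y > 0) & (alpha > 1e-14)) | ((y < 0) & (alpha < C - 1e-14))
        hi_v = np.max(yg[up]) if up.any() else 0.0
        lo_v = np.min(yg[lo]) if lo.any() else 0.0
        b = float((hi_v + lo_v) / 2.0)

    obj = float(np.sum(alpha) - 0.5 * alpha @ Q @ alpha)
    sv = np.flatnonzero(alpha > 1e-10)
    return SVMDualSolution(alpha=alpha, b=b, sv_index=sv, C=C, objective=obj)


# ---------------------------------------------------------------------------
# Reduced-gradient machinery on the simplex
# ---------------------------------------------------------------------------

def _quadforms(alpha: np.ndarray, y: np.ndarray, grams: list[np.ndarray]) -> np.ndarray:
    """q_m = a' diag(y) K_m diag(y) a for every kernel in the bank."""
    ay = alpha * y
    return np.array([float(ay @ Km @ ay) for Km in grams])


def objective_and_gradient(
    dual: SVMDualSolution, bank: KernelBank, y: np.ndarray, d: np.ndarray
) -> tuple[float, np.ndarray]:
    """Dual objective J(d) and its gradient dJ/dd_m = -q_m / 2."""
    alpha = dual.alpha
    if alpha.shape[0] != bank.n:
        raise ValueError("alpha length does not match bank size")
    q = _quadforms(alpha, np.asarray(y, dtype=float), bank.grams)
    d = np.asarray(d, dtype=float)
    J = float(np.sum(alpha) - 0.5 * np.dot(d, q))
    return J, -0.5 * q


def descent_direction(d: np.ndarray, g: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Simplex-tangent descent direction from the reduced gradient.

    mu is the index of the largest weight (smallest index on ties);
    components at zero whose partial derivative exceeds mu's are frozen,
    active components move along the negative reduced gradient, and mu
    absorbs the opposite sum so the direction sums to zero.
    """
    d = np.asarray(d, dtype=float)
    g = np.asarray(g, dtype=float)
    if abs(d.sum() - 1.0) > 1e-6 or d.min() < -1e-10:
        raise ValueError("d is not on the probability simplex")
    mu = int(np.argmax(d))  # argmax returns the first maximum
    D = np.zeros_like(d)
    active = np.zeros(d.shape[0], dtype=bool)
    for m in range(d.shape[0]):
        if m == mu:
            continue
        if d[m] <= tol:
            if g[m] - g[mu] > 0:
                D[m] = 0.0  # would leave the simplex; freeze at zero
            else:
                D[m] = -g[m] + g[mu]
                active[m] = True
        else:
            D[m] = -g[m] + g[mu]
            active[m] = True
    D[mu] = np.sum(g[active] - g[mu])
    return D


def _max_step(d: np.ndarray, D: np.ndarray) -> float:
    """Largest gamma with d + gamma D >= 0 componentwise."""
    neg = D < -1e-15
    if not neg.any():
        return np.inf
    return float(np.min(-d[neg] / D[neg]))


def _snap_simplex(d: np.ndarray, snap_tol: float = 1e-8) -> np.ndarray:
    d = np.where(d < snap_tol, 0.0, d)
    s = d.sum()
    if s <= 0:
        raise RuntimeError("all kernel weights vanished")
    return d / s


def line_search_update(
    d: np.ndarray,
    D: np.ndarray,
    bank: KernelBank,
    y: np.ndarray,
    settings: SolverSettings,
    J_current: float | None = None,
    max_halvings: int = 20,
) -> tuple[np.ndarray, SVMDualSolution, float, bool]:
    """Backtracking line search along the descent direction.

    Tries the maximal feasible step first (which drives boundary-hitting
    weights exactly to zero), then halves until the objective decreases.
    Returns ``(d_new, dual_new, J_new, moved)``; ``moved`` is False when
    no admissible step improves the objective.
    """
    d = np.asarray(d, dtype=float)
    D = np.asarray(D, dtype=float)
    from .kernels import combine

    if J_current is None:
        dual0 = svm_dual_solve(combine(bank, d), y, settings.C, tol=settings.inner_tol)
        J_current = dual0.objective
    if np.max(np.abs(D)) < 1e-14:
        dual0 = svm_dual_solve(combine(bank, d), y, settings.C, tol=settings.inner_tol)
        return d, dual0, dual0.objective, False
    gamma_max = _max_step(d, D)
    if not np.isfinite(gamma_max):
        # direction never hits the boundary; scale to a unit simplex move
        gamma_max = 1.0 / max(np.max(np.abs(D)), 1e-12)
    gamma = gamma_max
    for _ in range(max_halvings):
        d_try = _snap_simplex(np.clip(d + gamma * D, 0.0, None))
        dual_try = svm_dual_solve(
            combine(bank, d_try), y, settings.C, tol=settings.inner_tol
        )
        if dual_try.objective <= J_current - 1e-12 * max(1.0, abs(J_current)):
            return d_try, dual_try, dual_try.objective, True
        gamma *= 0.5
    dual0 = svm_dual_solve(combine(bank, d), y, settings.C, tol=settings.inner_tol)
    return d, dual0, dual0.objective, False


def duality_gap(
    dual: SVMDualSolution, bank: KernelBank, d: np.ndarray, y: np.ndarray
) -> float:
    """max_m a'G_m a - sum_m d_m a'G_m a  (G_m = diag(y) K_m diag(y))."""
    q = _quadforms(dual.alpha, np.asarray(y, dtype=float), bank.grams)
    return float(np.max(q) - np.dot(np.asarray(d, dtype=float), q))


# ---------------------------------------------------------------------------
# Outer loop
# ---------------------------------------------------------------------------

def fit(
    X: np.ndarray,
    y: np.ndarray,
    specs: list[KernelSpec],
    settings: SolverSettings | None = None,
) -> MKLModel:
    """Train the binary MKL-SVM.

    Labels may be any two values; they are mapped onto -1/+1 (sorted
    order: smaller label -> -1).  Features are optionally z-scored with
    training statistics before kernel evaluation.
    """
    settings = settings or SolverSettings()
    X = np.asarray(X, dtype=float)
    y_raw = np.asarray(y).ravel()
    classes = np.unique(y_raw)
    if classes.size != 2:
        raise ValueError(f"binary classifier requires exactly 2 classes, got {classes.size}")
    y = np.where(y_raw == classes[1], 1.0, -1.0)
    for c in classes:
        if np.sum(y_raw == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 training samples")

    mean = std = None
    if settings.standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std < 1e-12, 1.0, std)
        X = (X - mean) / std

    bank = build_bank(X, specs, normalize=settings.normalize_kernels)
    M = bank.M
    d = np.full(M, 1.0 / M)

    from .kernels import combine

    dual = svm_dual_solve(combine(bank, d), y, settings.C, tol=settings.inner_tol)
    J = dual.objective
    J_hist = [J]
    gap_hist = []
    converged = False
    it = 0
    for it in range(1, settings.max_outer_iters + 1):
        q = _quadforms(dual.alpha, y, bank.grams)
        combined = float(np.dot(d, q))
        gap = float(np.max(q) - combined)
        gap_hist.append(gap)
        eps = max(settings.gap_tol * abs(combined), settings.gap_abs_tol)
        if gap <= eps:
            converged = True
            break
        g = -0.5 * q
        D = descent_direction(d, g)
        d_new, dual_new, J_new, moved = line_search_update(
            d, D, bank, y, settings, J_current=J
        )
        if not moved:
            # stationary on the simplex; re-check the gap and stop
            gap = duality_gap(dual, bank, d, y)
            converged = gap <= eps
            break
        d, dual, J = d_new, dual_new, J_new
        J_hist.append(J)
    else:
        it = settings.max_outer_iters

    final_gap = duality_gap(dual, bank, d, y)
    if not gap_hist or gap_hist[-1] != final_gap:
        gap_hist.append(final_gap)
    eps = max(
        settings.gap_tol * abs(float(np.dot(d, _quadforms(dual.alpha, y, bank.grams)))),
        settings.gap_abs_tol,
    )
    converged = converged or final_gap <= eps
    if not converged:
        warnings.warn(
            f"MKL solver stopped after {it} outer iterations with duality gap "
            f"{final_gap:.3g} > tolerance {eps:.3g}"
        )
    return MKLModel(
        d=d,
        dual=dual,
        bank=bank,
        y_train=y,
        gap=final_gap,
        J=J,
        converged=converged,
        n_outer_iters=it,
        J_history=J_hist,
        gap_history=gap_hist,
        feature_mean=mean,
        feature_std=std,
        classes=(classes[0], classes[1]),
    )


def decision_function(model: MKLModel, X_new: np.ndarray) -> np.ndarray:
    """Real-valued scores  sum_sv a_i y_i sum_m d_m K_m(x, x_i) + b."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.bank.X_train.shape[1]:
        raise ValueError(
            f"feature-dimension mismatch: model trained with "
            f"{model.bank.X_train.shape[1]} features, got {X_new.shape[1]}"
        )
    if model.feature_mean is not None:
        X_new = (X_new - model.feature_mean) / model.feature_std
    blocks = model.bank.cross(X_new)
    ay = model.dual.alpha * model.y_train
    scores = np.zeros(X_new.shape[0])
    for dm, Km in zip(model.d, blocks):
        if dm != 0.0:
            scores += dm * (Km @ ay)
    return scores + model.dual.b


def predict(model: MKLModel, X_new: np.ndarray) -> np.ndarray:
    """Class labels; the sign convention maps score 0 to the +1 class."""
    scores = decision_function(model, X_new)
    lo, hi = model.classes
    return np.where(scores >= 0, hi, lo)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: MKLModel, path: str | Path) -> None:
    """Write the fitted model to a single JSON file."""
    payload = {
        "specs": [s.to_dict() for s in model.bank.specs],
        "d": model.d.tolist(),
        "alpha": model.dual.alpha.tolist(),
        "b": model.dual.b,
        "sv_index": model.dual.sv_index.tolist(),
        "C": model.dual.C,
        "X_train": model.bank.X_train.tolist(),
        "y_train": model.y_train.tolist(),
        "scales": model.bank.scales.tolist(),
        "normalized": model.bank.normalized,
        "feature_mean": None if model.feature_mean is None else model.feature_mean.tolist(),
        "feature_std": None if model.feature_std is None else model.feature_std.tolist(),
        "classes": [_jsonable(c) for c in model.classes],
        "gap": model.gap,
        "J": model.J,
        "converged": model.converged,
    }
    Path(path).write_text(json.dumps(payload))


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def load_model(path: str | Path) -> MKLModel:
    payload = json.loads(Path(path).read_text())
    specs = [KernelSpec.from_dict(s) for s in payload["specs"]]
    X_train = np.asarray(payload["X_train"], dtype=float)
    bank = build_bank(X_train, specs, normalize=payload["normalized"])
    bank.scales = np.asarray(payload["scales"])
    dual = SVMDualSolution(
        alpha=np.asarray(payload["alpha"]),
        b=payload["b"],
        sv_index=np.asarray(payload["sv_index"], dtype=int),
        C=payload["C"],
        objective=payload["J"],
    )
    return MKLModel(
        d=np.asarray(payload["d"]),
        dual=dual,
        bank=bank,
        y_train=np.asarray(payload["y_train"], dtype=float),
        gap=payload["gap"],
        J=payload["J"],
        converged=payload["converged"],
        n_outer_iters=0,
        feature_mean=None
        if payload["feature_mean"] is None
        else np.asarray(payload["feature_mean"]),
        feature_std=None
        if payload["feature_std"] is None
        else np.asarray(payload["feature_std"]),
        classes=tuple(payload["classes"]),
    )
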