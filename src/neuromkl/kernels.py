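"""Basis kernel functions and the precomputed Gram-matrix bank for MKL.

The MKL classifier combines a fixed *bank* of candidate kernels
``K(x, y) = sum_m d_m K_m(x, y)`` with convex weights ``d``.  This module
defines the three classical kernel families

* polynomial:  ``K(x, y) = ((x . y) + 1)^degree``
* Gaussian RBF: ``K(x, y) = exp(-||x - y||^2 / (2 width^2))``
* sigmoid:     ``K(x, y) = tanh(slope (x . y) + offset)``

and utilities to evaluate single kernel values, build the bank of Gram
matrices over a training set, evaluate rectangular test-vs-train blocks
with the training normalisation constants, and form convex combinations.

The default bank is three polynomial kernels (degrees 1, 2, 3) and ten
RBF kernels (widths 0.5, 1, 2, 5, 7, 10, 12, 15, 17, 20), the standard
choice for this classifier.  By default each Gram matrix is scaled to
unit mean diagonal (``trace(K)/n = 1``) so that no kernel dominates the
combination purely through scale; pass ``normalize=False`` for the raw
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KernelSpec",
    "KernelBank",
    "eval_kernel",
    "build_bank",
    "combine",
    "default_specs",
    "DEFAULT_POLY_DEGREES",
    "DEFAULT_RBF_WIDTHS",
]

DEFAULT_POLY_DEGREES = (1, 2, 3)
DEFAULT_RBF_WIDTHS = (0.5, 1.0, 2.0, 5.0, 7.0, 10.0, 12.0, 15.0, 17.0, 20.0)


@dataclass(frozen=True)
class KernelSpec:
    """Parameters of one basis kernel.

    Exactly the parameters of the chosen family must be set: ``degree``
    for ``poly``, ``width`` for ``rbf``, ``slope``/``offset`` for
    ``sigmoid``.
    """

    family: str
    degree: int | None = None
    width: float | None = None
    slope: float | None = None
    offset: float | None = None

    def __post_init__(self) -> None:
        if self.family == "poly":
            if self.degree is None or int(self.degree) < 1:
                raise ValueError("poly kernel requires integer degree >= 1")
            if self.width is not None or self.slope is not None or self.offset is not None:
                raise ValueError("poly kernel takes only 'degree'")
        elif self.family == "rbf":
            if self.width is None or not self.width > 0:
                raise ValueError("rbf kernel requires width > 0")
            if self.degree is not None or self.slope is not None or self.offset is not None:
                raise ValueError("rbf kernel takes only 'width'")
        elif self.family == "sigmoid":
            if self.slope is None or self.offset is None:
                raise ValueError("sigmoid kernel requires slope and offset")
            if self.degree is not None or self.width is not None:
                raise ValueError("sigmoid kernel takes only 'slope' and 'offset'")
        else:
            raise ValueError(f"unknown kernel family {self.family!r}")

    def label(self) -> str:
        if self.family == "poly":
            return f"poly(d={self.degree})"
        if self.family == "rbf":
            return f"rbf(w={self.width:g})"
        return f"sigmoid(k={self.slope:g},v={self.offset:g})"

    def to_dict(self) -> dict:
        d = {"family": self.family}
        for key in ("degree", "width", "slope", "offset"):
            val = getattr(self, key)
            if val is not None:
                d[key] = val
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(**d)


def default_specs(include_sigmoid: bool = False) -> list[KernelSpec]:
    """The default 13-kernel bank: poly degrees 1-3 plus ten RBF widths.

    The sigmoid kernel is implemented but excluded from the default bank;
    ``include_sigmoid=True`` appends tanh(x.y) (slope 1, offset 0).
    """
    specs = [KernelSpec("poly", degree=d) for d in DEFAULT_POLY_DEGREES]
    specs += [KernelSpec("rbf", width=w) for w in DEFAULT_RBF_WIDTHS]
    if include_sigmoid:
        specs.append(KernelSpec("sigmoid", slope=1.0, offset=0.0))
    return specs


def _check_matrix(X: np.ndarray, name: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"{name} must be 2-D (n_samples, n_features), got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name} contains non-finite values")
    return X


def gram(spec: KernelSpec, X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    """Kernel matrix K[i, j] = k(X[i], Y[j]) (Y defaults to X)."""
    X = _check_matrix(X, "X")
    Y = X if Y is None else _check_matrix(Y, "Y")
    if X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"feature-dimension mismatch: {X.shape[1]} vs {Y.shape[1]}"
        )
    if spec.family == "poly":
        return (X @ Y.T + 1.0) ** spec.degree
    if spec.family == "rbf":
        sq = (
            np.sum(X * X, axis=1)[:, None]
            + np.sum(Y * Y, axis=1)[None, :]
            - 2.0 * (X @ Y.T)
        )
        np.clip(sq, 0.0, None, out=sq)
        return np.exp(-sq / (2.0 * spec.width**2))
    return np.tanh(spec.slope * (X @ Y.T) + spec.offset)


def eval_kernel(spec: KernelSpec, x: np.ndarray, y: np.ndarray) -> float:
    """Scalar kernel value k(x, y) for a single pair of feature vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return float(gram(spec, x[None, :], y[None, :])[0, 0])


@dataclass
class KernelBank:
    """M precomputed Gram matrices over the same n training points.

    ``scales`` holds the per-kernel normalisation constant (trace/n of the
    raw training Gram) so rectangular test-vs-train blocks can be scaled
    consistently with the training matrices.
    """

    specs: list[KernelSpec]
    grams: list[np.ndarray]
    n: int
    X_train: np.ndarray
    scales: np.ndarray = field(default_factory=lambda: np.array([]))
    normalized: bool = True

    @property
    def M(self) -> int:
        return len(self.specs)

    def cross(self, X_new: np.ndarray) -> list[np.ndarray]:
        """Rectangular blocks K_m(X_new, X_train), same scaling as training."""
        X_new = _check_matrix(X_new, "X_new")
        if X_new.shape[1] != self.X_train.shape[1]:
            raise ValueError(
                f"feature-dimension mismatch: model trained with "
                f"{self.X_train.shape[1]} features, got {X_new.shape[1]}"
            )
        return [
            gram(spec, X_new, self.X_train) / s
            for spec, s in zip(self.specs, self.scales)
        ]


def build_bank(
    X: np.ndarray, specs: list[KernelSpec], normalize: bool = True
) -> KernelBank:
    """Build the bank of M training Gram matrices.

    With ``normalize`` each raw Gram is divided by trace/n so its mean
    diagonal entry is 1.
    """
    X = _check_matrix(X, "X")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 training samples")
    if not specs:
        raise ValueError("kernel spec list is empty")
    grams_, scales = [], []
    for spec in specs:
        K = gram(spec, X)
        s = float(np.trace(K)) / n if normalize else 1.0
        if s <= 0 or not np.isfinite(s):
            s = 1.0
        grams_.append(K / s)
        scales.append(s)
    return KernelBank(
        specs=list(specs),
        grams=grams_,
        n=n,
        X_train=X.copy(),
        scales=np.asarray(scales),
        normalized=normalize,
    )


def combine(bank: KernelBank, d: np.ndarray) -> np.ndarray:
    """Convex combination sum_m d_m K_m of the bank's Gram matrices."""
    d = np.asarray(d, dtype=float)
    if d.shape != (bank.M,):
        raise ValueError(f"weight vector length {d.shape} != number of kernels {bank.M}")
    K = np.zeros((bank.n, bank.n))
    for dm, Km in zip(d, bank.grams):
        if dm != 0.0:
            K += dm * Km
    return K
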