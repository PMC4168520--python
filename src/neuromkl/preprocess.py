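"""ICA and orthogonalized empirical mode decomposition preprocessing.

The cognitive-task path optionally cleans the multichannel recording
before feature extraction:

* ICA separates the channels into statistically independent sources
  (fixed-point log-cosh contrast after whitening); components carrying
  most of the variance can be retained and back-projected.
* EMD sifts a 1-D signal into intrinsic mode functions (IMFs) via
  cubic-spline envelope averaging; an orthogonalisation pass makes the
  IMF set mutually orthogonal (sequential Gram-Schmidt, rescaled so the
  components still sum to the original signal minus the residual).

Preprocessing is off by default in the pipeline: no published selection
rule exists for which components to keep, so the conservative default
runs features on the raw (region-averaged) signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from sklearn.decomposition import FastICA

__all__ = [
    "ICADecomposition",
    "IMFSet",
    "ica_decompose",
    "ica_clean",
    "emd_sift",
    "orthogonalize",
]


@dataclass
class ICADecomposition:
    """Result of fitting ICA to a channels x samples matrix."""

    W: np.ndarray        # unmixing (components x channels), incl. whitening
    A: np.ndarray        # mixing (channels x components)
    S: np.ndarray        # sources (components x samples)
    mean: np.ndarray     # per-channel mean removed before unmixing
    converged: bool
    seed: int


def ica_decompose(
    X: np.ndarray,
    n_components: int | None = None,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> ICADecomposition:
    """Fixed-point ICA (log-cosh non-Gaussianity, eigen-whitening).

    ``X`` is channels x samples.  Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (channels, samples)")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    n_ch, n_s = X.shape
    if n_s < 10 * n_ch:
        raise ValueError(f"too few samples ({n_s}) for {n_ch} channels")
    ica = FastICA(
        n_components=n_components,
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    import warnings as _w

    with _w.catch_warnings(record=True) as caught:
        _w.simplefilter("always")
        S = ica.fit_transform(X.T).T
    converged = not any("did not converge" in str(c.message) for c in caught)
    W = ica.components_
    A = ica.mixing_
    return ICADecomposition(
        W=W, A=A, S=S, mean=ica.mean_, converged=converged, seed=seed
    )


def ica_clean(
    X: np.ndarray, variance_threshold: float = 0.99, seed: int = 0
) -> np.ndarray:
    """Retain the highest-variance ICs up to a cumulative explained-variance
    threshold of the back-projected signal, and reconstruct the channels."""
    dec = ica_decompose(X, seed=seed)
    # variance each component contributes to the reconstruction
    contrib = np.array(
        [np.var(np.outer(dec.A[:, i], dec.S[i])) for i in range(dec.S.shape[0])]
    )
    order = np.argsort(contrib)[::-1]
    cum = np.cumsum(contrib[order]) / contrib.sum()
    keep = order[: int(np.searchsorted(cum, variance_threshold) + 1)]
    recon = dec.A[:, keep] @ dec.S[keep] + dec.mean[:, None]
    return recon


@dataclass
class IMFSet:
    """Ordered intrinsic mode functions plus the residual trend."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    orthogonalized: bool = False

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(x)
    maxima = np.flatnonzero((np.hstack([d, -1]) < 0) & (np.hstack([1, d]) > 0))
    minima = np.flatnonzero((np.hstack([d, 1]) > 0) & (np.hstack([-1, d]) < 0))
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    # mirror the first/last extremum beyond the ends to tame boundary swings
    n = len(x)
    pts = np.concatenate([[-idx[0] - 1], idx, [2 * n - idx[-1] - 1]])
    vals = np.concatenate([[x[idx[0]]], x[idx], [x[idx[-1]]]])
    return CubicSpline(pts, vals)(np.arange(n))


def emd_sift(
    x: np.ndarray,
    max_imfs: int = 10,
    max_sifts: int = 10,
    sd_tol: float = 0.05,
) -> IMFSet:
    """Standard EMD sifting with a normalised-SD stopping criterion.

    A monotone (or extrema-poor) signal yields zero IMFs with the signal
    itself as residual.
    """
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    residual = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(max_imfs):
        maxima, minima = _extrema(residual)
        if len(maxima) + len(minima) < 4:
            break
        h = residual.copy()
        for _ in range(max_sifts):
            maxima, minima = _extrema(h)
            if len(maxima) < 2 or len(minima) < 2:
                break
            mean_env = 0.5 * (_envelope(h, maxima) + _envelope(h, minima))
            h_new = h - mean_env
            denom = np.sum(h * h)
            sd = np.sum(mean_env * mean_env) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sd_tol:
                break
        imfs.append(h)
        residual = residual - h
    return IMFSet(imfs=imfs, residual=residual, orthogonalized=False)


def orthogonalize(imfset: IMFSet) -> IMFSet:
    """Sequential Gram-Schmidt over the IMFs, reconstruction-preserving.

    Each IMF is orthogonalised against the earlier (orthogonal)
    components; the projection coefficients are folded back as scale
    factors so the orthogonal set still sums to the same total.
    """
    ortho: list[np.ndarray] = []
    coef_sums = []
    for imf in imfset.imfs:
        v = imf.astype(float).copy()
        for j, o in enumerate(ortho):
            denom = float(o @ o)
            if denom > 0:
                beta = float(imf @ o) / denom
                v -= beta * o
                coef_sums[j] += beta
        ortho.append(v)
        coef_sums.append(0.0)
    scaled = [(1.0 + c) * o for c, o in zip(coef_sums, ortho)]
    return IMFSet(imfs=scaled, residual=imfset.residual.copy(), orthogonalized=True)
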