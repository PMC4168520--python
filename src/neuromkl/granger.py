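"""Pairwise time-domain and spectral Granger causality between EEG regions.

Signal X2 Granger-causes X1 when past values of X2 improve the linear
prediction of X1 beyond X1's own past.  For the bivariate VAR(p)

    X1(t) = sum_j A11_j X1(t-j) + sum_j A12_j X2(t-j) + e1(t)
    X2(t) = sum_j A21_j X1(t-j) + sum_j A22_j X2(t-j) + e2(t)

the time-domain measure is the log ratio of residual variances between
the restricted model (A12 omitted) and the full model,

    F_{2->1} = ln( var(e1_restricted) / var(e1_full) ),

and the spectral (Geweke) measure at frequency f is

    I_{2->1}(f) = -ln(1 - (S22 - S12^2/S11) |H12(f)|^2 / S11(f)),

where Sigma is the residual covariance, H(f) the VAR transfer matrix
(inverse of the Fourier-domain coefficient matrix) and S11(f) the model
power spectrum of X1 from H Sigma H*.

For EEG connectivity the montage is reduced to five scalp regions —
fronto-central, left sensorimotor, central, right sensorimotor and
occipital — by averaging member electrodes, and the feature vector per
trial holds the theta-band (4-8 Hz) average of I for all 20 ordered
region pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochedEEG, FeatureMatrix

__all__ = [
    "REGION_MAP",
    "REGION_ORDER",
    "VARModel",
    "region_average",
    "fit_var_pair",
    "fit_ar_restricted",
    "gc_time",
    "spectral_gc",
    "select_order_bic",
    "gc_features",
    "group_difference_ttest",
]

# 18-channel montage reduced to five regions; EOG channels excluded.
REGION_ORDER = ("FCENTRAL", "LSM", "CENTRAL", "RSM", "OCCIPITAL")
REGION_MAP = {
    "FCENTRAL": ["FP1", "FP2", "F7", "F3", "FZ", "F4", "F8"],
    "LSM": ["C3", "P3"],
    "CENTRAL": ["CZ", "PZ"],
    "RSM": ["C4", "P4"],
    "OCCIPITAL": ["O1", "O2"],
}


@dataclass
class VARModel:
    """Least-squares VAR fit: coefficients per lag, residual covariance."""

    order: int
    coefs: np.ndarray      # (p, k, k): coefs[j-1] multiplies X(t-j)
    sigma: np.ndarray      # (k, k) residual covariance
    residuals: np.ndarray  # (n - p, k)

    @property
    def k(self) -> int:
        return self.coefs.shape[1]

    def companion_radius(self) -> float:
        p, k = self.order, self.k
        comp = np.zeros((k * p, k * p))
        comp[:k, :] = np.concatenate(self.coefs, axis=1)
        if p > 1:
            comp[k:, : k * (p - 1)] = np.eye(k * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))


def region_average(epochs: EpochedEEG, region_map: dict | None = None) -> EpochedEEG:
    """Average the member electrodes of each region per time point."""
    region_map = region_map if region_map is not None else REGION_MAP
    order = [r for r in REGION_ORDER if r in region_map] + [
        r for r in region_map if r not in REGION_ORDER
    ]
    out = np.empty((epochs.n_trials, len(order), epochs.n_samples))
    for i, region in enumerate(order):
        idx = [epochs.channel_index(ch) for ch in region_map[region]]
        out[:, i, :] = epochs.data[:, idx, :].mean(axis=1)
    return EpochedEEG(
        data=out,
        fs=epochs.fs,
        channels=list(order),
        labels=epochs.labels,
        subjects=epochs.subjects,
    )


def _lagged_design(X: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack p lags of the columns of X into a regression design."""
    n, k = X.shape
    Y = X[p:]
    Z = np.column_stack([X[p - j : n - j] for j in range(1, p + 1)])
    return Y, Z


def _prepare_pair(x1, x2, p: int) -> np.ndarray:
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if x1.shape != x2.shape:
        raise ValueError("signals must have equal length")
    if len(x1) <= 10 * p:
        raise ValueError(f"signal length {len(x1)} too short for order {p} (need > {10 * p})")
    X = np.column_stack([x1, x2])
    return X - X.mean(axis=0)


def fit_var_pair(x1: np.ndarray, x2: np.ndarray, p: int) -> VARModel:
    """Full bivariate VAR(p) by per-equation least squares (demeaned)."""
    X = _prepare_pair(x1, x2, p)
    Y, Z = _lagged_design(X, p)
    B, _, rank, _ = np.linalg.lstsq(Z, Y, rcond=None)
    if rank < Z.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient lag regression")
    resid = Y - Z @ B
    sigma = resid.T @ resid / resid.shape[0]
    # B rows are ordered (lag1: x1, x2), (lag2: x1, x2), ...
    coefs = np.stack([B[2 * j : 2 * j + 2].T for j in range(p)])
    return VARModel(order=p, coefs=coefs, sigma=sigma, residuals=resid)


def fit_ar_restricted(x1: np.ndarray, p: int) -> VARModel:
    """Univariate AR(p) of x1 alone — the restricted model."""
    x1 = np.asarray(x1, dtype=float).ravel()
    if len(x1) <= 10 * p:
        raise ValueError(f"signal length {len(x1)} too short for order {p}")
    X = (x1 - x1.mean())[:, None]
    Y, Z = _lagged_design(X, p)
    B, _, rank, _ = np.linalg.lstsq(Z, Y, rcond=None)
    if rank < Z.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient lag regression")
    resid = Y - Z @ B
    sigma = resid.T @ resid / resid.shape[0]
    coefs = B.reshape(p, 1, 1)
    return VARModel(order=p, coefs=coefs, sigma=sigma, residuals=resid)


def gc_time(x1: np.ndarray, x2: np.ndarray, p: int) -> float:
    """Time-domain causality F_{2->1} = ln(var restricted / var full)."""
    full = fit_var_pair(x1, x2, p)
    restricted = fit_ar_restricted(x1, p)
    v_full = float(full.sigma[0, 0])
    v_res = float(restricted.sigma[0, 0])
    if v_full <= 0 or v_res <= 0:
        raise ValueError("zero residual variance; causality undefined")
    return float(np.log(v_res / v_full))


def spectral_gc(model: VARModel, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Spectral causality I_{2->1}(f) on a frequency grid (Hz).

    Requires a stable bivariate VAR (companion spectral radius < 1).
    """
    if model.k != 2:
        raise ValueError("spectral causality needs a bivariate model")
    if model.companion_radius() >= 1.0:
        raise ValueError("unstable VAR: companion spectral radius >= 1")
    freqs = np.asarray(freqs, dtype=float)
    sig = model.sigma
    s11, s22, s12 = sig[0, 0], sig[1, 1], sig[0, 1]
    partial = s22 - (s12 * s12) / s11 if s11 > 0 else s22
    out = np.empty(freqs.shape)
    eye = np.eye(2, dtype=complex)
    for idx, f in enumerate(freqs):
        A_f = eye.copy()
        for j in range(model.order):
            A_f -= model.coefs[j] * np.exp(-2j * np.pi * f * (j + 1) / fs)
        H = np.linalg.inv(A_f)
        S = H @ sig @ H.conj().T
        S11 = float(S[0, 0].real)
        ratio = partial * abs(H[0, 1]) ** 2 / S11 if S11 > 0 else 0.0
        out[idx] = -np.log(max(1.0 - ratio, 1e-300))
    return out


def select_order_bic(x1: np.ndarray, x2: np.ndarray, p_max: int = 20) -> int:
    """VAR order minimising the BIC of the bivariate fit."""
    x1 = np.asarray(x1, dtype=float).ravel()
    best_p, best_bic = 1, np.inf
    for p in range(1, p_max + 1):
        if len(x1) <= 10 * p:
            break
        model = fit_var_pair(x1, x2, p)
        nobs = model.residuals.shape[0]
        sign, logdet = np.linalg.slogdet(model.sigma)
        if sign <= 0:
            continue
        bic = logdet + np.log(nobs) * (4 * p) / nobs
        if bic < best_bic:
            best_p, best_bic = p, bic
    return best_p


def gc_features(
    epochs: EpochedEEG,
    band: tuple[float, float] = (4.0, 8.0),
    p: int | None = None,
    freq_step: float = 0.5,
) -> FeatureMatrix:
    """Per-trial band-averaged spectral causality for all ordered pairs.

    Column order is source-major over the region channels: for each
    source region, all targets in channel order.  ``p=None`` selects the
    order per trial/pair by BIC (1..20); an integer fixes it.
    """
    fs = epochs.fs
    freqs = np.arange(0.0, fs / 2.0 + freq_step / 2, freq_step)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    regions = epochs.channels
    pairs = [(s, t) for s in range(len(regions)) for t in range(len(regions)) if t != s]
    columns = [f"{regions[s]}->{regions[t]}" for s, t in pairs]
    values = np.empty((epochs.n_trials, len(pairs)))
    for trial in range(epochs.n_trials):
        for j, (s, t) in enumerate(pairs):
            x_target = epochs.data[trial, t]
            x_source = epochs.data[trial, s]
            order = p if p is not None else select_order_bic(x_target, x_source)
            model = fit_var_pair(x_target, x_source, order)
            spec = spectral_gc(model, freqs[in_band], fs)
            values[trial, j] = float(np.mean(spec))
    return FeatureMatrix(
        values=values,
        columns=columns,
        labels=epochs.labels,
        subjects=epochs.subjects,
        provenance={"path": "granger", "band": list(band), "p": p,
                    "freq_step": freq_step},
    )


def group_difference_ttest(
    features: FeatureMatrix, group_a, group_b
) -> tuple[float, float]:
    """Two-sample t-test on mean connectivity between two label groups.

    Thin reporting utility (standard statistic): compares the per-trial
    mean over all feature columns between the two groups.
    """
    from scipy import stats

    a = features.values[features.labels == group_a].mean(axis=1)
    b = features.values[features.labels == group_b].mean(axis=1)
    t, pval = stats.ttest_ind(a, b)
    return float(t), float(pval)
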