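"""Seeded synthetic-EEG generators for both feature paths.

Two statistical structures are emulated:

* **Mental-task EEG** — per class, each channel is a sum over the four
  rhythm bands of band-limited Gaussian noise (4th-order zero-phase
  Butterworth filtered white noise) scaled by the class's band power and
  a per-channel gain, plus a broadband noise floor.  Classes differing
  in, say, alpha power produce trials whose wavelet-band entropies
  separate.  Defaults: 6 channels (C3, C4, P3, P4, O1, O2), 250 Hz,
  10 s trials.

* **Coupled-VAR region signals** — five region channels simulated from
  a stable VAR whose diagonal dynamics are AR(2) oscillators resonant at
  a chosen frequency (default 6 Hz, theta) and whose off-diagonal lag-1
  terms realise a known directed coupling matrix.  A "patients vs
  controls" contrast halves designated couplings, mimicking the reduced
  fronto-central connectivity reported for stroke patients.  Defaults:
  256 Hz, 13 subjects per group.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
from scipy import signal as sps

from .containers import EpochedEEG

__all__ = [
    "MentalTaskSpec",
    "ConnectivitySpec",
    "BAND_DEFS_HZ",
    "MENTAL_CHANNELS",
    "gen_mental_eeg",
    "gen_coupled_var",
    "gen_two_group_study",
    "default_control_spec",
    "default_patient_spec",
    "theta_coupled_spec",
    "bandlimited_noise",
]

MENTAL_CHANNELS = ["C3", "C4", "P3", "P4", "O1", "O2"]
# lower delta edge kept off 0 Hz so the band-pass filter is well posed
BAND_DEFS_HZ = {"delta": (0.5, 4.0), "theta": (4.0, 8.0),
                "alpha": (8.0, 12.0), "beta": (12.0, 32.0)}


@dataclass
class MentalTaskSpec:
    """Per-class recipe for band-structured EEG trials."""

    name: str
    band_power: dict = field(
        default_factory=lambda: {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0}
    )
    channel_gain: np.ndarray | None = None  # defaults to ones
    noise_floor: float = 0.25
    fs: float = 250.0
    duration: float = 10.0

    def __post_init__(self) -> None:
        for band, p in self.band_power.items():
            if p < 0:
                raise ValueError(f"band power for {band} must be >= 0")


def bandlimited_noise(
    n: int, fs: float, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to [lo, hi] Hz
    (4th-order Butterworth, zero-phase)."""
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    s = x.std()
    return x / s if s > 0 else x


def gen_mental_eeg(
    specs: list[MentalTaskSpec], trials_per_class: int, seed: int
) -> EpochedEEG:
    """Generate labelled trials for each class spec."""
    if len(specs) < 2:
        raise ValueError("need at least 2 class specs")
    if trials_per_class <= 0:
        raise ValueError("trials_per_class must be positive")
    fs = specs[0].fs
    n_samples = int(round(specs[0].fs * specs[0].duration))
    rng = np.random.default_rng(seed)
    n_ch = len(MENTAL_CHANNELS)
    data, labels = [], []
    for spec in specs:
        if spec.fs != fs or int(round(spec.fs * spec.duration)) != n_samples:
            raise ValueError("all class specs must share fs and duration")
        gain = (
            np.ones(n_ch)
            if spec.channel_gain is None
            else np.asarray(spec.channel_gain, dtype=float)
        )
        if gain.shape != (n_ch,):
            raise ValueError(f"channel_gain must have length {n_ch}")
        for _ in range(trials_per_class):
            trial = np.zeros((n_ch, n_samples))
            for band, (lo, hi) in BAND_DEFS_HZ.items():
                power = spec.band_power.get(band, 0.0)
                if power <= 0:
                    continue
                amp = np.sqrt(power)
                for c in range(n_ch):
                    trial[c] += amp * gain[c] * bandlimited_noise(n_samples, fs, lo, hi, rng)
            trial += spec.noise_floor * rng.standard_normal((n_ch, n_samples))
            data.append(trial)
            labels.append(spec.name)
    return EpochedEEG(
        data=np.stack(data), fs=fs, channels=MENTAL_CHANNELS,
        labels=np.asarray(labels),
    )


# ---------------------------------------------------------------------------
# Coupled-VAR connectivity generator
# ---------------------------------------------------------------------------

REGION_NAMES = ["FCENTRAL", "LSM", "CENTRAL", "RSM", "OCCIPITAL"]


@dataclass
class ConnectivitySpec:
    """Recipe for five-region coupled-oscillator VAR signals.

    The diagonal of the VAR holds AR(2) oscillators with poles at
    ``resonance_hz`` and radius ``pole_radius``; ``coupling[s, t]`` is
    the lag-1 coefficient driving region t from region s.
    """

    coupling: np.ndarray = field(default_factory=lambda: np.zeros((5, 5)))
    resonance_hz: float = 6.0
    pole_radius: float = 0.95
    noise_scale: float = 1.0
    fs: float = 256.0
    group: str = "control"

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.coupling.shape != (5, 5):
            raise ValueError("coupling matrix must be 5x5")
        if np.any(np.diag(self.coupling) != 0):
            raise ValueError("coupling diagonal must be zero (intrinsic dynamics are AR(2))")

    def var_coefs(self) -> np.ndarray:
        """(2, 5, 5) lag-coefficient matrices of the generating VAR."""
        theta = 2.0 * np.pi * self.resonance_hz / self.fs
        a1 = 2.0 * self.pole_radius * np.cos(theta)
        a2 = -self.pole_radius**2
        A1 = np.eye(5) * a1 + self.coupling.T  # row = target equation
        A2 = np.eye(5) * a2
        return np.stack([A1, A2])

    def companion_radius(self) -> float:
        A = self.var_coefs()
        k = 5
        comp = np.zeros((2 * k, 2 * k))
        comp[:k, :k] = A[0]
        comp[:k, k:] = A[1]
        comp[k:, :k] = np.eye(k)
        return float(np.max(np.abs(np.linalg.eigvals(comp))))


def default_control_spec() -> ConnectivitySpec:
    """Healthy-control coupling: bidirectional fronto-central plus a
    left-to-right sensorimotor link (the pairs reported disconnected in
    patients during the 0-back task).

    The bidirectional F<->C loop bounds the admissible oscillator
    damping: near-unit-circle low-frequency AR(2) poles have enormous
    DC gain, so with lag-1 feedback of 0.4 the joint VAR is only stable
    for pole radius around 0.35 or below.  Unidirectional specs can use
    much sharper resonances (see :func:`theta_coupled_spec`).
    """
    coupling = np.zeros((5, 5))
    idx = {r: i for i, r in enumerate(REGION_NAMES)}
    coupling[idx["FCENTRAL"], idx["CENTRAL"]] = 0.4
    coupling[idx["CENTRAL"], idx["FCENTRAL"]] = 0.4
    coupling[idx["LSM"], idx["RSM"]] = 0.4
    return ConnectivitySpec(coupling=coupling, pole_radius=0.35, group="control")


def theta_coupled_spec(strength: float = 0.4) -> ConnectivitySpec:
    """Unidirectional F->C coupling between sharply theta-resonant
    oscillators (pole radius 0.95 at 6 Hz).  With no feedback loop the
    VAR is block-triangular, hence stable for any coupling strength."""
    coupling = np.zeros((5, 5))
    idx = {r: i for i, r in enumerate(REGION_NAMES)}
    coupling[idx["FCENTRAL"], idx["CENTRAL"]] = strength
    return ConnectivitySpec(coupling=coupling, pole_radius=0.95, group="coupled")


def default_patient_spec(reduction: float = 0.5) -> ConnectivitySpec:
    """Patient spec: the control couplings scaled down by ``reduction``,
    emulating the reduced cortical connectivity of the patient group."""
    spec = default_control_spec()
    return replace(spec, coupling=spec.coupling * reduction, group="patient")


DESIGNATED_PAIRS = [("FCENTRAL", "CENTRAL"), ("CENTRAL", "FCENTRAL"), ("LSM", "RSM")]


def gen_coupled_var(
    spec: ConnectivitySpec,
    trials: int,
    n_samples: int = 1024,
    seed: int = 0,
    burn_in: int = 500,
    label: str | None = None,
) -> EpochedEEG:
    """Simulate trials from the spec's VAR, discarding the burn-in."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    radius = spec.companion_radius()
    if radius >= 0.98:
        raise ValueError(f"unstable generator VAR (companion radius {radius:.3f} >= 0.98)")
    A = spec.var_coefs()
    rng = np.random.default_rng(seed)
    data = np.empty((trials, 5, n_samples))
    total = burn_in + n_samples
    for t in range(trials):
        x = np.zeros((total, 5))
        e = spec.noise_scale * rng.standard_normal((total, 5))
        for i in range(2, total):
            x[i] = A[0] @ x[i - 1] + A[1] @ x[i - 2] + e[i]
        data[t] = x[burn_in:].T
    lab = label if label is not None else spec.group
    return EpochedEEG(
        data=data, fs=spec.fs, channels=REGION_NAMES,
        labels=np.asarray([lab] * trials),
    )


def gen_two_group_study(
    control_spec: ConnectivitySpec | None = None,
    patient_spec: ConnectivitySpec | None = None,
    subjects_per_group: int = 13,
    trials_per_subject: int = 4,
    n_samples: int = 1024,
    seed: int = 0,
    jitter_sigma: float = 0.1,
) -> EpochedEEG:
    """Two-group study with subject-level lognormal gain jitter.

    Returns one ``EpochedEEG`` with group labels and subject ids, ready
    for subject-wise cross-validation splits.
    """
    control_spec = control_spec or default_control_spec()
    patient_spec = patient_spec or default_patient_spec()
    if (
        jitter_sigma == 0.0
        and np.array_equal(control_spec.coupling, patient_spec.coupling)
    ):
        warnings.warn("identical group specs with zero jitter: degenerate study")
    rng = np.random.default_rng(seed)
    all_data, labels, subjects = [], [], []
    for g, spec in (("control", control_spec), ("patient", patient_spec)):
        for s in range(subjects_per_group):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            eeg = gen_coupled_var(
                spec, trials_per_subject, n_samples=n_samples, seed=sub_seed, label=g
            )
            gains = np.exp(jitter_sigma * rng.standard_normal(5)) if jitter_sigma > 0 else np.ones(5)
            all_data.append(eeg.data * gains[None, :, None])
            labels += [g] * trials_per_subject
            subjects += [f"{g}_{s:02d}"] * trials_per_subject
    return EpochedEEG(
        data=np.concatenate(all_data),
        fs=control_spec.fs,
        channels=REGION_NAMES,
        labels=np.asarray(labels),
        subjects=np.asarray(subjects),
    )
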