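"""Cross-validation harness and end-to-end experiment driver.

Ties the feature paths to the classifier: wavelet-packet entropy for
mental-task EEG, theta-band spectral Granger causality for cognitive
(N-back style) EEG, both feeding the multiple-kernel SVM under
stratified 5-fold cross-validation (80% train / 20% test per fold).
When subject ids are present the folds split *subjects*, never trials
of one subject across train and test.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import multiclass, simplemkl
from .containers import CVResult, EpochedEEG, FeatureMatrix, load_eeg, save_features
from .kernels import KernelSpec, default_specs
from .simplemkl import SolverSettings

__all__ = [
    "kfold_cv",
    "single_kernel_cv",
    "permutation_cv",
    "run_experiment",
    "paired_ttest",
]


def _fold_indices(
    labels: np.ndarray,
    subjects: np.ndarray | None,
    k: int,
    seed: int,
    subject_wise: bool | str = "auto",
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold index pairs; grouped by subject when ids exist."""
    use_subjects = (
        subjects is not None if subject_wise == "auto" else bool(subject_wise)
    )
    if use_subjects and subjects is None:
        raise ValueError("subject-wise folds requested but no subject ids present")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    if not use_subjects:
        classes, counts = np.unique(labels, return_counts=True)
        if counts.min() < k:
            raise ValueError(
                f"class {classes[np.argmin(counts)]!r} has fewer samples than folds ({k})"
            )
        return list(skf.split(np.zeros(len(labels)), labels))
    # stratify subjects by their (single) class, then expand to trials
    subj_ids, first_idx = np.unique(subjects, return_index=True)
    subj_labels = labels[first_idx]
    folds = []
    for train_s, test_s in skf.split(np.zeros(len(subj_ids)), subj_labels):
        train_mask = np.isin(subjects, subj_ids[train_s])
        test_mask = np.isin(subjects, subj_ids[test_s])
        folds.append((np.flatnonzero(train_mask), np.flatnonzero(test_mask)))
    return folds


def kfold_cv(
    features: FeatureMatrix,
    k: int = 5,
    specs: list[KernelSpec] | None = None,
    settings: SolverSettings | None = None,
    seed: int = 0,
    subject_wise: bool | str = "auto",
) -> CVResult:
    """Stratified k-fold cross-validation of the MKL classifier.

    Binary problems use the binary solver directly; K > 2 classes use
    one-vs-rest.  Feature standardisation happens inside the model fit,
    on training-fold statistics only.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    specs = specs if specs is not None else default_specs()
    settings = settings or SolverSettings()
    X, y = features.values, features.labels
    classes = np.unique(y)
    folds = _fold_indices(y, features.subjects, k, seed, subject_wise)
    accs, weights = [], []
    conf = pd.DataFrame(0, index=classes, columns=classes)
    for train_idx, test_idx in folds:
        Xtr, ytr = X[train_idx], y[train_idx]
        Xte, yte = X[test_idx], y[test_idx]
        if classes.size == 2:
            model = simplemkl.fit(Xtr, ytr, specs, settings)
            pred = simplemkl.predict(model, Xte)
            weights.append(model.d)
        else:
            ovr = multiclass.fit_ovr(Xtr, ytr, specs, settings)
            pred = multiclass.predict_ovr(ovr, Xte)
            weights.append(multiclass.pooled_kernel_weights(ovr))
        accs.append(float(np.mean(pred == yte)))
        for true, hat in zip(yte, pred):
            conf.loc[true, hat] += 1
    return CVResult(
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        confusion=conf,
        seed=seed,
        settings={"C": settings.C, "gap_tol": settings.gap_tol, "k": k,
                  "M": len(specs)},
        kernel_weights=weights,
    )


def single_kernel_cv(
    features: FeatureMatrix,
    specs: list[KernelSpec] | None = None,
    k: int = 5,
    settings: SolverSettings | None = None,
    seed: int = 0,
    subject_wise: bool | str = "auto",
) -> dict[str, float]:
    """Mean CV accuracy of a plain single-kernel SVM for each candidate
    kernel (same folds as :func:`kfold_cv` at the same seed)."""
    specs = specs if specs is not None else default_specs()
    out = {}
    for spec in specs:
        res = kfold_cv(features, k=k, specs=[spec], settings=settings,
                       seed=seed, subject_wise=subject_wise)
        out[spec.label()] = res.mean_accuracy
    return out


def permutation_cv(
    features: FeatureMatrix,
    k: int = 5,
    specs: list[KernelSpec] | None = None,
    settings: SolverSettings | None = None,
    seed: int = 0,
    subject_wise: bool | str = "auto",
) -> CVResult:
    """CV after shuffling the labels — the chance-level control.

    Subject-wise data shuffles labels at the subject level so every
    trial of a subject keeps one (random) label.
    """
    rng = np.random.default_rng(seed)
    labels = features.labels.copy()
    if features.subjects is not None:
        subj_ids, first_idx = np.unique(features.subjects, return_index=True)
        subj_labels = labels[first_idx].copy()
        rng.shuffle(subj_labels)
        lut = dict(zip(subj_ids, subj_labels))
        labels = np.asarray([lut[s] for s in features.subjects])
    else:
        rng.shuffle(labels)
    shuffled = FeatureMatrix(
        values=features.values,
        columns=features.columns,
        labels=labels,
        subjects=features.subjects,
        provenance={**features.provenance, "permuted": True},
    )
    return kfold_cv(shuffled, k=k, specs=specs, settings=settings, seed=seed,
                    subject_wise=subject_wise)


def paired_ttest(acc_a: np.ndarray, acc_b: np.ndarray) -> tuple[float, float]:
    """Paired t-test between per-fold (or per-subject) accuracies of two
    classifier variants.  Standard statistic, reporting utility only."""
    from scipy import stats

    t, p = stats.ttest_rel(np.asarray(acc_a, float), np.asarray(acc_b, float))
    return float(t), float(p)


# ---------------------------------------------------------------------------
# End-to-end experiment
# ---------------------------------------------------------------------------

def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_experiment(config: dict, out_dir: str | Path | None = None) -> CVResult:
    """Run one experiment path end to end from a config dict.

    Required keys: ``path`` ("wpe" | "granger") and a data source —
    either ``data``/``meta`` CSV+sidecar file paths or ``synth`` with
    generator settings.  Optional: ``C``, ``gap_tol``, ``folds``,
    ``seed``, ``kernels`` ({"poly_degrees": [...], "rbf_widths": [...]}),
    ``var_order``, ``preprocess_ica``.
    Writes features, per-fold kernel-weight summary and a run manifest
    to ``out_dir`` when given.
    """
    path = config.get("path")
    if path not in ("wpe", "granger"):
        raise ValueError("config['path'] must be 'wpe' or 'granger'")
    seed = int(config.get("seed", 0))
    epochs = _load_source(config, seed)
    if path == "wpe":
        from . import wpe as _wpe

        features = _wpe.wpe_features(epochs)
    else:
        from . import granger as _granger

        if config.get("preprocess_ica", False):
            from . import preprocess as _pre

            cleaned = np.stack(
                [_pre.ica_clean(trial, seed=seed) for trial in epochs.data]
            )
            epochs = EpochedEEG(cleaned, epochs.fs, epochs.channels,
                                epochs.labels, epochs.subjects)
        if set(epochs.channels) != set(_granger.REGION_ORDER):
            epochs = _granger.region_average(epochs)
        features = _granger.gc_features(epochs, p=config.get("var_order"))

    kconf = config.get("kernels")
    if kconf:
        specs = [KernelSpec("poly", degree=d) for d in kconf.get("poly_degrees", [])]
        specs += [KernelSpec("rbf", width=w) for w in kconf.get("rbf_widths", [])]
    else:
        specs = default_specs()
    settings = SolverSettings(
        C=float(config.get("C", 100.0)),
        gap_tol=float(config.get("gap_tol", 0.01)),
        seed=seed,
    )
    result = kfold_cv(features, k=int(config.get("folds", 5)), specs=specs,
                      settings=settings, seed=seed)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_features(features, out_dir / "features.csv")
        weights = np.vstack([np.atleast_2d(w) for w in result.kernel_weights])
        pd.DataFrame(weights, columns=[s.label() for s in specs]).to_csv(
            out_dir / "kernel_weights.csv", index=False
        )
        manifest = {
            "config": config,
            "config_hash": _config_hash(config),
            "fold_accuracies": result.fold_accuracies,
            "mean_accuracy": result.mean_accuracy,
            "settings": result.settings,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, default=str, indent=1))
        result.confusion.to_csv(out_dir / "confusion.csv")
    return result


def _load_source(config: dict, seed: int) -> EpochedEEG:
    if "data" in config:
        return load_eeg(config["data"], config.get("meta"))
    synth = config.get("synth")
    if not synth:
        raise ValueError("config needs either 'data'/'meta' paths or a 'synth' block")
    from . import synthdata as _syn

    kind = synth.get("kind", "mental")
    if kind == "mental":
        specs = []
        for cls in synth["classes"]:
            specs.append(_syn.MentalTaskSpec(name=cls["name"],
                                             band_power=cls.get("band_power", None)
                                             or {"delta": 1, "theta": 1, "alpha": 1, "beta": 1}))
        return _syn.gen_mental_eeg(specs, int(synth.get("trials_per_class", 40)), seed)
    if kind == "two_group":
        return _syn.gen_two_group_study(
            subjects_per_group=int(synth.get("subjects_per_group", 13)),
            trials_per_subject=int(synth.get("trials_per_subject", 4)),
            n_samples=int(synth.get("n_samples", 1024)),
            seed=seed,
        )
    raise ValueError(f"unknown synth kind {kind!r}")
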