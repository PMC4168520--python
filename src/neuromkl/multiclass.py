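"""One-versus-rest extension of the binary MKL-SVM to K classes.

One binary model is trained per class (that class relabelled +1, the
rest -1); a test sample is assigned to the class whose model produces
the largest real-valued decision score.  Each binary problem learns its
own kernel weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import simplemkl
from .kernels import KernelSpec
from .simplemkl import MKLModel, SolverSettings

__all__ = ["OvRModel", "fit_ovr", "predict_ovr", "decision_matrix",
           "pooled_kernel_weights", "save_ovr", "load_ovr"]


@dataclass
class OvRModel:
    class_labels: list
    models: list[MKLModel]

    @property
    def K(self) -> int:
        return len(self.class_labels)


def fit_ovr(
    X: np.ndarray,
    y: np.ndarray,
    specs: list[KernelSpec],
    settings: SolverSettings | None = None,
) -> OvRModel:
    """Train K binary one-vs-rest MKL models."""
    y = np.asarray(y).ravel()
    classes = list(np.unique(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if np.sum(y == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 training samples")
    models = []
    for c in classes:
        y_bin = np.where(y == c, 1, -1)
        models.append(simplemkl.fit(X, y_bin, specs, settings))
    return OvRModel(class_labels=classes, models=models)


def decision_matrix(model: OvRModel, X_new: np.ndarray) -> np.ndarray:
    """n x K matrix of per-class decision scores."""
    return np.column_stack(
        [simplemkl.decision_function(m, X_new) for m in model.models]
    )


def predict_ovr(model: OvRModel, X_new: np.ndarray) -> np.ndarray:
    """Argmax of the K decision scores; ties go to the earlier class."""
    scores = decision_matrix(model, X_new)
    idx = np.argmax(scores, axis=1)  # first maximum on exact ties
    return np.asarray([model.class_labels[i] for i in idx])


def pooled_kernel_weights(model: OvRModel) -> np.ndarray:
    """K x M matrix of learned kernel weights, one row per binary problem.

    Weight summaries (e.g. boxplots across classification problems) pool
    these rows.
    """
    return np.vstack([m.d for m in model.models])


def save_ovr(model: OvRModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"class_labels": [simplemkl._jsonable(c) for c in model.class_labels],
                "files": []}
    for i, m in enumerate(model.models):
        fname = f"class_{i}.json"
        simplemkl.save_model(m, directory / fname)
        manifest["files"].append(fname)
    (directory / "manifest.json").write_text(json.dumps(manifest))


def load_ovr(directory: str | Path) -> OvRModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    models = [simplemkl.load_model(directory / f) for f in manifest["files"]]
    return OvRModel(class_labels=manifest["class_labels"], models=models)
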