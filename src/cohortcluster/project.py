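"""Project training-derived cluster labels onto a validation cohort.

A feed-forward classifier (single hidden layer, width ``hidden_multiplier *
n_markers``) is trained on the classified training samples; a deterministic
nearest-centroid model is available as a config choice and is forced when
the training labels cannot support a classifier (fewer than two clusters
with at least two members).  The projected clustering carries the training
label ids, so equivalent clusters across cohorts are label-identical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .cohort import UNCLASSIFIED, Clustering, CohortError, CohortMatrix

log = logging.getLogger(__name__)


@dataclass
class ProjectorConfig:
    method: str = "mlp"  # "mlp" or "centroid"
    hidden_multiplier: int = 2
    max_iter: int = 300
    tol: float = 1e-5
    seed: int = 0


@dataclass
class Projector:
    kind: str  # "mlp", "centroid" or "constant"
    marker_names: list[str]
    classes: np.ndarray
    model: object | None = None
    centroids: np.ndarray | None = None
    constant_label: int | None = None
    train_accuracy: float = float("nan")
    seed: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.kind == "constant":
            return np.full(X.shape[0], self.constant_label, dtype=int)
        if self.kind == "centroid":
            d2 = ((X[:, None, :] - self.centroids[None, :, :]) ** 2).sum(-1)
            return self.classes[np.argmin(d2, axis=1)]
        return np.asarray(self.model.predict(X), dtype=int)


def _centroid_projector(X, y, classes, marker_names, seed) -> Projector:
    cents = np.array([X[y == c].mean(axis=0) for c in classes])
    proj = Projector("centroid", marker_names, classes, centroids=cents, seed=seed)
    proj.train_accuracy = float(np.mean(proj.predict(X) == y))
    return proj


def train_projector(
    cohort: CohortMatrix,
    clustering: Clustering,
    config: ProjectorConfig | None = None,
) -> Projector:
    """Fit a projector on the classified samples of a training clustering."""
    config = config or ProjectorConfig()
    if not np.array_equal(cohort.sample_ids, clustering.sample_ids):
        raise CohortError("clustering ids do not match cohort ids")
    mask = clustering.labels != UNCLASSIFIED
    if not mask.any():
        raise CohortError("no classified training samples to fit on")
    X = np.asarray(cohort.markers, float)[mask]
    y = clustering.labels[mask]
    classes, counts = np.unique(y, return_counts=True)
    names = list(cohort.marker_names)

    if classes.size == 1:
        log.info("single-cluster training input: constant projector")
        proj = Projector("constant", names, classes, constant_label=int(classes[0]),
                         seed=config.seed)
        proj.train_accuracy = 1.0
        return proj
    if np.sum(counts >= 2) < 2 or config.method == "centroid":
        if config.method != "centroid":
            log.info("too few populated clusters for a classifier; nearest-centroid fallback")
        return _centroid_projector(X, y, classes, names, config.seed)

    hidden = max(2, config.hidden_multiplier * cohort.n_markers)
    model = MLPClassifier(
        hidden_layer_sizes=(hidden,),
        max_iter=config.max_iter,
        tol=config.tol,
        random_state=int(config.seed),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    proj = Projector("mlp", names, classes, model=model, seed=config.seed)
    proj.train_accuracy = float(np.mean(model.predict(X) == y))
    return proj


def project(projector: Projector, cohort: CohortMatrix) -> Clustering:
    """Assign every validation sample to a training cluster label."""
    if list(cohort.marker_names) != list(projector.marker_names):
        a, b = set(cohort.marker_names), set(projector.marker_names)
        diff = sorted(a.symmetric_difference(b))
        raise CohortError(f"marker set mismatch between cohorts: {diff}")
    X = np.asarray(cohort.markers, float)
    raw = projector.predict(X)
    # training label ids are carried over verbatim so "equivalent clusters"
    # across cohorts are label-identical (a training label may end up empty)
    return Clustering(
        cohort.sample_ids,
        raw,
        provenance={"algorithm": "projection", "kind": projector.kind,
                    "train_accuracy": projector.train_accuracy},
    )
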