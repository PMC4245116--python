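"""Fisher discriminant analysis: two-class rules and a multi-class variant.

The two-class rule is the cascade workhorse: a linear score
``y = a_1 x_1 + ... + a_n x_n`` with weights proportional to
``(S_w + ridge I)^{-1} (mu_A - mu_B)`` (pooled within-class scatter S_w)
and a threshold at the midpoint of the projected class means, optionally
shifted by the log prior ratio.  The multi-class variant projects onto the
canonical directions of ``S_w^{-1} S_b`` and classifies by the nearest
class centroid in that space; with two classes and no prior shift it is
decision-equivalent to the two-class rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg


class DegenerateRule(ValueError):
    """The projected class means coincide; no discriminating direction."""


class SingularScatter(np.linalg.LinAlgError):
    """Within-class scatter not invertible even after ridge regularization."""


def _as_matrix(table, columns) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        return table[list(columns)].to_numpy(float)
    return np.asarray(table, float)


def _within_scatter(X: np.ndarray, y: np.ndarray, classes) -> np.ndarray:
    sw = np.zeros((X.shape[1], X.shape[1]))
    for c in classes:
        xc = X[y == c]
        d = xc - xc.mean(axis=0)
        sw += d.T @ d
    return sw


def _default_ridge(sw: np.ndarray, n: int) -> float:
    return 1e-6 * np.trace(sw) / max(n, 1)


@dataclass
class FisherRule:
    """Trained two-class linear discriminant."""

    feature_columns: list
    weights: np.ndarray
    threshold: float
    class_pair: tuple  # (label_A, label_B); score >= threshold -> label_A
    ridge: float
    prior_shift: bool = False

    def scores(self, table) -> np.ndarray:
        X = np.atleast_2d(_as_matrix(table, self.feature_columns))
        return X @ self.weights

    def classify(self, table) -> np.ndarray:
        """Label per row; scores at the threshold go to the first class."""
        y = self.scores(table)
        a, b = self.class_pair
        return np.where(y >= self.threshold, a, b)

    def to_dict(self) -> dict:
        return {
            "feature_columns": list(self.feature_columns),
            "weights": [float(w) for w in self.weights],
            "threshold": float(self.threshold),
            "class_pair": list(self.class_pair),
            "ridge": float(self.ridge),
            "prior_shift": self.prior_shift,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FisherRule":
        return cls(
            feature_columns=list(d["feature_columns"]),
            weights=np.asarray(d["weights"], float),
            threshold=float(d["threshold"]),
            class_pair=tuple(d["class_pair"]),
            ridge=float(d["ridge"]),
            prior_shift=bool(d.get("prior_shift", False)),
        )


def fit_two_class(
    table,
    labels,
    subset_columns=None,
    class_pair=None,
    ridge: float | None = None,
    prior_shift: bool = False,
) -> FisherRule:
    """Fit a two-class Fisher rule on the given feature columns.

    ``class_pair`` fixes which label sits on the high-score side (defaults
    to sorted order).  ``prior_shift`` subtracts ``ln(n_A/n_B)`` from the
    midpoint threshold (covariance-scaled weights), matching unequal
    class priors; it is off by default for balanced designs.
    """
    y = np.asarray(labels)
    if subset_columns is None:
        subset_columns = list(table.columns)
    X = _as_matrix(table, subset_columns)
    classes = sorted(np.unique(y)) if class_pair is None else list(class_pair)
    if len(np.unique(y)) != 2:
        raise ValueError("fit_two_class requires exactly two classes")
    a, b = classes
    na, nb = int((y == a).sum()), int((y == b).sum())
    if min(na, nb) < 2:
        raise ValueError("each class needs at least 2 samples")

    mu_a = X[y == a].mean(axis=0)
    mu_b = X[y == b].mean(axis=0)
    sw = _within_scatter(X, y, (a, b))
    if ridge is None:
        ridge = _default_ridge(sw, len(y))
    if prior_shift:
        # covariance scaling so the log-prior term is on the right scale
        sw = sw / (len(y) - 2)
        ridge = ridge / (len(y) - 2)
    try:
        w = linalg.solve(sw + ridge * np.eye(sw.shape[0]), mu_a - mu_b,
                         assume_a="pos")
    except linalg.LinAlgError as exc:  # pragma: no cover
        raise SingularScatter(str(exc)) from exc
    if not np.all(np.isfinite(w)):
        raise SingularScatter("non-finite discriminant weights")

    pa, pb = float(w @ mu_a), float(w @ mu_b)
    if abs(pa - pb) < 1e-12 * max(1.0, abs(pa), abs(pb)):
        raise DegenerateRule("projected class means coincide")
    if pa < pb:  # keep label_A on the high side
        w, pa, pb = -w, -pa, -pb
    threshold = (pa + pb) / 2.0
    if prior_shift:
        threshold -= np.log(na / nb)
    return FisherRule(
        feature_columns=list(subset_columns),
        weights=w,
        threshold=threshold,
        class_pair=(a, b),
        ridge=float(ridge),
        prior_shift=prior_shift,
    )


@dataclass
class MultiClassFisherModel:
    """Canonical-variate Fisher model with nearest-centroid classification."""

    feature_columns: list
    directions: np.ndarray  # n_features x n_directions
    centroids: np.ndarray  # n_classes x n_directions
    class_labels: list
    ridge: float

    def transform(self, table) -> np.ndarray:
        X = _as_matrix(table, self.feature_columns)
        return np.atleast_2d(X) @ self.directions

    def classify(self, table) -> np.ndarray:
        Z = self.transform(table)
        d2 = ((Z[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return np.asarray(self.class_labels)[np.argmin(d2, axis=1)]

    def to_dict(self) -> dict:
        return {
            "feature_columns": list(self.feature_columns),
            "directions": self.directions.tolist(),
            "centroids": self.centroids.tolist(),
            "class_labels": list(self.class_labels),
            "ridge": float(self.ridge),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MultiClassFisherModel":
        return cls(
            feature_columns=list(d["feature_columns"]),
            directions=np.asarray(d["directions"], float),
            centroids=np.asarray(d["centroids"], float),
            class_labels=list(d["class_labels"]),
            ridge=float(d["ridge"]),
        )


def fit_multiclass(
    table, labels, subset_columns=None, ridge: float | None = None
) -> MultiClassFisherModel:
    """Canonical Fisher discriminant over two or more classes.

    Directions are the leading generalized eigenvectors of
    ``S_b v = lambda (S_w + ridge I) v`` (at most C-1 of them).
    """
    y = np.asarray(labels)
    if subset_columns is None:
        subset_columns = list(table.columns)
    X = _as_matrix(table, subset_columns)
    classes = sorted(np.unique(y))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    mu = X.mean(axis=0)
    sw = _within_scatter(X, y, classes)
    sb = np.zeros_like(sw)
    for c in classes:
        nc = int((y == c).sum())
        d = X[y == c].mean(axis=0) - mu
        sb += nc * np.outer(d, d)
    if ridge is None:
        ridge = _default_ridge(sw, len(y))
    vals, vecs = linalg.eigh(sb, sw + ridge * np.eye(sw.shape[0]))
    order = np.argsort(vals)[::-1][: len(classes) - 1]
    directions = vecs[:, order]
    Z = X @ directions
    centroids = np.stack([Z[y == c].mean(axis=0) for c in classes])
    return MultiClassFisherModel(
        feature_columns=list(subset_columns),
        directions=directions,
        centroids=centroids,
        class_labels=classes,
        ridge=float(ridge),
    )


def save_model(model, path) -> None:
    kind = "two_class" if isinstance(model, FisherRule) else "multiclass"
    with open(path, "w") as fh:
        json.dump({"kind": kind, "model": model.to_dict()}, fh, indent=2)


def load_model(path):
    with open(path) as fh:
        d = json.load(fh)
    if d["kind"] == "two_class":
        return FisherRule.from_dict(d["model"])
    return MultiClassFisherModel.from_dict(d["model"])
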