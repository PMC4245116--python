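"""Support-vector feature selection (SVFS).

Features are ranked by backward elimination with a soft-margin linear SVM:
at each round the surviving features are standardized, an SVM is fitted,
each feature is scored by the perturbation of the margin objective caused
by removing it (for a linear kernel this is w_j^2), and the lowest-scoring
feature is eliminated.  Redundant survivors (|Pearson r| above ``r_max``)
are then collapsed onto the higher-ranked member, and the subset size is
chosen from a stratified k-fold cross-validation curve: the smallest size
whose accuracy is within ``tolerance`` of the best.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


class DegenerateLabels(ValueError):
    """Fewer than two samples in one of the classes."""


@dataclass
class SVFSConfig:
    C: float = 1.0
    k_folds: int = 5
    tolerance: float = 0.01
    r_max: float = 0.95
    seed: int = 0


@dataclass
class SelectionTrace:
    """Full record of one selection run.

    ``elimination_order`` lists features first-removed to last-removed, so
    reversing it gives the importance ranking.  ``cv_accuracy_by_size`` is
    indexed by subset size over the redundancy-filtered survivors.
    """

    elimination_order: list
    cv_accuracy_by_size: dict[int, float]
    chosen_subset: list
    rng_seed: int
    config: dict = field(default_factory=dict)

    def ranking(self) -> list:
        return list(reversed(self.elimination_order))

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["cv_accuracy_by_size"] = {
            str(k): v for k, v in self.cv_accuracy_by_size.items()
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _check_labels(y: np.ndarray) -> None:
    vals, counts = np.unique(y, return_counts=True)
    if len(vals) != 2:
        raise DegenerateLabels(f"need exactly 2 classes, got {list(vals)}")
    if counts.min() < 2:
        raise DegenerateLabels("each class needs at least 2 samples")


def _svm_weights(X: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    scaler = StandardScaler().fit(X)
    clf = SVC(kernel="linear", C=C).fit(scaler.transform(X), y)
    return np.asarray(clf.coef_).ravel()


def elimination_order(table: pd.DataFrame, labels, columns, C: float = 1.0) -> list:
    """Backward-elimination order over ``columns`` (first removed first).

    Constant features contribute nothing to the margin; they are assigned
    score zero and removed before any SVM is fitted, in column order.
    """
    y = np.asarray(labels)
    _check_labels(y)
    order: list = []
    constant = [c for c in columns if table[c].nunique() <= 1]
    order.extend(constant)
    surviving = [c for c in columns if c not in constant]
    while len(surviving) > 1:
        w = _svm_weights(table[surviving].to_numpy(float), y, C)
        scores = w**2
        drop = surviving[int(np.argmin(scores))]  # argmin is first-of-ties
        order.append(drop)
        surviving.remove(drop)
    order.extend(surviving)
    return order


def redundancy_filter(
    table: pd.DataFrame, candidate_subset, r_max: float = 0.95, rank=None
) -> list:
    """Drop the lower-ranked member of every highly correlated pair.

    ``rank`` orders candidates best-first (defaults to the given order).
    Candidates are scanned best-first; a candidate is kept only if its
    absolute Pearson correlation with every already-kept feature is at most
    ``r_max``.
    """
    cand = list(candidate_subset)
    if not cand:
        raise ValueError("candidate subset is empty")
    if rank is None:
        rank = cand
    ordered = [c for c in rank if c in cand]
    kept: list = []
    for c in ordered:
        x = table[c].to_numpy(float)
        ok = True
        for k in kept:
            z = table[k].to_numpy(float)
            if x.std() == 0 or z.std() == 0:
                r = 1.0 if x.std() == z.std() == 0 else 0.0
            else:
                r = np.corrcoef(x, z)[0, 1]
            if abs(r) > r_max:
                ok = False
                break
        if ok:
            kept.append(c)
    return kept


def rank_and_eliminate(
    table: pd.DataFrame,
    labels,
    columns=None,
    config: SVFSConfig | None = None,
) -> SelectionTrace:
    """Run the full SVFS procedure on a binary problem.

    Returns a :class:`SelectionTrace` whose ``chosen_subset`` is the
    smallest redundancy-filtered prefix of the importance ranking whose
    cross-validated accuracy is within ``config.tolerance`` of the best.
    """
    if config is None:
        config = SVFSConfig()
    if columns is None:
        columns = [c for c in table.columns if c.startswith("f")]
    y = np.asarray(labels)
    _check_labels(y)

    order = elimination_order(table, y, list(columns), C=config.C)
    rank = list(reversed(order))
    survivors = redundancy_filter(table, rank, r_max=config.r_max, rank=rank)

    _, counts = np.unique(y, return_counts=True)
    cv = StratifiedKFold(
        n_splits=min(config.k_folds, int(counts.min())),
        shuffle=True,
        random_state=config.seed,
    )
    accs: dict[int, float] = {}
    for m in range(1, len(survivors) + 1):
        cols = survivors[:m]
        pipe = make_pipeline(StandardScaler(), SVC(kernel="linear", C=config.C))
        scores = cross_val_score(pipe, table[cols].to_numpy(float), y, cv=cv)
        accs[m] = float(scores.mean())
    best = max(accs.values())
    size = min(m for m, a in accs.items() if a >= best - config.tolerance)

    return SelectionTrace(
        elimination_order=order,
        cv_accuracy_by_size=accs,
        chosen_subset=survivors[:size],
        rng_seed=config.seed,
        config=asdict(config),
    )
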