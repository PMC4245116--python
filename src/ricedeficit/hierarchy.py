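"""Three-level hierarchical identification of N/P/K deficiency.

Stage 1 separates Normal from deficient plants, stage 2 separates N
deficiency from the P/K pool, stage 3 separates P from K.  Each stage is a
two-class Fisher rule on its own characteristic subset; a sample follows
the cascade until a stage claims it (a deficient sample wrongly accepted
as Normal at stage 1 simply stays Normal — there is no recycling).

Subset presets
--------------
``table9``       the reference per-stage subsets (8, 5 and 7 characteristics),
``text_variant`` the same with the stage-3 leaf-spacing characteristic
                 (index 24, LS23) replaced by the 2nd-minus-3rd leaf-length
                 difference (index 18, L23) — both appear in the source
                 description of stage 3,
``universal``    the 10-characteristic all-stage subset used by the flat
                 (non-hierarchical) four-class baseline,
``auto``         run SVFS per stage on the training data.

Models are trained and evaluated per leaf position; the oldest (3rd) leaf
carries the strongest symptoms and is expected to win.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import registry
from .fisher import FisherRule, fit_two_class, fit_multiclass, MultiClassFisherModel
from .svfs import SVFSConfig, rank_and_eliminate

CLASSES = ("Normal", "Ndef", "Pdef", "Kdef")

PRESETS: dict[str, dict[int, tuple[int, ...]]] = {
    "table9": {
        1: (2, 6, 14, 26, 27, 29, 30, 31),
        2: (2, 3, 30, 31, 32),
        3: (2, 13, 14, 16, 24, 27, 30),
    },
    "text_variant": {
        1: (2, 6, 14, 26, 27, 29, 30, 31),
        2: (2, 3, 30, 31, 32),
        3: (2, 13, 14, 16, 18, 27, 30),
    },
}

#: all-stage universal characteristics for the flat 4-class baseline
UNIVERSAL_SUBSET: tuple[int, ...] = (2, 4, 6, 13, 14, 15, 18, 19, 20, 26)

_STAGE_PAIRS = {
    1: ("Normal", "Deficient"),
    2: ("Ndef", "PKdef"),
    3: ("Pdef", "Kdef"),
}


class MissingClass(ValueError):
    """A nutrition class required for training is absent."""


class SubsetNotInRegistry(KeyError):
    """A stage subset references an unknown characteristic index."""


def _stage_labels(stage: int, classes: pd.Series) -> pd.Series:
    if stage == 1:
        return classes.where(classes == "Normal", "Deficient")
    if stage == 2:
        return classes.where(classes == "Ndef", "PKdef")
    return classes


@dataclass
class HierarchicalModel:
    """Three fitted stage rules plus their subsets for one leaf position."""

    stage1: FisherRule
    stage2: FisherRule
    stage3: FisherRule
    stage_subsets: dict[int, tuple[int, ...]]
    leaf_position: int
    preset: str = "table9"
    selection_traces: dict = field(default_factory=dict)

    @property
    def rules(self) -> dict[int, FisherRule]:
        return {1: self.stage1, 2: self.stage2, 3: self.stage3}

    def to_dict(self) -> dict:
        return {
            "leaf_position": self.leaf_position,
            "preset": self.preset,
            "stage_subsets": {str(k): list(v) for k, v in self.stage_subsets.items()},
            "rules": {str(k): r.to_dict() for k, r in self.rules.items()},
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "HierarchicalModel":
        rules = {int(k): FisherRule.from_dict(v) for k, v in d["rules"].items()}
        return cls(
            stage1=rules[1], stage2=rules[2], stage3=rules[3],
            stage_subsets={int(k): tuple(v) for k, v in d["stage_subsets"].items()},
            leaf_position=int(d["leaf_position"]),
            preset=d.get("preset", "table9"),
        )

    @classmethod
    def load(cls, path) -> "HierarchicalModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _resolve_subsets(subsets, table, labels, svfs_config) -> tuple[dict, str, dict]:
    traces = {}
    if isinstance(subsets, str):
        if subsets == "auto":
            resolved = {}
            cfg = svfs_config or SVFSConfig()
            for stage in (1, 2, 3):
                sub = _stage_table(table, labels, stage)
                y = _stage_labels(stage, sub["class"])
                trace = rank_and_eliminate(sub, y, registry.COLUMNS, cfg)
                traces[stage] = trace
                resolved[stage] = tuple(
                    registry.INDEX_OF[c] for c in trace.chosen_subset
                )
            return resolved, "auto", traces
        if subsets not in PRESETS:
            raise KeyError(f"unknown subset preset {subsets!r}")
        return dict(PRESETS[subsets]), subsets, traces
    resolved = {int(k): tuple(int(i) for i in v) for k, v in subsets.items()}
    for v in resolved.values():
        try:
            registry.validate_indices(v)
        except KeyError as exc:
            raise SubsetNotInRegistry(str(exc)) from exc
    return resolved, "custom", traces


def _stage_table(table: pd.DataFrame, labels: pd.Series, stage: int) -> pd.DataFrame:
    t = table.copy()
    t["class"] = np.asarray(labels)
    if stage == 1:
        return t
    if stage == 2:
        return t[t["class"].isin(["Ndef", "Pdef", "Kdef"])]
    return t[t["class"].isin(["Pdef", "Kdef"])]


def train_cascade(
    table: pd.DataFrame,
    labels=None,
    subsets="table9",
    position: int | None = None,
    svfs_config: SVFSConfig | None = None,
    ridge: float | None = None,
    prior_shift: bool = False,
) -> HierarchicalModel:
    """Fit the three stage rules on one leaf position.

    ``table`` is a feature table (``extract_table`` output).  ``labels``
    defaults to its ``class`` column; ``position`` filters the table's
    ``pos`` column when present.  ``subsets`` is a preset name, ``"auto"``
    (per-stage SVFS), or an explicit ``{stage: indices}`` mapping.
    """
    t = table.copy()
    if labels is not None:
        t["class"] = np.asarray(labels)
    if position is not None and "pos" in t.columns:
        t = t[t["pos"] == position].reset_index(drop=True)
    if "class" not in t.columns:
        raise ValueError("no class labels provided")
    present = set(t["class"].unique())
    missing = [c for c in CLASSES if c not in present]
    if missing:
        raise MissingClass(f"absent classes: {missing}")

    resolved, preset, traces = _resolve_subsets(subsets, t, t["class"], svfs_config)
    rules = {}
    for stage in (1, 2, 3):
        sub = _stage_table(t, t["class"], stage)
        y = _stage_labels(stage, sub["class"])
        cols = registry.columns_for(resolved[stage])
        rules[stage] = fit_two_class(
            sub, y, cols, class_pair=_STAGE_PAIRS[stage],
            ridge=ridge, prior_shift=prior_shift,
        )
    return HierarchicalModel(
        stage1=rules[1], stage2=rules[2], stage3=rules[3],
        stage_subsets=resolved,
        leaf_position=position if position is not None else 0,
        preset=preset,
        selection_traces=traces,
    )


def predict_cascade(
    model: HierarchicalModel, table, return_trace: bool = False
):
    """Predict one of {Normal, Ndef, Pdef, Kdef} for every row.

    With ``return_trace`` also returns the last stage each sample visited
    (1, 2 or 3) — a sample accepted at a stage never reaches later stages.
    """
    if isinstance(table, pd.Series):
        table = table.to_frame().T
    n = len(table)
    pred = np.empty(n, dtype=object)
    stage_seen = np.ones(n, dtype=int)

    p1 = model.stage1.classify(table)
    normal = p1 == "Normal"
    pred[normal] = "Normal"

    rest = ~normal
    if rest.any():
        stage_seen[rest] = 2
        t2 = table[rest]
        p2 = model.stage2.classify(t2)
        idx2 = np.nonzero(rest)[0]
        pred[idx2[p2 == "Ndef"]] = "Ndef"
        deeper = idx2[p2 == "PKdef"]
        if len(deeper):
            stage_seen[deeper] = 3
            p3 = model.stage3.classify(table.iloc[deeper])
            pred[deeper] = p3
    if return_trace:
        return pred, stage_seen
    return pred


@dataclass
class EvaluationReport:
    """Accuracy summary of one model on one labelled table."""

    overall_accuracy: float
    per_class_accuracy: dict[str, float]
    confusion: pd.DataFrame  # rows: true class, columns: predicted
    stage_accuracies: dict[int, float]
    leaf_position: int
    n_per_class: dict[str, int]

    def to_text(self) -> str:
        lines = [
            f"leaf position: {self.leaf_position}",
            f"overall accuracy: {100 * self.overall_accuracy:.2f}%",
            "per-class accuracy: "
            + ", ".join(f"{k} {100 * v:.2f}%" for k, v in
                        self.per_class_accuracy.items()),
            "stage accuracies: "
            + ", ".join(f"stage{k} {100 * v:.2f}%" for k, v in
                        self.stage_accuracies.items()),
            "confusion matrix (rows = true, columns = predicted):",
            self.confusion.to_string(),
        ]
        return "\n".join(lines)


def evaluate(model: HierarchicalModel, table: pd.DataFrame, labels=None
             ) -> EvaluationReport:
    """Confusion matrix, per-class/stage and overall accuracy of a cascade."""
    t = table.copy()
    if labels is not None:
        t["class"] = np.asarray(labels)
    y = t["class"].to_numpy()
    pred = predict_cascade(model, t)

    conf = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES), dtype=int)
    for yt, yp in zip(y, pred):
        conf.loc[yt, yp] += 1
    n_per_class = {c: int((y == c).sum()) for c in CLASSES}
    per_class = {
        c: conf.loc[c, c] / n_per_class[c] if n_per_class[c] else np.nan
        for c in CLASSES
    }
    overall = float(np.trace(conf.to_numpy())) / len(y)

    stage_acc = {}
    y1 = np.where(y == "Normal", "Normal", "Deficient")
    stage_acc[1] = float((model.stage1.classify(t) == y1).mean())
    d2 = t[t["class"].isin(["Ndef", "Pdef", "Kdef"])]
    if len(d2):
        y2 = np.where(d2["class"] == "Ndef", "Ndef", "PKdef")
        stage_acc[2] = float((model.stage2.classify(d2) == y2).mean())
    d3 = t[t["class"].isin(["Pdef", "Kdef"])]
    if len(d3):
        stage_acc[3] = float(
            (model.stage3.classify(d3) == d3["class"].to_numpy()).mean()
        )
    return EvaluationReport(
        overall_accuracy=overall,
        per_class_accuracy=per_class,
        confusion=conf,
        stage_accuracies=stage_acc,
        leaf_position=model.leaf_position,
        n_per_class=n_per_class,
    )


def best_position(reports) -> int:
    """Leaf position with the highest overall accuracy; ties go to the
    larger index (the older leaf, which physiologically shows symptoms
    first)."""
    reports = list(reports)
    if not reports:
        raise ValueError("no reports")
    best = max(reports, key=lambda r: (r.overall_accuracy, r.leaf_position))
    return best.leaf_position


def fit_flat_baseline(
    table: pd.DataFrame,
    labels=None,
    subset=UNIVERSAL_SUBSET,
    position: int | None = None,
) -> MultiClassFisherModel:
    """Non-hierarchical four-class Fisher baseline on the universal subset."""
    t = table.copy()
    if labels is not None:
        t["class"] = np.asarray(labels)
    if position is not None and "pos" in t.columns:
        t = t[t["pos"] == position].reset_index(drop=True)
    registry.validate_indices(subset)
    return fit_multiclass(t, t["class"], registry.columns_for(subset))
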