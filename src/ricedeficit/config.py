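"""YAML configuration loading for the command-line pipeline.

The config file mirrors the module boundaries::

    segment:
      threshold: 235
      method: minwhite
    features:
      lightness_mode: mean
      tau_white: 200
      tau_spread: 30
    svfs:
      C: 1.0
      k_folds: 5
      tolerance: 0.01
      r_max: 0.95
      seed: 0
    subsets:
      preset: table9        # or text_variant / auto / explicit stage lists
      stage1: [2, 6, 14, 26, 27, 29, 30, 31]

Every key is optional; omitted values fall back to module defaults.
"""

from __future__ import annotations

import yaml

from .features import ExtractionConfig
from .svfs import SVFSConfig


def load_config(path=None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def extraction_config(cfg: dict) -> ExtractionConfig:
    seg = cfg.get("segment", {})
    feat = cfg.get("features", {})
    return ExtractionConfig(
        segment_threshold=seg.get("threshold", 235),
        segment_method=seg.get("method", "minwhite"),
        lightness_mode=feat.get("lightness_mode", "mean"),
        tip_window=feat.get("tip_window", 0.2),
        tau_white=feat.get("tau_white", 200),
        tau_spread=feat.get("tau_spread", 30),
    )


def svfs_config(cfg: dict) -> SVFSConfig:
    s = cfg.get("svfs", {})
    return SVFSConfig(
        C=s.get("C", 1.0),
        k_folds=s.get("k_folds", 5),
        tolerance=s.get("tolerance", 0.01),
        r_max=s.get("r_max", 0.95),
        seed=s.get("seed", 0),
    )


def subsets_spec(cfg: dict):
    sub = cfg.get("subsets", {})
    if not sub:
        return "table9"
    if "preset" in sub and not any(k.startswith("stage") for k in sub):
        return sub["preset"]
    explicit = {
        int(k.removeprefix("stage")): tuple(v)
        for k, v in sub.items()
        if k.startswith("stage")
    }
    return explicit or sub.get("preset", "table9")
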