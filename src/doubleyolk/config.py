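"""Loading classifier configurations from YAML/JSON, plus shipped presets.

A configuration file has two anchor blocks and optional overrides::

    gi: {low: 1.30, medium: 1.40, high: 1.50}
    wi: {low: 65.0, medium: 75.0, high: 85.0}
    decision_threshold: 0.5      # optional
    rules:                       # optional 3x3 grid of 0/1, GI rows x WI cols
      - [0, 0, 1]
      - [0, 0, 1]
      - [0, 1, 1]

JSON files use the same schema (YAML is a superset, so one loader serves
both).  Two presets ship with the package:

* ``case3`` — GI (1.30, 1.40, 1.50), WI (65, 75, 85): the production
  configuration, chosen for its low single-yolk error.
* ``worked_example`` — GI (1.30, 1.40, 1.50), WI (66, 74, 82): the
  membership sets under which the documented worked example (ratio 1.45,
  weight 72 g -> truth 0.449) evaluates exactly.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .engine import DoubleYolkClassifier, RuleBase
from .membership import InputMFSet

__all__ = ["PRESETS", "preset_path", "load_classifier", "classifier_from_anchors"]

PRESETS = ("case3", "worked_example")


def preset_path(name: str) -> Path:
    """Filesystem path of a shipped preset configuration."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESETS)}")
    return Path(str(resources.files("doubleyolk.data").joinpath(f"{name}.yaml")))


def classifier_from_anchors(gi_anchors, wi_anchors, rules: RuleBase | None = None,
                            threshold: float = 0.5) -> DoubleYolkClassifier:
    """Build a classifier directly from two (low, med, high) anchor triples."""
    gi = InputMFSet("GI", *map(float, gi_anchors), units="")
    wi = InputMFSet("WI", *map(float, wi_anchors), units="g")
    return DoubleYolkClassifier(gi, wi, rules or RuleBase(), threshold)


def _anchor_triple(block, key: str) -> tuple[float, float, float]:
    try:
        return (float(block["low"]), float(block["medium"]), float(block["high"]))
    except (KeyError, TypeError) as exc:
        raise ValueError(f"config block {key!r} needs low/medium/high values") from exc


def load_classifier(source) -> DoubleYolkClassifier:
    """Load a classifier from a preset name or a YAML/JSON file path."""
    if isinstance(source, str) and source in PRESETS:
        source = preset_path(source)
    raw = yaml.safe_load(Path(source).read_text())
    if not isinstance(raw, dict) or "gi" not in raw or "wi" not in raw:
        raise ValueError(f"{source}: config must define 'gi' and 'wi' anchor blocks")
    rules = RuleBase(tuple(map(tuple, raw["rules"]))) if "rules" in raw else RuleBase()
    return classifier_from_anchors(
        _anchor_triple(raw["gi"], "gi"),
        _anchor_triple(raw["wi"], "wi"),
        rules=rules,
        threshold=float(raw.get("decision_threshold", 0.5)),
    )
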