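"""Error accounting for yolk classifiers and membership-anchor sweeps.

Two error types matter commercially, and both are expressed as
percentages of *all* eggs graded (not per-class recall):

* **single-yolk error** — a cracked-and-checked SY egg that the
  algorithm called DY (the customer who paid a premium is disappointed);
* **double-yolk error** — a true DY egg called SY (lost revenue).

The total error is their sum, i.e. the overall misclassification rate.
A good configuration minimises the single-yolk error first — buyers of
double-yolk eggs should receive 100% double yolks — and the total error
second.

:func:`sweep_mf_configs` re-runs the fuzzy classifier over a list of
(GI, WI) anchor-triple configurations and reports the three errors per
configuration; a 20-case sweep fixture ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .config import classifier_from_anchors
from .engine import RuleBase
from .records import DY, SY, EggRecord

__all__ = ["ErrorReport", "MFConfigResult", "compute_errors", "sweep_mf_configs",
           "load_sweep_configs", "default_sweep_configs", "sweep_to_dataframe"]


@dataclass(frozen=True)
class ErrorReport:
    """Misclassification counts and their percentages of all eggs."""

    n_total: int
    n_sy_error: int  # true SY predicted DY
    n_dy_error: int  # true DY predicted SY

    @property
    def sy_error_pct(self) -> float:
        return 100.0 * self.n_sy_error / self.n_total

    @property
    def dy_error_pct(self) -> float:
        return 100.0 * self.n_dy_error / self.n_total

    @property
    def total_error_pct(self) -> float:
        return self.sy_error_pct + self.dy_error_pct

    def __str__(self) -> str:
        return (
            f"n={self.n_total}  SY-error {self.sy_error_pct:.2f}%  "
            f"DY-error {self.dy_error_pct:.2f}%  total {self.total_error_pct:.2f}%"
        )


@dataclass(frozen=True)
class MFConfigResult:
    """One swept anchor configuration and its error report."""

    gi_anchors: tuple[float, float, float]
    wi_anchors: tuple[float, float, float]
    report: ErrorReport | None
    error: str | None = None  # set when the configuration itself was invalid

    @property
    def ok(self) -> bool:
        return self.report is not None


def compute_errors(truths: Sequence[str], predictions: Sequence[str]) -> ErrorReport:
    """Count both error types for predicted vs true SY/DY labels."""
    if len(truths) == 0:
        raise ValueError("cannot evaluate an empty label list")
    if len(truths) != len(predictions):
        raise ValueError(f"length mismatch: {len(truths)} truths vs {len(predictions)} predictions")
    n_sy_err = n_dy_err = 0
    for t, p in zip(truths, predictions):
        if t not in (SY, DY) or p not in (SY, DY):
            raise ValueError(f"labels must be 'SY' or 'DY', got ({t!r}, {p!r})")
        if t == SY and p == DY:
            n_sy_err += 1
        elif t == DY and p == SY:
            n_dy_err += 1
    return ErrorReport(n_total=len(truths), n_sy_error=n_sy_err, n_dy_error=n_dy_err)


def sweep_mf_configs(eggs: Sequence[EggRecord],
                     configs: Sequence[tuple[Sequence[float], Sequence[float]]],
                     rules: RuleBase | None = None,
                     threshold: float = 0.5) -> list[MFConfigResult]:
    """Evaluate the fuzzy classifier under each (GI, WI) anchor pair.

    Every egg must carry a ground-truth label.  An invalid anchor triple
    (not strictly increasing) is flagged and skipped; the sweep continues.
    """
    truths = [e.label for e in eggs]
    if any(t is None for t in truths):
        raise ValueError("all eggs must be labeled for a sweep")
    out: list[MFConfigResult] = []
    for gi_anchors, wi_anchors in configs:
        gi_t = tuple(float(v) for v in gi_anchors)
        wi_t = tuple(float(v) for v in wi_anchors)
        try:
            clf = classifier_from_anchors(gi_t, wi_t, rules=rules, threshold=threshold)
        except ValueError as exc:
            out.append(MFConfigResult(gi_t, wi_t, report=None, error=str(exc)))
            continue
        report = compute_errors(truths, clf.predict(eggs))
        out.append(MFConfigResult(gi_t, wi_t, report=report))
    return out


def load_sweep_configs(path) -> list[tuple[tuple[float, ...], tuple[float, ...]]]:
    """Read anchor configurations from CSV or YAML.

    CSV needs columns ``gi_low, gi_medium, gi_high, wi_low, wi_medium,
    wi_high``; YAML is a list of ``{gi: [l,m,h], wi: [l,m,h]}`` entries.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml", ".json"):
        raw = yaml.safe_load(path.read_text())
        return [(tuple(map(float, item["gi"])), tuple(map(float, item["wi"]))) for item in raw]
    df = pd.read_csv(path)
    cols = ["gi_low", "gi_medium", "gi_high", "wi_low", "wi_medium", "wi_high"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing sweep columns {missing}")
    return [
        ((row.gi_low, row.gi_medium, row.gi_high), (row.wi_low, row.wi_medium, row.wi_high))
        for row in df[cols].astype(float).itertuples()
    ]


def default_sweep_configs() -> list[tuple[tuple[float, ...], tuple[float, ...]]]:
    """The 20 packaged anchor configurations used for shape studies."""
    return load_sweep_configs(str(resources.files("doubleyolk.data").joinpath("mf_sweep_cases.csv")))


def sweep_to_dataframe(results: Sequence[MFConfigResult]) -> pd.DataFrame:
    """Tabulate sweep results with one row per configuration."""
    rows = []
    for i, r in enumerate(results, start=1):
        row = {
            "case": i,
            "gi_low": r.gi_anchors[0], "gi_medium": r.gi_anchors[1], "gi_high": r.gi_anchors[2],
            "wi_low": r.wi_anchors[0], "wi_medium": r.wi_anchors[1], "wi_high": r.wi_anchors[2],
        }
        if r.ok:
            row.update(
                sy_error_pct=round(r.report.sy_error_pct, 2),
                dy_error_pct=round(r.report.dy_error_pct, 2),
                total_error_pct=round(r.report.total_error_pct, 2),
                status="ok",
            )
        else:
            row.update(sy_error_pct=None, dy_error_pct=None, total_error_pct=None,
                       status=f"skipped: {r.error}")
        rows.append(row)
    return pd.DataFrame(rows)
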