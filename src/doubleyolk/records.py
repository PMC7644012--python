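"""The egg measurement record and its canonical CSV representation.

One egg is described by two indicators: its weight in grams (WI) and the
dimensionless ratio of its major- to minor-axis length (GI).  The raw axis
lengths are optional — when present the ratio must equal their quotient.
An optional ground-truth label marks the egg as single-yolk (``"SY"``) or
double-yolk (``"DY"``).

The canonical CSV layout has columns ``weight_g, major, minor, ratio,
label`` (comma-separated, header row, '.' decimal separator); ``major``,
``minor`` and ``label`` may be empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["SY", "DY", "EggRecord", "eggs_to_dataframe", "dataframe_to_eggs",
           "write_egg_csv", "read_egg_csv"]

SY = "SY"
DY = "DY"

_CSV_COLUMNS = ["weight_g", "major", "minor", "ratio", "label"]


@dataclass(frozen=True)
class EggRecord:
    """One egg: weight (g), shape ratio, optional axes and true label.

    ``ratio`` is the geometric indicator, major/minor axis length, so it
    is dimensionless and at least 1.  Axis lengths may be in any single
    consistent unit (mm for caliper data, pixels for image data) — the
    ratio cancels it.
    """

    weight: float
    ratio: float
    major: float | None = None
    minor: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.weight) and self.weight > 0):
            raise ValueError(f"weight must be a positive finite number of grams, got {self.weight!r}")
        if not (math.isfinite(self.ratio) and self.ratio >= 1.0):
            raise ValueError(f"axis ratio must be finite and >= 1, got {self.ratio!r}")
        if (self.major is None) != (self.minor is None):
            raise ValueError("major and minor axis lengths must be given together")
        if self.major is not None and self.minor is not None:
            if self.major < self.minor or self.minor <= 0:
                raise ValueError("axes must satisfy major >= minor > 0")
            if abs(self.ratio - self.major / self.minor) > 1e-9:
                raise ValueError(
                    f"ratio {self.ratio} inconsistent with major/minor = {self.major / self.minor}"
                )
        if self.label is not None and self.label not in (SY, DY):
            raise ValueError(f"label must be 'SY', 'DY' or None, got {self.label!r}")

    @classmethod
    def from_axes(cls, weight: float, major: float, minor: float,
                  label: str | None = None) -> "EggRecord":
        """Build a record from raw axis lengths, deriving the ratio."""
        if minor <= 0:
            raise ValueError("minor axis must be positive")
        return cls(weight=weight, ratio=major / minor, major=major, minor=minor, label=label)


def eggs_to_dataframe(eggs: Iterable[EggRecord]) -> pd.DataFrame:
    """Tabulate records into the canonical column layout."""
    rows = [
        {
            "weight_g": e.weight,
            "major": e.major,
            "minor": e.minor,
            "ratio": e.ratio,
            "label": e.label,
        }
        for e in eggs
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def dataframe_to_eggs(df: pd.DataFrame) -> list[EggRecord]:
    """Parse a canonical-layout table back into records.

    ``weight_g`` and either ``ratio`` or both axis columns are required
    per row; a missing ``label`` column (or empty cells) yields unlabeled
    records.
    """
    if "weight_g" not in df.columns:
        raise ValueError("missing required column 'weight_g'")
    has_ratio = "ratio" in df.columns
    has_axes = "major" in df.columns and "minor" in df.columns
    if not (has_ratio or has_axes):
        raise ValueError("need a 'ratio' column or both 'major' and 'minor'")
    eggs: list[EggRecord] = []
    for _, row in df.iterrows():
        label = row.get("label")
        if pd.isna(label) or label == "":
            label = None
        major = row.get("major") if has_axes else None
        minor = row.get("minor") if has_axes else None
        if major is not None and (pd.isna(major) or pd.isna(minor)):
            major = minor = None
        if has_ratio and not pd.isna(row["ratio"]):
            ratio = float(row["ratio"])
        else:
            ratio = float(major) / float(minor)  # type: ignore[arg-type]
        eggs.append(
            EggRecord(
                weight=float(row["weight_g"]),
                ratio=ratio,
                major=None if major is None else float(major),
                minor=None if minor is None else float(minor),
                label=label,
            )
        )
    return eggs


def write_egg_csv(eggs: Sequence[EggRecord], path) -> None:
    eggs_to_dataframe(eggs).to_csv(path, index=False, float_format="%.10g")


def read_egg_csv(path) -> list[EggRecord]:
    return dataframe_to_eggs(pd.read_csv(path))
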