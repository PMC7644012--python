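"""Triangular membership functions and fuzzification of egg indicators.

A crisp indicator value — the geometric indicator GI (major/minor axis
ratio, dimensionless) or the weight indicator WI (grams) — is mapped to
degrees of membership in three linguistic fuzzy sets *low*, *medium* and
*high*.  Each set is a piecewise-linear (triangular) membership function:

* ``low``    — a lower shoulder: degree 1 up to its breakpoint, then a
  linear ramp down to 0;
* ``medium`` — a full triangle peaking at 1;
* ``high``   — an upper shoulder: a linear ramp up, then degree 1 from
  its breakpoint onward.

The three functions for one indicator are generated from a single strictly
increasing anchor triple ``(anchor_low, anchor_med, anchor_high)``:
low = shoulder falling from ``anchor_low`` to ``anchor_med``, medium =
triangle over ``(anchor_low, anchor_med, anchor_high)``, high = shoulder
rising from ``anchor_med`` to ``anchor_high``.  Adjacent sets overlap, so
at most two of the three degrees are nonzero at any input.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import NamedTuple

__all__ = ["MFShape", "TriangularMF", "FuzzyDegrees", "InputMFSet"]


class MFShape(enum.Enum):
    """Shape of a triangular membership function."""

    FULL = "full"
    LOWER_SHOULDER = "lower_shoulder"
    UPPER_SHOULDER = "upper_shoulder"


class FuzzyDegrees(NamedTuple):
    """Membership degrees of one crisp input in the low/medium/high sets."""

    low: float
    medium: float
    high: float


@dataclass(frozen=True)
class TriangularMF:
    """One triangular fuzzy set: a full triangle or a shoulder half-triangle.

    Parameters
    ----------
    shape
        ``FULL`` uses all three breakpoints ``a < b < c`` with peak 1 at
        ``b``.  ``LOWER_SHOULDER`` saturates at 1 for ``x <= b`` and falls
        linearly to 0 at ``c`` (``a`` is ignored).  ``UPPER_SHOULDER`` is 0
        for ``x <= a``, rises linearly and saturates at 1 for ``x >= b``
        (``c`` is ignored).
    a, b, c
        Breakpoints on the input axis.

    Notes
    -----
    The printed piecewise definition of the full triangle assigns 1 only at
    ``x = b``; the two linear ramps already attain 1 there, so the
    continuous piecewise-linear form implemented here is value-identical
    and needs no special case.
    """

    shape: MFShape
    a: float = math.nan
    b: float = math.nan
    c: float = math.nan

    def __post_init__(self) -> None:
        if not isinstance(self.shape, MFShape):
            object.__setattr__(self, "shape", MFShape(self.shape))
        if not math.isfinite(self.b):
            raise ValueError("breakpoint b must be finite")
        if self.shape is MFShape.FULL:
            if not (math.isfinite(self.a) and math.isfinite(self.c)):
                raise ValueError("full triangle needs finite a and c")
            if not (self.a < self.b < self.c):
                raise ValueError(
                    f"full triangle requires a < b < c, got {self.a}, {self.b}, {self.c}"
                )
        elif self.shape is MFShape.LOWER_SHOULDER:
            if not math.isfinite(self.c):
                raise ValueError("lower shoulder needs finite c")
            if not self.b < self.c:
                raise ValueError(f"lower shoulder requires b < c, got {self.b}, {self.c}")
        else:  # UPPER_SHOULDER
            if not math.isfinite(self.a):
                raise ValueError("upper shoulder needs finite a")
            if not self.a < self.b:
                raise ValueError(f"upper shoulder requires a < b, got {self.a}, {self.b}")

    @classmethod
    def full(cls, a: float, b: float, c: float) -> "TriangularMF":
        return cls(MFShape.FULL, a, b, c)

    @classmethod
    def lower_shoulder(cls, b: float, c: float) -> "TriangularMF":
        return cls(MFShape.LOWER_SHOULDER, b=b, c=c)

    @classmethod
    def upper_shoulder(cls, a: float, b: float) -> "TriangularMF":
        return cls(MFShape.UPPER_SHOULDER, a=a, b=b)

    def __call__(self, x: float) -> float:
        """Evaluate the membership degree at ``x`` (always in [0, 1])."""
        x = float(x)
        if not math.isfinite(x):
            raise ValueError(f"input must be finite, got {x!r}")
        if self.shape is MFShape.FULL:
            if x <= self.a or x >= self.c:
                return 0.0
            if x <= self.b:
                return (x - self.a) / (self.b - self.a)
            return (self.c - x) / (self.c - self.b)
        if self.shape is MFShape.LOWER_SHOULDER:
            if x <= self.b:
                return 1.0
            if x >= self.c:
                return 0.0
            return (self.c - x) / (self.c - self.b)
        # UPPER_SHOULDER
        if x <= self.a:
            return 0.0
        if x >= self.b:
            return 1.0
        return (x - self.a) / (self.b - self.a)


def evaluate_mf(mf: TriangularMF, x: float) -> float:
    """Functional alias for ``mf(x)``."""
    return mf(x)


@dataclass(frozen=True)
class InputMFSet:
    """The low/medium/high fuzzy partition of one indicator.

    Parameters
    ----------
    name
        Indicator name, conventionally ``"GI"`` (shape ratio) or
        ``"WI"`` (weight).
    anchor_low, anchor_med, anchor_high
        Strictly increasing anchors that generate the three sets.
    units
        Display units: ``"g"`` for weight, ``""`` for the dimensionless
        ratio.
    """

    name: str
    anchor_low: float
    anchor_med: float
    anchor_high: float
    units: str = ""

    def __post_init__(self) -> None:
        for v in (self.anchor_low, self.anchor_med, self.anchor_high):
            if not math.isfinite(v):
                raise ValueError("anchors must be finite")
        if not (self.anchor_low < self.anchor_med < self.anchor_high):
            raise ValueError(
                "anchors must be strictly increasing, got "
                f"({self.anchor_low}, {self.anchor_med}, {self.anchor_high})"
            )

    @property
    def anchors(self) -> tuple[float, float, float]:
        return (self.anchor_low, self.anchor_med, self.anchor_high)

    @property
    def low(self) -> TriangularMF:
        return TriangularMF.lower_shoulder(self.anchor_low, self.anchor_med)

    @property
    def medium(self) -> TriangularMF:
        return TriangularMF.full(self.anchor_low, self.anchor_med, self.anchor_high)

    @property
    def high(self) -> TriangularMF:
        return TriangularMF.upper_shoulder(self.anchor_med, self.anchor_high)

    def fuzzify(self, x: float) -> FuzzyDegrees:
        """Degrees of ``x`` in the low, medium and high sets.

        Inputs below ``anchor_low`` give (1, 0, 0); above ``anchor_high``,
        (0, 0, 1) — the shoulders cover the whole real line.
        """
        return FuzzyDegrees(self.low(x), self.medium(x), self.high(x))


def fuzzify(mfset: InputMFSet, x: float) -> FuzzyDegrees:
    """Functional alias for ``mfset.fuzzify(x)``."""
    return mfset.fuzzify(x)
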