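"""Mamdani-style fuzzy inference for single- vs double-yolk classification.

The pipeline, applied to one egg:

1. **Fuzzify** the shape ratio (GI) and weight (WI) into low/medium/high
   degrees (:mod:`doubleyolk.membership`).
2. **Fire** the nine rules — one per (GI category, WI category) pair —
   with the *min* operator: a rule's strength is the minimum of its two
   antecedent degrees.
3. **Aggregate** per output class by root-sum-square: the single-yolk
   mass is sqrt of the sum of squared strengths over the rules that
   conclude SY, likewise for DY.
4. **Defuzzify** by the centroid of the two output classes, treated as
   singletons at centers 0 (single) and 1 (double):
   ``truth = (m_SY*0 + m_DY*1) / (m_SY + m_DY)``.

The truth value lies in [0, 1]; an egg is called double-yolk when it
reaches the decision threshold (default 0.5, with the tie assigned to
DY so that class is closed).

The default rule grid, rows = GI (low, med, high) x cols = WI (low, med,
high), is ``[[0,0,1],[0,0,1],[0,1,1]]`` — heavy eggs are double-yolk at
any shape, and elongated eggs need only medium weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .membership import FuzzyDegrees, InputMFSet
from .records import DY, SY, EggRecord

__all__ = [
    "RuleBase",
    "ClassificationResult",
    "fire_rules",
    "aggregate_rss",
    "defuzzify_centroid",
    "classify_egg",
    "DoubleYolkClassifier",
]

_DEFAULT_GRID = ((0, 0, 1), (0, 0, 1), (0, 1, 1))


@dataclass(frozen=True)
class RuleBase:
    """The 3x3 rule grid and the two output-class centers.

    ``outcome[i][j]`` is the conclusion (0 = SY, 1 = DY) of the rule whose
    antecedent pairs GI category ``i`` with WI category ``j`` (categories
    ordered low, medium, high).  Flattened row-major this is the
    conventional rule order R1..R9.  Output membership is singleton at
    ``center_single`` and ``center_double``; the defaults 0 and 1 make the
    truth value directly readable as a double-yolk propensity.
    """

    outcome: tuple[tuple[int, int, int], ...] = _DEFAULT_GRID
    center_single: float = 0.0
    center_double: float = 1.0

    def __post_init__(self) -> None:
        grid = tuple(tuple(int(v) for v in row) for row in self.outcome)
        if len(grid) != 3 or any(len(row) != 3 for row in grid):
            raise ValueError("rule grid must be 3x3")
        if any(v not in (0, 1) for row in grid for v in row):
            raise ValueError("rule outcomes must be 0 (SY) or 1 (DY)")
        object.__setattr__(self, "outcome", grid)

    @property
    def flat(self) -> np.ndarray:
        """Outcomes in rule order R1..R9 (GI-major)."""
        return np.asarray(self.outcome, dtype=int).ravel()

    def inverted(self) -> "RuleBase":
        """Rule base with every conclusion flipped (used in symmetry checks)."""
        flipped = tuple(tuple(1 - v for v in row) for row in self.outcome)
        return RuleBase(flipped, self.center_single, self.center_double)


@dataclass(frozen=True)
class ClassificationResult:
    """Full audit trail of one egg's classification.

    ``rule_strengths`` holds the nine firing strengths in rule order
    R1..R9; ``mass_single``/``mass_double`` are the root-sum-square
    aggregates; ``truth_value`` is the defuzzified output in [0, 1] and
    ``label`` the thresholded call.  ``degenerate`` flags the (only
    theoretically possible) case of no rule firing, reported as truth 0.
    """

    gi_degrees: FuzzyDegrees
    wi_degrees: FuzzyDegrees
    rule_strengths: tuple[float, ...]
    mass_single: float
    mass_double: float
    truth_value: float
    label: str
    threshold: float = 0.5
    degenerate: bool = False


def fire_rules(gi_degrees: FuzzyDegrees, wi_degrees: FuzzyDegrees) -> np.ndarray:
    """Strengths of the nine rules under the min operator, order R1..R9."""
    gi = np.asarray(gi_degrees, dtype=float)
    wi = np.asarray(wi_degrees, dtype=float)
    if gi.shape != (3,) or wi.shape != (3,):
        raise ValueError("each input needs exactly three degrees")
    if ((gi < 0) | (gi > 1) | (wi < 0) | (wi > 1)).any():
        raise ValueError("membership degrees must lie in [0, 1]")
    return np.minimum.outer(gi, wi).ravel()


def aggregate_rss(rule_strengths, rules: RuleBase = RuleBase()) -> tuple[float, float]:
    """Root-sum-square masses (single, double) of the fired rules."""
    s = np.asarray(rule_strengths, dtype=float)
    if s.shape != (9,):
        raise ValueError("expected nine rule strengths")
    out = rules.flat
    mass_single = float(np.sqrt(np.sum(s[out == 0] ** 2)))
    mass_double = float(np.sqrt(np.sum(s[out == 1] ** 2)))
    return mass_single, mass_double


def defuzzify_centroid(mass_single: float, mass_double: float,
                       rules: RuleBase = RuleBase()) -> tuple[float, bool]:
    """Centroid (center-of-gravity) truth value, with a degeneracy flag.

    Returns ``(truth_value, degenerate)``.  With the default centers 0/1
    the truth value is ``mass_double / (mass_single + mass_double)``.  If
    both masses are zero no rule fired and the egg defaults to truth 0
    (single-yolk) with ``degenerate=True`` rather than raising — this is
    unreachable with shoulder membership sets, which cover the whole axis,
    but can occur with user-supplied rule grids.
    """
    if mass_single < 0 or mass_double < 0:
        raise ValueError("aggregated masses must be nonnegative")
    total = mass_single + mass_double
    if total == 0:
        return 0.0, True
    value = (mass_single * rules.center_single + mass_double * rules.center_double) / total
    return value, False


def classify_egg(egg: EggRecord, gi_set: InputMFSet, wi_set: InputMFSet,
                 rules: RuleBase = RuleBase(), threshold: float = 0.5) -> ClassificationResult:
    """Run the full fuzzify -> fire -> aggregate -> defuzzify pipeline.

    The label is DY iff ``truth_value >= threshold`` (ties to DY, so the
    double-yolk class is the closed set).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    gi_deg = gi_set.fuzzify(egg.ratio)
    wi_deg = wi_set.fuzzify(egg.weight)
    strengths = fire_rules(gi_deg, wi_deg)
    m_s, m_d = aggregate_rss(strengths, rules)
    truth, degenerate = defuzzify_centroid(m_s, m_d, rules)
    label = DY if truth >= threshold else SY
    return ClassificationResult(
        gi_degrees=gi_deg,
        wi_degrees=wi_deg,
        rule_strengths=tuple(float(v) for v in strengths),
        mass_single=m_s,
        mass_double=m_d,
        truth_value=truth,
        label=label,
        threshold=threshold,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class DoubleYolkClassifier:
    """A configured classifier: membership sets, rule grid and threshold.

    Convenience wrapper so callers configure once and classify many eggs;
    build from a preset or config file with
    :func:`doubleyolk.config.load_classifier`.
    """

    gi_set: InputMFSet
    wi_set: InputMFSet
    rules: RuleBase = field(default_factory=RuleBase)
    threshold: float = 0.5

    def classify(self, egg: EggRecord) -> ClassificationResult:
        return classify_egg(egg, self.gi_set, self.wi_set, self.rules, self.threshold)

    def classify_value(self, weight: float, ratio: float) -> ClassificationResult:
        return self.classify(EggRecord(weight=weight, ratio=ratio))

    def truth_value(self, weight: float, ratio: float) -> float:
        return self.classify_value(weight, ratio).truth_value

    def predict(self, eggs) -> list[str]:
        """Thresholded SY/DY labels for a sequence of eggs."""
        return [self.classify(e).label for e in eggs]
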