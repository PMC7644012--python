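"""Independent oracles, kept deliberately naive and separate from the package.

Literal transcriptions of the piecewise membership equations, the rule
table and the inference chain, written as plain Python loops with no
imports from :mod:`doubleyolk`'s numeric code paths, so the package and
the oracle can only agree by computing the same mathematics.
"""

from __future__ import annotations

import math


def trimf_full(x: float, a: float, b: float, c: float) -> float:
    """Full triangle, transcribed case by case."""
    if x <= a:
        return 0.0
    if a < x < b:
        return (x - a) / (b - a)
    if x == b:
        return 1.0
    if b < x < c:
        return (c - x) / (c - b)
    return 0.0  # x >= c


def trimf_lower(x: float, b: float, c: float) -> float:
    """Shoulder saturating at 1 on the low side."""
    if x <= b:
        return 1.0
    if b < x < c:
        return (c - x) / (c - b)
    return 0.0  # x >= c


def trimf_upper(x: float, a: float, b: float) -> float:
    """Shoulder saturating at 1 on the high side."""
    if x <= a:
        return 0.0
    if a < x < b:
        return (x - a) / (b - a)
    return 1.0  # x >= b


# rule table: (GI row, WI col) -> 0 single / 1 double
RULE_TABLE = [
    [0, 0, 1],
    [0, 0, 1],
    [0, 1, 1],
]


def fuzzify3(x: float, lo: float, mid: float, hi: float) -> list[float]:
    return [trimf_lower(x, lo, mid), trimf_full(x, lo, mid, hi), trimf_upper(x, mid, hi)]


def classify_literal(ratio: float, weight: float,
                     gi_anchors: tuple[float, float, float],
                     wi_anchors: tuple[float, float, float],
                     threshold: float = 0.5) -> dict:
    """The full inference chain, one explicit step at a time."""
    gi = fuzzify3(ratio, *gi_anchors)
    wi = fuzzify3(weight, *wi_anchors)
    strengths = []
    for i in range(3):
        for j in range(3):
            strengths.append(min(gi[i], wi[j]))
    sum_sq_single = 0.0
    sum_sq_double = 0.0
    k = 0
    for i in range(3):
        for j in range(3):
            if RULE_TABLE[i][j] == 0:
                sum_sq_single += strengths[k] ** 2
            else:
                sum_sq_double += strengths[k] ** 2
            k += 1
    mass_single = math.sqrt(sum_sq_single)
    mass_double = math.sqrt(sum_sq_double)
    if mass_single + mass_double == 0.0:
        truth = 0.0
    else:
        truth = (mass_single * 0.0 + mass_double * 1.0) / (mass_single + mass_double)
    return {
        "gi": gi,
        "wi": wi,
        "strengths": strengths,
        "mass_single": mass_single,
        "mass_double": mass_double,
        "truth": truth,
        "label": "DY" if truth >= threshold else "SY",
    }


def lloyd_brute(points, init, max_iter: int = 100):
    """Plain-loop Lloyd iterations: returns (centroids, assignments, n_iter)."""
    cents = [list(map(float, c)) for c in init]
    assign = [0] * len(points)
    for it in range(1, max_iter + 1):
        for idx, p in enumerate(points):
            d = [math.dist(p, c) for c in cents]
            assign[idx] = d.index(min(d))
        new_cents = []
        for k in range(2):
            members = [p for p, a in zip(points, assign) if a == k]
            if members:
                new_cents.append([sum(m[0] for m in members) / len(members),
                                  sum(m[1] for m in members) / len(members)])
            else:
                new_cents.append(list(cents[k]))
        if new_cents == cents:
            return cents, assign, it
        cents = new_cents
    return cents, assign, max_iter
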