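"""Synthetic egg populations mimicking a commercial flock's morphometry.

No measured egg dataset ships with this package, so every downstream
module is exercised on simulated populations with the documented field
structure: a majority single-yolk (SY) class averaging 69.6 g weight and
1.349 axis ratio, and a minority double-yolk (DY) class averaging 84.9 g
and 1.420, split exactly 180/99 by default.

The two classes are deliberately *not* symmetric Gaussians, because the
flock they emulate is not: the SY weight distribution is right-skewed
(skew-normal), so a tail of large SY eggs reaches into the 78-85 g zone,
and the DY class is a two-mode mixture — large DY eggs that any method
classifies easily, plus a sub-population of small DY eggs (default 35%
of DY, centered near 78.5 g) whose weights and shapes resemble those
large SY eggs.  This overlap structure is what defeats a hard weight
threshold (the K-means baseline misgrades mostly SY eggs, at roughly
triple its DY error rate) and is the regime the fuzzy classifier exists
for.  The skew, mode locations and dispersions were calibrated once
against that reported baseline error signature; they are modelling
choices, not measured values.

Within each class, weight and ratio are positively correlated (default
0.3): heavier eggs run slightly more elongated.  Weights are truncated
at 40 g and ratios at 1.01 to exclude physically impossible eggs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .records import DY, SY, EggRecord

__all__ = ["PopulationConfig", "generate_population", "worked_example_fixture",
           "DEFAULT_SEED"]

DEFAULT_SEED = 1105

_MIN_WEIGHT_G = 40.0
_MIN_RATIO = 1.01


@dataclass(frozen=True)
class PopulationConfig:
    """Parameters of the two-class synthetic egg population.

    Means and SDs are (weight g, ratio) pairs.  ``sy_mean``/``dy_mean``
    are the *class* means; the DY large-mode mean is derived so the
    mixture hits ``dy_mean`` exactly.  ``dy_fraction`` is the exact
    fraction of double-yolk eggs (stratified draw, so the split is
    reproducible, not Bernoulli).  ``sy_weight_skew`` is the skew-normal
    shape of the SY weight marginal (0 = symmetric); ``dy_small_*``
    describe the small-DY sub-population (``dy_sd`` describes the large
    mode).  ``weight_ratio_correlation`` applies within each component.
    """

    n_total: int = 279
    dy_fraction: float = 99 / 279
    sy_mean: tuple[float, float] = (69.61, 1.3494)
    dy_mean: tuple[float, float] = (84.92, 1.4202)
    sy_sd: tuple[float, float] = (7.0, 0.045)
    dy_sd: tuple[float, float] = (4.5, 0.045)
    sy_weight_skew: float = 4.0
    dy_small_fraction: float = 0.35
    dy_small_mean: tuple[float, float] = (78.5, 1.41)
    dy_small_sd: tuple[float, float] = (4.0, 0.045)
    weight_ratio_correlation: float = 0.3
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_total < 2:
            raise ValueError("population needs at least 2 eggs")
        if not 0.0 < self.dy_fraction < 1.0:
            raise ValueError(f"dy_fraction must lie strictly in (0, 1), got {self.dy_fraction}")
        if any(s < 0 for s in (*self.sy_sd, *self.dy_sd, *self.dy_small_sd)):
            raise ValueError("standard deviations must be nonnegative")
        if not -1.0 < self.weight_ratio_correlation < 1.0:
            raise ValueError("correlation must lie strictly in (-1, 1)")
        if not 0.0 <= self.dy_small_fraction < 1.0:
            raise ValueError("dy_small_fraction must lie in [0, 1)")
        if self.dy_mean[0] <= self.sy_mean[0]:
            raise ValueError("double-yolk eggs must be heavier on average than single-yolk")

    @property
    def n_dy(self) -> int:
        return round(self.n_total * self.dy_fraction)

    @property
    def n_sy(self) -> int:
        return self.n_total - self.n_dy

    @property
    def dy_large_mean(self) -> tuple[float, float]:
        """Large-DY-mode mean, derived so the mixture mean is ``dy_mean``."""
        f = self.dy_small_fraction
        if f == 0.0:
            return self.dy_mean
        return (
            (self.dy_mean[0] - f * self.dy_small_mean[0]) / (1 - f),
            (self.dy_mean[1] - f * self.dy_small_mean[1]) / (1 - f),
        )


def _skewnorm_weights(rng: np.random.Generator, n: int, mean: float, sd: float,
                      shape: float) -> np.ndarray:
    """Skew-normal draws parameterized by their mean and SD."""
    if sd == 0.0:
        return np.full(n, mean)
    delta = shape / math.sqrt(1.0 + shape * shape)
    scale = sd / math.sqrt(1.0 - 2.0 * delta * delta / math.pi)
    loc = mean - scale * delta * math.sqrt(2.0 / math.pi)
    return stats.skewnorm.rvs(shape, loc=loc, scale=scale, size=n, random_state=rng)


def _draw_component(rng: np.random.Generator, n: int, mean, sd, corr: float,
                    weight_skew: float = 0.0) -> np.ndarray:
    """Draw n (weight, ratio) pairs from one population component.

    The ratio is generated conditionally on the (possibly skewed) weight,
    which preserves the configured marginal mean/SD and correlation.
    """
    if n == 0:
        return np.empty((0, 2))
    w = _skewnorm_weights(rng, n, mean[0], sd[0], weight_skew)
    z = rng.standard_normal(n)
    if sd[0] > 0:
        r = mean[1] + corr * sd[1] * (w - mean[0]) / sd[0] + sd[1] * math.sqrt(1 - corr**2) * z
    else:
        r = mean[1] + sd[1] * z
    pts = np.column_stack([w, r])
    pts[:, 0] = np.maximum(pts[:, 0], _MIN_WEIGHT_G)
    pts[:, 1] = np.maximum(pts[:, 1], _MIN_RATIO)
    return pts


def _minor_axis_mm(rng: np.random.Generator, weight: np.ndarray) -> np.ndarray:
    """Plausible minor-axis length: a hen egg of ~60 g is ~44 mm wide."""
    return 44.0 + 0.18 * (weight - 60.0) + rng.normal(0.0, 0.4, size=weight.shape)


def generate_population(config: PopulationConfig | None = None, *,
                        seed: int | None = None) -> list[EggRecord]:
    """Generate a labeled egg population, reproducible from its seed.

    Class counts are exact (stratified); each egg also carries consistent
    major/minor axis lengths in millimetres, back-computed from its ratio
    and a weight-dependent width.
    """
    config = config or PopulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    sy = _draw_component(rng, config.n_sy, config.sy_mean, config.sy_sd,
                         config.weight_ratio_correlation, config.sy_weight_skew)
    n_small = round(config.n_dy * config.dy_small_fraction)
    dy_small = _draw_component(rng, n_small, config.dy_small_mean, config.dy_small_sd,
                               config.weight_ratio_correlation)
    dy_large = _draw_component(rng, config.n_dy - n_small, config.dy_large_mean,
                               config.dy_sd, config.weight_ratio_correlation)
    dy = np.vstack([dy_small, dy_large])
    eggs: list[EggRecord] = []
    for pts, label in ((sy, SY), (dy, DY)):
        minor = _minor_axis_mm(rng, pts[:, 0])
        for (w, r), m in zip(pts, minor):
            eggs.append(EggRecord(weight=float(w), ratio=float(r),
                                  major=float(r * m), minor=float(m), label=label))
    return eggs


def worked_example_fixture() -> EggRecord:
    """The single documented worked-example egg: 72 g, axis ratio 1.45."""
    return EggRecord(weight=72.0, ratio=1.45)
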