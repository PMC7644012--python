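"""K-means (k = 2) hard-clustering baseline in (weight, ratio) space.

Lloyd's algorithm, run exactly as a practitioner would by hand:

1. pick two initial centroids;
2. assign every egg to the nearest centroid (Euclidean distance);
3. recompute each centroid as the mean of its assigned eggs;
4. repeat until the centroids do not change (exact repetition), or a
   safety cap of iterations is reached.

Distance is *unscaled* by default, so the gram axis dominates the
dimensionless ratio axis numerically and the clustering is nearly a
weight threshold; ``scaling="standardize"`` divides each axis by its
sample SD first.  Because the split is hard, eggs in the SY/DY
intersection zone are forced to one side — the failure mode the fuzzy
classifier addresses.

The cluster with the lower centroid weight is read as single-yolk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import DY, SY, EggRecord

__all__ = ["KMeansResult", "DEFAULT_INIT_CENTROIDS", "run_kmeans",
           "kmeans_labels", "random_init"]

# Two extreme eggs of the reference flock: a reproducible, data-plausible start.
DEFAULT_INIT_CENTROIDS = ((57.64, 1.2599), (97.78, 1.5065))


@dataclass(frozen=True, eq=False)
class KMeansResult:
    """Outcome of one Lloyd run.

    ``centroids`` are the final two (weight g, ratio) centers in the
    *original* units regardless of scaling; ``trace`` records them after
    every iteration (entry 0 = the initial pair), so a converged run's
    last two entries are identical.  ``empty_cluster`` flags that a
    cluster lost all its points at some iteration and kept its previous
    centroid.
    """

    centroids: np.ndarray
    assignments: np.ndarray
    trace: tuple[np.ndarray, ...]
    n_iterations: int
    converged: bool
    scaling: str = "none"
    empty_cluster: bool = False

    @property
    def inertia(self) -> float:
        """Within-cluster sum of squared (unscaled) distances."""
        diffs = self._points - self.centroids[self.assignments]
        return float(np.sum(diffs**2))


def _as_points(eggs: Sequence[EggRecord] | np.ndarray) -> np.ndarray:
    if isinstance(eggs, np.ndarray):
        pts = np.asarray(eggs, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("point array must have shape (n, 2)")
        return pts
    return np.array([[e.weight, e.ratio] for e in eggs], dtype=float)


def run_kmeans(eggs: Sequence[EggRecord] | np.ndarray,
               init_centroids=DEFAULT_INIT_CENTROIDS,
               max_iter: int = 100,
               scaling: str = "none") -> KMeansResult:
    """Cluster eggs into two groups by Lloyd iterations.

    Parameters
    ----------
    eggs
        Egg records, or an ``(n, 2)`` array of (weight g, ratio) points.
    init_centroids
        Two distinct starting centers in original units.
    max_iter
        Safety cap; the natural stop is exact centroid repetition.
    scaling
        ``"none"`` (raw grams vs ratio) or ``"standardize"`` (divide each
        axis by its sample SD before measuring distances).
    """
    pts = _as_points(eggs)
    if len(pts) < 2:
        raise ValueError("need at least 2 eggs")
    cent = np.array(init_centroids, dtype=float)
    if cent.shape != (2, 2) or np.allclose(cent[0], cent[1]):
        raise ValueError("need two distinct initial centroids")
    if scaling not in ("none", "standardize"):
        raise ValueError(f"unknown scaling {scaling!r}")

    if scaling == "standardize":
        scale = pts.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
    else:
        scale = np.ones(2)

    work = pts / scale
    cent_w = cent / scale
    trace = [cent_w * scale]
    assignments = np.zeros(len(pts), dtype=int)
    converged = False
    empty = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d = np.linalg.norm(work[:, None, :] - cent_w[None, :, :], axis=2)
        assignments = np.argmin(d, axis=1)
        new_cent = cent_w.copy()
        for k in (0, 1):
            members = work[assignments == k]
            if len(members):
                new_cent[k] = members.mean(axis=0)
            else:
                empty = True  # keep the previous centroid
        trace.append(new_cent * scale)
        if np.array_equal(new_cent, cent_w):
            converged = True
            cent_w = new_cent
            break
        cent_w = new_cent

    result = KMeansResult(
        centroids=cent_w * scale,
        assignments=assignments,
        trace=tuple(trace),
        n_iterations=n_iter,
        converged=converged,
        scaling=scaling,
        empty_cluster=empty,
    )
    object.__setattr__(result, "_points", pts)
    return result


def kmeans_labels(result: KMeansResult) -> list[str]:
    """Read the two clusters as SY/DY: the lighter-centroid cluster is SY.

    Ties on centroid weight fall back to the ratio axis; fully identical
    centroids are ambiguous and raise.
    """
    w0, w1 = result.centroids[:, 0]
    if w0 != w1:
        sy_cluster = 0 if w0 < w1 else 1
    else:
        r0, r1 = result.centroids[:, 1]
        if r0 == r1:
            raise ValueError("identical centroids: clusters cannot be told apart")
        sy_cluster = 0 if r0 < r1 else 1
    return [SY if a == sy_cluster else DY for a in result.assignments]


def random_init(eggs: Sequence[EggRecord] | np.ndarray, seed: int) -> np.ndarray:
    """Two random starting centroids, uniform over the data's bounding box."""
    pts = _as_points(eggs)
    rng = np.random.default_rng(seed)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    while True:
        cent = rng.uniform(lo, hi, size=(2, 2))
        if not np.allclose(cent[0], cent[1]):
            return cent
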