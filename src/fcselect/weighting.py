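"""Filter-based feature weighting, knee-point stratification, and task generation.

Each edge feature j receives three univariate scores:

* Fisher criterion  h_j = |mu_j0 - mu_j1|^2 / (sd_j0^2 + sd_j1^2),
  the squared between-class mean gap over the summed within-class
  variances (population standard deviations throughout);
* mutual information m_j between the discretised feature (equal-frequency
  bins) and the class label, in nats;
* marginal dispersion sigma_j, the population standard deviation.

The combined weight is the convex combination
s_j = a1*h_j + a2*m_j + a3*sigma_j (components min-max normalised by
default so the mixing weights are commensurable).  Sorting s_j descending
gives a weight curve on which two knee points — maximisers of the
perpendicular distance to the chord joining the curve's endpoints — split
the features into core / important / remaining strata.  Task candidate
sets are then drawn probabilistically: feature j enters a task when a
uniform draw lambda falls at or below its rescaled selection probability
P'_j = P_j / max(P), which guarantees the top-weighted feature is in
every task while low-weight features retain a proportional chance.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np

from .data import FeatureDataset

__all__ = [
    "FeatureWeightTable",
    "KneePartition",
    "TaskCollection",
    "fisher_scores",
    "mutual_information_scores",
    "std_scores",
    "combine_weights",
    "compute_weight_table",
    "detect_knees",
    "selection_probabilities",
    "generate_tasks",
]

_EPS = 1e-12


@dataclasses.dataclass
class FeatureWeightTable:
    fisher: np.ndarray
    mutinfo: np.ndarray
    stdev: np.ndarray
    combined: np.ndarray
    rank_order: np.ndarray          # permutation: rank_order[0] = best feature id
    alphas: tuple[float, float, float]

    def __post_init__(self) -> None:
        q = self.combined.size
        if sorted(self.rank_order.tolist()) != list(range(q)):
            raise ValueError("rank_order must be a permutation of 0..q-1")
        if abs(sum(self.alphas) - 1.0) > 1e-12:
            raise ValueError("alphas must sum to 1")

    @property
    def n_features(self) -> int:
        return self.combined.size

    def sorted_weights(self) -> np.ndarray:
        return self.combined[self.rank_order]


@dataclasses.dataclass
class KneePartition:
    knee1: int | None               # rank position (0-based) of the first knee
    knee2: int | None
    strata: np.ndarray              # per-feature labels "core"/"important"/"remaining"


@dataclasses.dataclass
class TaskCollection:
    masks: np.ndarray               # (n, q) binary
    lambdas: np.ndarray
    seed: int

    @property
    def n_tasks(self) -> int:
        return self.masks.shape[0]


def fisher_scores(ds: FeatureDataset) -> np.ndarray:
    """Per-feature Fisher class-separability scores."""
    ds.require_both_classes()
    x0 = ds.features[ds.labels == 0]
    x1 = ds.features[ds.labels == 1]
    num = np.abs(x0.mean(axis=0) - x1.mean(axis=0)) ** 2
    den = x0.std(axis=0) ** 2 + x1.std(axis=0) ** 2
    return num / (den + _EPS)


def mutual_information_scores(ds: FeatureDataset, n_bins: int = 10,
                              normalize: bool = False) -> np.ndarray:
    """MI (nats) between each equal-frequency-binned feature and the label.

    Implements the plug-in double sum over the empirical joint distribution;
    ``normalize`` divides by the label entropy H(Y), bounding scores in [0,1].
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    y = ds.labels
    p = y.size
    py = np.bincount(y, minlength=2) / p
    hy = -np.sum(py[py > 0] * np.log(py[py > 0]))
    out = np.empty(ds.n_features)
    for j in range(ds.n_features):
        z = _equal_frequency_bins(ds.features[:, j], n_bins)
        out[j] = _discrete_mi(z, y)
    if normalize and hy > 0:
        out = out / hy
    return out


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="left")


def _discrete_mi(z: np.ndarray, y: np.ndarray) -> float:
    _, z = np.unique(z, return_inverse=True)
    joint = np.zeros((z.max() + 1, 2))
    np.add.at(joint, (z, y), 1.0)
    joint /= joint.sum()
    pz = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (pz * py))
    return float(np.nansum(terms))


def std_scores(ds: FeatureDataset) -> np.ndarray:
    """Per-feature population standard deviation (marginal dispersion)."""
    if ds.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    return ds.features.std(axis=0)


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi - lo < _EPS:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def combine_weights(fisher: np.ndarray, mutinfo: np.ndarray, stdev: np.ndarray,
                    alphas: Sequence[float] = (0.4, 0.4, 0.2),
                    raw_components: bool = False) -> FeatureWeightTable:
    """Convex combination of the three score components.

    Components are min-max normalised across features before mixing unless
    ``raw_components`` is set (the literal unscaled combination).  Rank ties
    break toward the smaller feature index.
    """
    a1, a2, a3 = alphas
    if abs(a1 + a2 + a3 - 1.0) > 1e-12:
        raise ValueError(f"alphas must sum to 1, got {alphas}")
    h, m, s = (np.asarray(v, dtype=float) for v in (fisher, mutinfo, stdev))
    if raw_components:
        hn, mn, sn = h, m, s
    else:
        hn, mn, sn = _minmax(h), _minmax(m), _minmax(s)
    combined = a1 * hn + a2 * mn + a3 * sn
    # stable sort on -combined -> ties resolve to the smallest index
    order = np.argsort(-combined, kind="stable")
    return FeatureWeightTable(h, m, s, combined, order, (a1, a2, a3))


def compute_weight_table(ds: FeatureDataset, alphas: Sequence[float] = (0.4, 0.4, 0.2),
                         n_bins: int = 10, raw_components: bool = False,
                         normalize_mi: bool = False) -> FeatureWeightTable:
    """Score every feature and combine into a ranked weight table."""
    return combine_weights(
        fisher_scores(ds),
        mutual_information_scores(ds, n_bins=n_bins, normalize=normalize_mi),
        std_scores(ds),
        alphas=alphas,
        raw_components=raw_components,
    )


def _chord_distances(y: np.ndarray) -> np.ndarray:
    """Perpendicular distance of each curve point to the endpoint chord.

    x-coordinates are the 1-based rank indices; endpoints get distance 0.
    """
    n = y.size
    x = np.arange(1, n + 1, dtype=float)
    a = (y[-1] - y[0]) / (x[-1] - x[0])
    b = y[0] - a * x[0]
    d = np.abs(y - (a * x + b)) / np.sqrt(a * a + 1.0)
    d[0] = d[-1] = 0.0
    return d


def detect_knees(weights_sorted_desc: np.ndarray) -> KneePartition:
    """Locate up to two knee points on a descending weight curve.

    The first knee maximises the chord distance over interior points of the
    full curve; the second repeats the procedure on the sub-curve strictly
    after the first knee.  A maximal distance below 1e-12 (flat or perfectly
    linear curve) yields no knee and the affected strata collapse.
    """
    y = np.asarray(weights_sorted_desc, dtype=float)
    q = y.size
    if q < 3:
        raise ValueError("need at least 3 points for knee detection")

    def best_interior(seg: np.ndarray) -> int | None:
        if seg.size < 3:
            return None
        d = _chord_distances(seg)
        j = int(np.argmax(d[1:-1])) + 1
        return j if d[j] >= _EPS else None

    knee1 = best_interior(y)
    knee2 = None
    if knee1 is not None:
        sub = y[knee1 + 1:]
        j2 = best_interior(sub)
        if j2 is not None:
            knee2 = knee1 + 1 + j2

    strata = np.empty(q, dtype=object)
    if knee1 is None:
        strata[:] = "core"
    elif knee2 is None:
        strata[:knee1] = "core"
        strata[knee1:] = "important"
    else:
        strata[:knee1] = "core"
        strata[knee1:knee2] = "important"
        strata[knee2:] = "remaining"
    return KneePartition(knee1, knee2, strata)


def selection_probabilities(table: FeatureWeightTable) -> tuple[np.ndarray, np.ndarray]:
    """Weight-proportional probabilities P and their max-rescaled form P'."""
    w = table.combined
    total = w.sum()
    if total <= 0:
        raise ValueError("all combined weights are zero; cannot form probabilities")
    p = w / total
    return p, p / p.max()


def generate_tasks(p_prime: np.ndarray, n: int, seed: int,
                   mode: Literal["per_task_lambda", "per_feature_lambda"] = "per_task_lambda",
                   max_retries: int = 100) -> TaskCollection:
    """Draw n task candidate sets from the rescaled selection probabilities.

    The default draws one threshold lambda per task (feature j enters when
    lambda <= P'_j); ``per_feature_lambda`` draws an independent lambda per
    feature.  Empty tasks are redrawn up to ``max_retries`` times.
    """
    if n < 1:
        raise ValueError("need at least one task")
    p_prime = np.asarray(p_prime, dtype=float)
    rng = np.random.default_rng(seed)
    masks, lams = [], []
    for _ in range(n):
        for attempt in range(max_retries):
            if mode == "per_task_lambda":
                lam = rng.uniform()
                mask = (lam <= p_prime).astype(np.int8)
                lam_rec = lam
            elif mode == "per_feature_lambda":
                lam = rng.uniform(size=p_prime.size)
                mask = (lam <= p_prime).astype(np.int8)
                lam_rec = np.nan
            else:
                raise ValueError(f"unknown task mode {mode!r}")
            if mask.any():
                masks.append(mask)
                lams.append(lam_rec)
                break
        else:
            raise RuntimeError(f"failed to draw a nonempty task in {max_retries} tries")
    return TaskCollection(np.array(masks), np.array(lams), seed)
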