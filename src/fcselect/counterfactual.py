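"""Diverse counterfactual explanations for the linear margin classifier.

For a patient's selected-feature vector c, the explainer seeks L
perturbed vectors x^1..x^L whose predictions flip to the target class
while staying close to c and mutually distinct.  The joint objective
minimised over the whole candidate set is

    (1/L) sum_l hinge(x^l)  +  gamma1 * (1/L) sum_l dist(x^l, c)
                            -  gamma2 * det(K)

with hinge(x) = max(0, 1 - z * (w.x + b)) (z = +1 for target class 1,
-1 for class 0), dist the mean per-feature absolute difference scaled by
the training-set median absolute deviation (MAD), and K the
similarity kernel K_uv = 1 / (1 + dist(x^u, x^v)) whose determinant is a
determinantal-point-process diversity score (near 0 for duplicate
candidates, near 1 for well-separated ones).  A small seeded jitter on
the kernel diagonal keeps the determinant away from exact singularity.

Hinge and proximity terms have analytic subgradients; the determinant
term is differentiated by central finite differences, which is cheap
because only the k selected features are perturbed (k << q).
Counterfactual values are not box-constrained by default: a modified
edge may leave the [-1, 1] correlation range, which is reported rather
than clipped.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .classify import MarginModel
from .data import FeatureDataset, ROIAtlas

__all__ = [
    "CFConfig",
    "MADVector",
    "CounterfactualSet",
    "compute_mads",
    "hinge_loss",
    "proximity",
    "diversity_det",
    "cf_objective",
    "generate_counterfactuals",
    "change_report",
]


@dataclasses.dataclass(frozen=True)
class CFConfig:
    L: int = 10
    gamma1: float = 0.5
    gamma2: float = 1.0
    target_label: int = 1
    learning_rate: float = 0.05
    max_iters: int = 1000
    init_noise_sd: float = 0.1
    diag_jitter_scale: float = 1e-4
    seed: int = 0
    clip_range: tuple[float, float] | None = None
    normalize_by: str = "k"            # "k": mean over features; "L": literal 1/L constant

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("need at least one counterfactual")
        if self.gamma1 < 0 or self.gamma2 < 0:
            raise ValueError("gamma weights must be non-negative")
        if self.target_label not in (0, 1):
            raise ValueError("target_label must be 0 or 1")


@dataclasses.dataclass
class MADVector:
    values: np.ndarray
    fallback_sd: np.ndarray            # features where MAD==0 fell back to the sd
    fallback_unit: np.ndarray          # features where sd was also 0 -> 1.0


@dataclasses.dataclass
class CounterfactualSet:
    original: np.ndarray               # (k,)
    candidates: np.ndarray             # (L, k)
    valid: np.ndarray                  # (L,) bool
    hinge_part: float
    proximity_part: float
    diversity_part: float
    total: float
    iterations: int
    feature_ids: np.ndarray

    @property
    def validity_rate(self) -> float:
        return float(self.valid.mean())


def compute_mads(ds_train: FeatureDataset, mask: np.ndarray) -> MADVector:
    """Median absolute deviation per selected feature, with degeneracy fallbacks.

    A zero MAD (more than half the training values identical) falls back to
    the feature's population standard deviation, then to 1.0, so the
    proximity scale is always strictly positive.
    """
    ids = np.flatnonzero(np.asarray(mask).astype(bool))
    x = ds_train.features[:, ids]
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med), axis=0)
    sd = x.std(axis=0)
    fb_sd = mad == 0
    mad = np.where(fb_sd, sd, mad)
    fb_unit = mad == 0
    mad = np.where(fb_unit, 1.0, mad)
    return MADVector(mad, fb_sd & ~fb_unit, fb_unit)


def hinge_loss(model: MarginModel, x: np.ndarray, target_label: int) -> float:
    """max(0, 1 - z * logit) with z = +1 for target 1, -1 for target 0."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.weights.size:
        raise ValueError(
            f"dimension mismatch: x has {x.shape[-1]} features, model {model.weights.size}")
    z = 1.0 if target_label == 1 else -1.0
    logit = float(x @ model.weights + model.bias)
    return max(0.0, 1.0 - z * logit)


def proximity(x: np.ndarray, c: np.ndarray, mads: MADVector | np.ndarray,
              normalize_by: str = "k", L: int | None = None) -> float:
    """MAD-scaled mean absolute per-feature distance between x and c."""
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    if x.shape != c.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {c.shape}")
    mvals = mads.values if isinstance(mads, MADVector) else np.asarray(mads, dtype=float)
    denom = x.size if normalize_by == "k" else (L if L is not None else x.size)
    return float(np.sum(np.abs(x - c) / mvals) / denom)


def diversity_det(candidates: np.ndarray, mads: MADVector | np.ndarray,
                  jitter_scale: float = 1e-4,
                  rng: np.random.Generator | None = None,
                  jitter: np.ndarray | None = None) -> float:
    """Determinant of the inverse-distance similarity kernel over candidates.

    ``jitter`` (or a draw of uniform [0, jitter_scale] from ``rng``) is
    added to the diagonal to keep near-singular kernels numerically stable.
    """
    x = np.atleast_2d(np.asarray(candidates, dtype=float))
    L = x.shape[0]
    if jitter is None:
        if rng is None:
            rng = np.random.default_rng(0)
        jitter = rng.uniform(0.0, jitter_scale, size=L)
    k = np.empty((L, L))
    for u in range(L):
        k[u, u] = 1.0 + jitter[u]
        for v in range(u + 1, L):
            k[u, v] = k[v, u] = 1.0 / (1.0 + proximity(x[u], x[v], mads))
    return float(np.linalg.det(k))


def cf_objective(model: MarginModel, candidates: np.ndarray, c: np.ndarray,
                 mads: MADVector, config: CFConfig,
                 jitter: np.ndarray | None = None) -> tuple[float, dict[str, float]]:
    """Joint counterfactual objective and its decomposition."""
    x = np.atleast_2d(candidates)
    L = x.shape[0]
    hinge = float(np.mean([hinge_loss(model, x[l], config.target_label) for l in range(L)]))
    prox = float(np.mean([
        proximity(x[l], c, mads, config.normalize_by, L) for l in range(L)]))
    div = diversity_det(x, mads, config.diag_jitter_scale, jitter=jitter)
    total = hinge + config.gamma1 * prox - config.gamma2 * div
    return total, {"hinge": hinge, "proximity": prox, "diversity": div}


def _diversity_grad(x: np.ndarray, mads: MADVector, jitter: np.ndarray,
                    h: float = 1e-5) -> np.ndarray:
    """Central-difference gradient of det(K) w.r.t. every candidate coordinate."""
    g = np.zeros_like(x)
    for l in range(x.shape[0]):
        for j in range(x.shape[1]):
            orig = x[l, j]
            x[l, j] = orig + h
            fp = diversity_det(x, mads, jitter=jitter)
            x[l, j] = orig - h
            fm = diversity_det(x, mads, jitter=jitter)
            x[l, j] = orig
            g[l, j] = (fp - fm) / (2 * h)
    return g


def generate_counterfactuals(model: MarginModel, c: np.ndarray,
                             ds_train: FeatureDataset, config: CFConfig,
                             mads: MADVector | None = None) -> CounterfactualSet:
    """Jointly optimise L diverse counterfactual candidates for one subject.

    Candidates start at c plus seeded Gaussian noise and follow fixed-step
    subgradient descent on :func:`cf_objective`; descent stops early once
    every candidate is valid and the relative objective change falls below
    1e-5.  Only the model's selected features are represented (and hence
    perturbed); all other edges are implicitly frozen.
    """
    c = np.asarray(c, dtype=float)
    k = model.weights.size
    if c.size != k:
        raise ValueError(f"subject vector has {c.size} features, model expects {k}")
    if mads is None:
        mads = compute_mads(ds_train, np.isin(np.arange(ds_train.n_features),
                                              model.feature_ids))
    rng = np.random.default_rng(config.seed)
    jitter = rng.uniform(0.0, config.diag_jitter_scale, size=config.L)
    x = c + rng.normal(0.0, config.init_noise_sd, size=(config.L, k))

    z = 1.0 if config.target_label == 1 else -1.0
    w = model.weights
    denom = k if config.normalize_by == "k" else config.L
    prev_total = np.inf
    iters_used = config.max_iters
    for it in range(config.max_iters):
        # gradients of the L-sum (same minimiser as the mean, per-candidate steps)
        logits = x @ w + model.bias
        active = (1.0 - z * logits) > 0          # hinge subgradient support
        g_hinge = np.where(active[:, None], -z * w[None, :], 0.0)
        g_prox = config.gamma1 * np.sign(x - c) / (mads.values * denom)
        g_div = (config.L * _diversity_grad(x, mads, jitter) if config.gamma2 > 0
                 else np.zeros_like(x))
        x -= config.learning_rate * (g_hinge + g_prox - config.gamma2 * g_div)
        if config.clip_range is not None:
            x = np.clip(x, *config.clip_range)

        total, _ = cf_objective(model, x, c, mads, config, jitter=jitter)
        if not np.isfinite(total):
            raise FloatingPointError(f"non-finite objective at iteration {it}")
        preds = (x @ w + model.bias >= 0).astype(int)
        all_valid = bool(np.all(preds == config.target_label))
        rel_change = abs(prev_total - total) / max(1.0, abs(total))
        if all_valid and rel_change < 1e-5:
            iters_used = it + 1
            break
        prev_total = total

    total, parts = cf_objective(model, x, c, mads, config, jitter=jitter)
    preds = (x @ w + model.bias >= 0).astype(int)
    return CounterfactualSet(
        original=c, candidates=x, valid=preds == config.target_label,
        hinge_part=parts["hinge"], proximity_part=parts["proximity"],
        diversity_part=parts["diversity"], total=total,
        iterations=iters_used, feature_ids=model.feature_ids.copy(),
    )


def change_report(cfs: CounterfactualSet, edge_index: list[tuple[int, int]],
                  atlas: ROIAtlas, tol: float = 1e-6) -> pd.DataFrame:
    """Per-candidate, per-edge table of original vs counterfactual FC values."""
    if cfs.feature_ids.max() >= len(edge_index):
        raise ValueError("edge_index does not cover the model's feature ids")
    rows = []
    for l in range(cfs.candidates.shape[0]):
        for pos, fid in enumerate(cfs.feature_ids):
            a, b = edge_index[fid]
            orig = cfs.original[pos]
            new = cfs.candidates[l, pos]
            delta = new - orig
            direction = ("unchanged" if abs(delta) < tol
                         else "increase" if delta > 0 else "decrease")
            rows.append((l + 1, fid + 1, atlas.names[a], atlas.names[b],
                         orig, new, delta, direction))
    return pd.DataFrame(rows, columns=[
        "candidate_id", "feature_id", "roi_a", "roi_b",
        "original_value", "cf_value", "delta", "direction"])
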