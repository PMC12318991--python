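"""Binary multi-task grey wolf optimisation with knowledge transfer.

Each task is a wrapper feature-selection search over its candidate edge
set.  Wolves hold continuous positions in [0,1]^dim that decode to binary
masks at the 0.5 threshold; the three best masks found so far (alpha,
beta, delta) jointly steer every other wolf through the classic encircle
update with a linearly decaying exploration coefficient d: 2 -> 0.

Fitness trades inner-cross-validated accuracy of the margin classifier
against subset size:

    fitness = rho * ACC - (1 - rho) * |mask| / dim

Tasks run sequentially.  After each task its best mask is added to a
global knowledge base of per-feature selection counts; later tasks
initialise their packs from the normalised counts (floored at a small
epsilon so no feature goes extinct), which is the knowledge-transfer
mechanism that lets early discoveries seed later searches.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data import FeatureDataset
from .weighting import TaskCollection

__all__ = [
    "GWOConfig",
    "Pack",
    "KnowledgeBase",
    "TaskResult",
    "MultiTaskResult",
    "coefficient_vectors",
    "encircle_update",
    "binarize",
    "fitness",
    "FitnessEvaluator",
    "transfer_probabilities",
    "initialize_pack",
    "run_gwo_task",
    "run_multitask",
]


@dataclasses.dataclass(frozen=True)
class GWOConfig:
    pack_size: int = 30
    t_max: int = 100
    rho: float = 0.9
    seed: int = 0
    inner_cv_folds: int = 3
    transfer_floor: float = 0.05
    svm_C: float = 1.0
    aggregate: str = "majority"        # majority | best | union
    knowledge_transfer: bool = True
    penalty_scope: str = "task"        # "task": dim = candidate count; "global": dim = q

    def __post_init__(self) -> None:
        if self.pack_size < 4:
            raise ValueError("pack_size must be at least 4 (three leaders + one)")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.t_max < 1:
            raise ValueError("t_max must be at least 1")
        if self.aggregate not in ("majority", "best", "union"):
            raise ValueError(f"unknown aggregate rule {self.aggregate!r}")


@dataclasses.dataclass
class Pack:
    positions: np.ndarray           # (pack_size, dim) in [0,1]
    leader_masks: list[np.ndarray]  # alpha, beta, delta binary masks
    leader_fitness: list[float]     # descending
    t: int = 0


@dataclasses.dataclass
class KnowledgeBase:
    counts: np.ndarray              # (q,) cumulative selection counts
    tasks_recorded: int = 0

    @classmethod
    def empty(cls, q: int) -> "KnowledgeBase":
        return cls(np.zeros(q, dtype=int), 0)

    def record(self, mask: np.ndarray) -> None:
        self.counts += np.asarray(mask, dtype=int)
        self.tasks_recorded += 1


@dataclasses.dataclass
class TaskResult:
    task_id: int
    best_mask: np.ndarray           # global-index binary vector (length q)
    best_fitness: float
    fitness_trace: np.ndarray       # per-iteration best-so-far
    initial_best_fitness: float


@dataclasses.dataclass
class MultiTaskResult:
    task_results: list[TaskResult]
    aggregated_mask: np.ndarray
    selection_frequency: np.ndarray
    knowledge_base: KnowledgeBase

    @property
    def best_task(self) -> TaskResult:
        return max(self.task_results, key=lambda r: r.best_fitness)


def coefficient_vectors(t: int, t_max: int, rng: np.random.Generator,
                        dim: int) -> tuple[float, np.ndarray, np.ndarray]:
    """Exploration coefficients: d decays linearly 2 -> 0; A in [-d, d], C in [0, 2]."""
    d = 2.0 * (1.0 - t / t_max)
    r1 = rng.uniform(size=dim)
    r2 = rng.uniform(size=dim)
    return d, 2.0 * d * r1 - d, 2.0 * r2


def encircle_update(position: np.ndarray, leaders: Sequence[np.ndarray],
                    t: int, t_max: int, rng: np.random.Generator) -> np.ndarray:
    """Move a wolf toward the mean of the three leader-guided targets."""
    dim = position.size
    acc = np.zeros(dim)
    for leader in leaders:
        _, a_vec, c_vec = coefficient_vectors(t, t_max, rng, dim)
        dist = np.abs(c_vec * leader - position)
        acc += leader - a_vec * dist
    return np.clip(acc / len(leaders), 0.0, 1.0)


def binarize(position: np.ndarray) -> np.ndarray:
    """Decode a continuous position to a binary mask at the 0.5 threshold."""
    return (np.asarray(position) >= 0.5).astype(np.int8)


class FitnessEvaluator:
    """Memoised wrapper-fitness over a task's candidate features.

    ACC is the mean stratified inner-CV accuracy of a linear SVM on the
    masked training features; the parsimony penalty is |mask|/dim with dim
    the task candidate count (or the global feature count when
    ``penalty_scope="global"``).  Empty masks score -1.
    """

    def __init__(self, ds_train: FeatureDataset, candidate_ids: np.ndarray,
                 config: GWOConfig, global_q: int | None = None):
        ds_train.require_both_classes()
        counts = np.bincount(ds_train.labels, minlength=2)
        self.n_folds = min(config.inner_cv_folds, int(counts.min()))
        if self.n_folds < 2:
            raise ValueError("training split must have >= 2 subjects per class")
        self.x = ds_train.features[:, candidate_ids]
        self.y = ds_train.labels
        self.config = config
        self.dim = (global_q if config.penalty_scope == "global" and global_q
                    else candidate_ids.size)
        self._splits = list(
            StratifiedKFold(self.n_folds, shuffle=True,
                            random_state=config.seed % (2**32)).split(self.x, self.y))
        self._cache: dict[bytes, float] = {}
        self.n_evals = 0

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=np.int8)
        key = mask.tobytes()
        if key in self._cache:
            return self._cache[key]
        if not mask.any():
            fit = -1.0
        else:
            cols = np.flatnonzero(mask)
            acc = 0.0
            for tr, te in self._splits:
                clf = SVC(kernel="linear", C=self.config.svm_C)
                clf.fit(self.x[np.ix_(tr, cols)], self.y[tr])
                acc += float(np.mean(clf.predict(self.x[np.ix_(te, cols)]) == self.y[te]))
            acc /= len(self._splits)
            rho = self.config.rho
            fit = rho * acc - (1.0 - rho) * mask.sum() / self.dim
            self.n_evals += 1
        self._cache[key] = fit
        return fit


def fitness(mask: np.ndarray, ds_train: FeatureDataset, config: GWOConfig,
            candidate_ids: np.ndarray | None = None) -> float:
    """One-shot fitness evaluation (see :class:`FitnessEvaluator`)."""
    if candidate_ids is None:
        candidate_ids = np.arange(ds_train.n_features)
    return FitnessEvaluator(ds_train, candidate_ids, config)(mask)


def transfer_probabilities(kb: KnowledgeBase, floor: float = 0.05) -> np.ndarray | None:
    """Per-feature initialisation probabilities from the knowledge base.

    Selection counts are normalised to a distribution and floored at
    ``floor`` so unseen features keep a small inclusion chance; returns
    None when there is no history (caller falls back to the weighting
    probabilities P').
    """
    total = kb.counts.sum()
    if total <= 0:
        return None
    return np.maximum(kb.counts / total, floor)


def initialize_pack(dim: int, p_init: np.ndarray, config: GWOConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Bernoulli-initialise wolf positions: bit j set iff lambda <= p_init_j."""
    lam = rng.uniform(size=(config.pack_size, dim))
    return (lam <= p_init).astype(float)


def _update_leaders(masks: list[np.ndarray], fits: list[float],
                    leaders: list[np.ndarray], lfits: list[float]) -> None:
    """Merge new (mask, fitness) pairs into the alpha/beta/delta shortlist."""
    for m, f in zip(masks, fits):
        if any(np.array_equal(m, lm) for lm in leaders):
            continue
        for i in range(3):
            if i >= len(lfits) or f > lfits[i]:
                leaders.insert(i, m)
                lfits.insert(i, f)
                del leaders[3:], lfits[3:]
                break


def run_gwo_task(task_mask: np.ndarray, ds_train: FeatureDataset, kb: KnowledgeBase,
                 config: GWOConfig, p_prime: np.ndarray, task_id: int = 0,
                 rng: np.random.Generator | None = None) -> TaskResult:
    """Optimise one task's feature subset with the grey wolf search."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    candidate_ids = np.flatnonzero(task_mask)
    if candidate_ids.size == 0:
        raise ValueError("task candidate set is empty")
    q = task_mask.size
    evaluator = FitnessEvaluator(ds_train, candidate_ids, config, global_q=q)
    dim = candidate_ids.size

    p_init = transfer_probabilities(kb, config.transfer_floor) if config.knowledge_transfer else None
    p_local = p_prime[candidate_ids] if p_init is None else p_init[candidate_ids]
    positions = initialize_pack(dim, p_local, config, rng)

    masks = [binarize(p) for p in positions]
    fits = [evaluator(m) for m in masks]
    leaders: list[np.ndarray] = []
    lfits: list[float] = []
    _update_leaders(masks, fits, leaders, lfits)
    while len(leaders) < 3:                    # degenerate tiny packs
        leaders.append(leaders[-1].copy())
        lfits.append(lfits[-1])
    initial_best = lfits[0]

    trace = np.empty(config.t_max)
    for t in range(1, config.t_max + 1):
        lead_pos = [lm.astype(float) for lm in leaders]
        new_masks, new_fits = [], []
        for w in range(config.pack_size):
            positions[w] = encircle_update(positions[w], lead_pos, t, config.t_max, rng)
            m = binarize(positions[w])
            new_masks.append(m)
            new_fits.append(evaluator(m))
        _update_leaders(new_masks, new_fits, leaders, lfits)
        trace[t - 1] = lfits[0]

    best_local = leaders[0]
    best_global = np.zeros(q, dtype=np.int8)
    best_global[candidate_ids[best_local.astype(bool)]] = 1
    return TaskResult(task_id, best_global, lfits[0], trace, initial_best)


def run_multitask(tasks: TaskCollection, ds_train: FeatureDataset, config: GWOConfig,
                  p_prime: np.ndarray) -> MultiTaskResult:
    """Run all tasks sequentially, sharing knowledge, and aggregate the bests.

    The aggregated mask keeps features selected by a strict majority of
    task bests (``aggregate="majority"``, falling back to the best task's
    mask if the majority set is empty), the single best task's mask
    (``"best"``), or the union of all task bests (``"union"``).
    """
    q = ds_train.n_features
    kb = KnowledgeBase.empty(q)
    rng = np.random.default_rng(config.seed)
    results = []
    for i in range(tasks.n_tasks):
        res = run_gwo_task(tasks.masks[i], ds_train, kb, config, p_prime,
                           task_id=i, rng=rng)
        kb.record(res.best_mask)
        results.append(res)

    stack = np.array([r.best_mask for r in results])
    freq = stack.mean(axis=0)
    n = tasks.n_tasks
    if config.aggregate == "majority":
        agg = (stack.sum(axis=0) > n / 2).astype(np.int8)
        if not agg.any():
            agg = max(results, key=lambda r: r.best_fitness).best_mask.copy()
    elif config.aggregate == "best":
        agg = max(results, key=lambda r: r.best_fitness).best_mask.copy()
    else:
        agg = (stack.sum(axis=0) > 0).astype(np.int8)
    return MultiTaskResult(results, agg, freq, kb)
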