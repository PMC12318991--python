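"""Model/Results facade tying the pipeline stages together.

:class:`MultiTaskSelection` is built from a :class:`~fcselect.data.FeatureDataset`
and configuration; ``fit()`` runs weighting -> knee stratification ->
task generation -> knowledge-transfer GWO -> aggregation -> margin-model
training, and returns a :class:`MultiTaskSelectionResults` that carries
the selected edges, fitness traces, the trained classifier, and hangs
cross-validation and counterfactual explanation off the fitted state.
"""

from __future__ import annotations

import dataclasses
import zlib

import numpy as np
import pandas as pd

from . import classify, counterfactual, gwo, weighting
from .data import FeatureDataset, ROIAtlas

__all__ = ["MultiTaskSelection", "MultiTaskSelectionResults", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) % (2**31)


class MultiTaskSelection:
    """Multi-task wrapper feature selection over edge features.

    Parameters mirror the method's knobs: the weighting mix ``alphas``
    (Fisher, MI, dispersion), the task count ``n_tasks``, and the GWO
    search budget/penalty in ``gwo_config``.
    """

    def __init__(self, dataset: FeatureDataset,
                 alphas: tuple[float, float, float] = (0.4, 0.4, 0.2),
                 n_bins: int = 10,
                 n_tasks: int = 8,
                 task_mode: str = "per_task_lambda",
                 gwo_config: gwo.GWOConfig | None = None,
                 svm_C: float = 1.0):
        dataset.require_both_classes()
        self.dataset = dataset
        self.alphas = tuple(alphas)
        self.n_bins = n_bins
        self.n_tasks = n_tasks
        self.task_mode = task_mode
        self.gwo_config = gwo_config or gwo.GWOConfig()
        self.svm_C = svm_C

    @classmethod
    def from_dataframe(cls, features: pd.DataFrame, labels: pd.Series,
                       n_rois: int, **kwargs) -> "MultiTaskSelection":
        from .data import edge_index_for
        ds = FeatureDataset(features.to_numpy(float), labels.to_numpy(int),
                            edge_index_for(n_rois), n_rois)
        return cls(ds, **kwargs)

    def select_mask(self, ds_train: FeatureDataset, seed: int) -> np.ndarray:
        """Run the full selection stack on a training split; return the mask."""
        table = weighting.compute_weight_table(ds_train, self.alphas, self.n_bins)
        _, p_prime = weighting.selection_probabilities(table)
        tasks = weighting.generate_tasks(
            p_prime, self.n_tasks, stage_seed(seed, "tasks"), self.task_mode)
        cfg = dataclasses.replace(self.gwo_config, seed=stage_seed(seed, "gwo"))
        mt = gwo.run_multitask(tasks, ds_train, cfg, p_prime)
        return mt.aggregated_mask

    def fit(self, seed: int = 0) -> "MultiTaskSelectionResults":
        ds = self.dataset
        table = weighting.compute_weight_table(ds, self.alphas, self.n_bins)
        knees = weighting.detect_knees(table.sorted_weights())
        _, p_prime = weighting.selection_probabilities(table)
        tasks = weighting.generate_tasks(
            p_prime, self.n_tasks, stage_seed(seed, "tasks"), self.task_mode)
        cfg = dataclasses.replace(self.gwo_config, seed=stage_seed(seed, "gwo"))
        mt = gwo.run_multitask(tasks, ds, cfg, p_prime)
        margin = classify.train_margin_model(ds, mt.aggregated_mask, C=self.svm_C)
        return MultiTaskSelectionResults(self, seed, table, knees, p_prime,
                                         tasks, mt, margin)


@dataclasses.dataclass
class MultiTaskSelectionResults:
    """Fitted state: weights, strata, task bests, selected edges, classifier."""

    model: MultiTaskSelection
    seed: int
    weight_table: weighting.FeatureWeightTable
    knees: weighting.KneePartition
    p_prime: np.ndarray
    tasks: weighting.TaskCollection
    multitask: gwo.MultiTaskResult
    margin_model: classify.MarginModel

    @property
    def selected_features(self) -> np.ndarray:
        return np.flatnonzero(self.multitask.aggregated_mask)

    def weights_frame(self) -> pd.DataFrame:
        ds = self.model.dataset
        atlas = ds.atlas or ROIAtlas.generic(ds.n_rois)
        t = self.weight_table
        rank = np.empty(t.n_features, dtype=int)
        rank[t.rank_order] = np.arange(1, t.n_features + 1)
        # strata are stored in rank order; map back to feature order
        strata = np.empty(t.n_features, dtype=object)
        strata[t.rank_order] = self.knees.strata
        return pd.DataFrame({
            "feature_id": np.arange(1, t.n_features + 1),
            "roi_a": [atlas.names[a] for a, _ in ds.edge_index],
            "roi_b": [atlas.names[b] for _, b in ds.edge_index],
            "fisher": t.fisher, "mutinfo": t.mutinfo, "stdev": t.stdev,
            "combined": t.combined, "rank": rank, "stratum": strata,
        })

    def selection_frame(self) -> pd.DataFrame:
        ds = self.model.dataset
        atlas = ds.atlas or ROIAtlas.generic(ds.n_rois)
        stack = np.array([r.best_mask for r in self.multitask.task_results])
        return pd.DataFrame({
            "feature_id": np.arange(1, ds.n_features + 1),
            "roi_a": [atlas.names[a] for a, _ in ds.edge_index],
            "roi_b": [atlas.names[b] for _, b in ds.edge_index],
            "selected": self.multitask.aggregated_mask,
            "frequency": self.multitask.selection_frequency,
            "tasks_selected": stack.sum(axis=0),
        })

    def trace_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.multitask.task_results:
            for it, f in enumerate(r.fitness_trace, start=1):
                rows.append((r.task_id + 1, it, f))
        return pd.DataFrame(rows, columns=["task_id", "iteration", "best_fitness"])

    def cross_validate(self, n_folds: int = 5, seed: int | None = None) -> classify.CVReport:
        """Leak-free nested CV of the whole pipeline on this model's dataset."""
        return classify.cross_validate_pipeline(
            self.model.dataset, self.model.select_mask,
            seed if seed is not None else stage_seed(self.seed, "cv"),
            n_folds=n_folds, C=self.model.svm_C)

    def explain(self, subject: int, config: counterfactual.CFConfig | None = None
                ) -> counterfactual.CounterfactualSet:
        """Generate diverse counterfactuals for one subject (row index)."""
        config = config or counterfactual.CFConfig(seed=stage_seed(self.seed, "cf"))
        ds = self.model.dataset
        c = ds.features[subject, self.selected_features]
        return counterfactual.generate_counterfactuals(
            self.margin_model, c, ds, config)

    def summary(self) -> str:
        ds = self.model.dataset
        mt = self.multitask
        k = int(mt.aggregated_mask.sum())
        knee1 = "-" if self.knees.knee1 is None else str(self.knees.knee1 + 1)
        knee2 = "-" if self.knees.knee2 is None else str(self.knees.knee2 + 1)
        lines = [
            "Multi-task GWO feature selection",
            "=" * 40,
            f"subjects: {ds.n_subjects} ({int(np.sum(ds.labels == 0))} patients / "
            f"{int(np.sum(ds.labels == 1))} controls)",
            f"ROIs: {ds.n_rois}   edge features: {ds.n_features}",
            f"weighting alphas: {self.model.alphas}",
            f"knee ranks: {knee1}, {knee2}",
            f"tasks: {self.tasks.n_tasks}   pack: {self.model.gwo_config.pack_size}"
            f"   t_max: {self.model.gwo_config.t_max}   rho: {self.model.gwo_config.rho}",
            f"selected features: {k} of {ds.n_features}",
            f"best task fitness: {mt.best_task.best_fitness:.4f}",
            "",
            "top selected edges (by task frequency):",
        ]
        sel = self.selection_frame()
        top = sel[sel.selected == 1].sort_values(
            ["frequency", "feature_id"], ascending=[False, True]).head(10)
        for _, row in top.iterrows():
            lines.append(f"  {row.roi_a} -- {row.roi_b}   freq {row.frequency:.2f}")
        return "\n".join(lines)
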