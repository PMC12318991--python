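"""Functional-connectivity data structures, file I/O, and synthetic cohorts.

A subject's resting-state signal is summarised as an N x N matrix of
pairwise Pearson correlations between region-of-interest (ROI) time
series.  Because the matrix is symmetric with unit diagonal, only the
q = N(N-1)/2 upper-triangular entries carry information; they are
vectorised row-major into the per-subject feature vector that every
downstream stage (weighting, selection, classification, counterfactuals)
consumes.

Real clinical cohorts are not redistributable, so :func:`synthesize_dataset`
builds surrogate two-class cohorts with a small planted set of
discriminative edges, which is what the test-suite and the worked
examples run on.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROIAtlas",
    "ConnectivityMatrix",
    "FeatureDataset",
    "SyntheticSpec",
    "compute_fc_matrix",
    "vectorize_upper",
    "devectorize",
    "edge_index_for",
    "load_dataset",
    "save_dataset",
    "synthesize_dataset",
]

_SYMMETRY_TOL = 1e-10


@dataclasses.dataclass(frozen=True)
class ROIAtlas:
    """Ordered list of ROI labels defining node identity and edge names."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise ValueError("an atlas needs at least 2 ROIs")
        if len(set(self.names)) != len(self.names):
            raise ValueError("ROI names must be unique")

    @classmethod
    def generic(cls, n_rois: int) -> "ROIAtlas":
        return cls(tuple(f"ROI{i + 1:03d}" for i in range(n_rois)))

    @classmethod
    def from_file(cls, path: str | Path) -> "ROIAtlas":
        names = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        return cls(tuple(names))

    @property
    def n_rois(self) -> int:
        return len(self.names)


@dataclasses.dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric ROI x ROI connectivity (correlation) matrix."""

    values: np.ndarray
    n_rois: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if v.shape[0] != self.n_rois:
            raise ValueError("n_rois does not match matrix shape")
        if not np.allclose(v, v.T, atol=_SYMMETRY_TOL, rtol=0):
            raise ValueError("connectivity matrix is not symmetric")
        object.__setattr__(self, "values", v)


@dataclasses.dataclass
class FeatureDataset:
    """Subjects x edge-features design matrix with binary labels.

    Labels follow the clinical coding 0 = patient, 1 = control.
    ``edge_index`` maps feature column j to the unordered ROI pair it
    measures, in row-major upper-triangle order.
    """

    features: np.ndarray           # (p, q)
    labels: np.ndarray             # (p,) in {0, 1}
    edge_index: list[tuple[int, int]]
    n_rois: int
    atlas: ROIAtlas | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        p, q = self.features.shape
        n = self.n_rois
        if q != n * (n - 1) // 2:
            raise ValueError(f"q={q} incompatible with N={n} (expect N(N-1)/2)")
        if self.labels.shape != (p,):
            raise ValueError("labels length must equal number of subjects")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be coded 0 (patient) / 1 (control)")
        if len(self.edge_index) != q:
            raise ValueError("edge_index length must equal q")

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def require_both_classes(self) -> None:
        present = set(np.unique(self.labels))
        if present != {0, 1}:
            raise ValueError(f"both classes required, found labels {sorted(present)}")

    def subset(self, rows: np.ndarray) -> "FeatureDataset":
        return FeatureDataset(
            self.features[rows], self.labels[rows], list(self.edge_index),
            self.n_rois, self.atlas,
        )


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a surrogate two-class connectome cohort.

    ``planted_edges`` edges get a mean shift of ``effect_size`` in the
    patient class (label 0); all remaining edges are class-identical
    noise, so the planted set is the full ground-truth signal.
    """

    n_rois: int = 20
    n_per_class: tuple[int, int] = (40, 40)
    planted_edges: int = 5
    effect_size: float = 1.5
    noise_sd: float = 0.3
    mode: Literal["features", "timeseries"] = "features"
    timeseries_length: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        q = self.n_rois * (self.n_rois - 1) // 2
        if self.planted_edges > q:
            raise ValueError(f"planted_edges={self.planted_edges} exceeds q={q}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")

    @property
    def n_edges(self) -> int:
        return self.n_rois * (self.n_rois - 1) // 2


def edge_index_for(n_rois: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle pair list: (0,1), (0,2), ..., (N-2,N-1)."""
    return [(a, b) for a in range(n_rois) for b in range(a + 1, n_rois)]


def compute_fc_matrix(timeseries: np.ndarray, atlas: ROIAtlas | None = None) -> ConnectivityMatrix:
    """Pearson-correlation functional connectivity from a T x N series.

    Raises on fewer than 3 time points or a constant ROI column (the
    correlation would be undefined); the error names the offending ROI.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a T x N matrix")
    t_len, n = ts.shape
    if t_len < 3:
        raise ValueError(f"need at least 3 time points, got {t_len}")
    sds = ts.std(axis=0)
    const = np.flatnonzero(sds == 0)
    if const.size:
        name = atlas.names[const[0]] if atlas is not None else f"column {const[0]}"
        raise ValueError(f"constant time series for ROI {name}; correlation undefined")
    r = np.corrcoef(ts, rowvar=False)
    # corrcoef can drift off exact symmetry/unit diagonal by float noise
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, n)


def vectorize_upper(cm: ConnectivityMatrix) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Upper-triangle entries in row-major order plus the pair index."""
    n = cm.n_rois
    iu = np.triu_indices(n, k=1)
    return cm.values[iu].copy(), edge_index_for(n)


def devectorize(v: np.ndarray, n_rois: int) -> ConnectivityMatrix:
    """Inverse of :func:`vectorize_upper`; unit diagonal imposed."""
    v = np.asarray(v, dtype=float)
    q = n_rois * (n_rois - 1) // 2
    if v.shape != (q,):
        raise ValueError(f"edge vector length {v.shape} incompatible with N={n_rois} (expect {q})")
    m = np.eye(n_rois)
    iu = np.triu_indices(n_rois, k=1)
    m[iu] = v
    m[(iu[1], iu[0])] = v
    return ConnectivityMatrix(m, n_rois)


def _read_matrix(path: Path) -> np.ndarray:
    sep = "," if path.suffix.lower() == ".csv" else r"\s+"
    return pd.read_csv(path, sep=sep, header=None).to_numpy(dtype=float)


def load_dataset(
    subject_table: str | Path,
    data_dir: str | Path,
    mode: Literal["matrix", "timeseries"] = "matrix",
    atlas: ROIAtlas | None = None,
) -> FeatureDataset:
    """Assemble a :class:`FeatureDataset` from per-subject delimited files.

    ``subject_table`` is a TSV with columns ``subject_id`` and ``label``;
    each ``subject_id`` names a file under ``data_dir`` holding either an
    N x N connectivity matrix or a T x N time-series table.
    """
    table = pd.read_csv(subject_table, sep="\t")
    missing = {"subject_id", "label"} - set(table.columns)
    if missing:
        raise ValueError(f"subject table lacks columns: {sorted(missing)}")
    data_dir = Path(data_dir)

    labels = []
    for raw in table["label"]:
        lab = _coerce_label(raw)
        labels.append(lab)

    rows, n_ref, bad = [], None, []
    for sid in table["subject_id"].astype(str):
        matches = sorted(data_dir.glob(f"{sid}.*")) or [data_dir / sid]
        path = matches[0]
        if not path.exists():
            raise FileNotFoundError(f"no data file for subject {sid} in {data_dir}")
        arr = _read_matrix(path)
        if mode == "timeseries":
            cm = compute_fc_matrix(arr, atlas)
        else:
            cm = ConnectivityMatrix(arr, arr.shape[0])
        if n_ref is None:
            n_ref = cm.n_rois
        if cm.n_rois != n_ref:
            bad.append(f"{path.name} (N={cm.n_rois})")
            continue
        rows.append(vectorize_upper(cm)[0])
    if bad:
        raise ValueError(f"inconsistent ROI count (expected N={n_ref}): {', '.join(bad)}")

    return FeatureDataset(
        np.vstack(rows), np.array(labels), edge_index_for(n_ref), n_ref, atlas
    )


def _coerce_label(raw: object) -> int:
    mapping = {"0": 0, "1": 1, "patient": 0, "sz": 0, "control": 1, "nc": 1, "hc": 1}
    key = str(raw).strip().lower()
    if key not in mapping:
        raise ValueError(f"unknown label value {raw!r}; expected 0/1, patient/control, SZ/NC")
    return mapping[key]


def save_dataset(ds: FeatureDataset, out_dir: str | Path, manifest_extra: dict | None = None) -> Path:
    """Write a dataset bundle: features.tsv, labels.tsv, edge_index.tsv, manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "features.tsv", ds.features, delimiter="\t", fmt="%.17g")
    np.savetxt(out / "labels.tsv", ds.labels, delimiter="\t", fmt="%d")
    names = ds.atlas.names if ds.atlas else ROIAtlas.generic(ds.n_rois).names
    with open(out / "edge_index.tsv", "w") as fh:
        fh.write("edge_id\troi_a\troi_b\n")
        for j, (a, b) in enumerate(ds.edge_index):
            fh.write(f"{j + 1}\t{names[a]}\t{names[b]}\n")
    manifest = {"n_rois": ds.n_rois, "n_subjects": ds.n_subjects,
                "n_features": ds.n_features, "roi_names": list(names)}
    manifest.update(manifest_extra or {})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def load_dataset_bundle(bundle_dir: str | Path) -> FeatureDataset:
    """Read back a bundle written by :func:`save_dataset`."""
    d = Path(bundle_dir)
    feats = np.loadtxt(d / "features.tsv", delimiter="\t", ndmin=2)
    labels = np.loadtxt(d / "labels.tsv", dtype=int, ndmin=1)
    manifest = json.loads((d / "manifest.json").read_text())
    n = int(manifest["n_rois"])
    atlas = ROIAtlas(tuple(manifest["roi_names"])) if "roi_names" in manifest else None
    return FeatureDataset(feats, labels, edge_index_for(n), n, atlas)


def synthesize_dataset(spec: SyntheticSpec) -> tuple[FeatureDataset, np.ndarray]:
    """Generate a surrogate cohort and return it with the planted edge ids.

    ``features`` mode draws every edge i.i.d. Normal(0, noise_sd^2) and adds
    ``effect_size`` to the planted edges of patients (label 0) only.
    ``timeseries`` mode builds per-class multivariate-normal ROI series whose
    population correlation differs by about ``effect_size`` on planted edges
    and passes them through :func:`compute_fc_matrix`.  Deterministic in
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    q = spec.n_edges
    n0, n1 = spec.n_per_class
    planted = np.sort(rng.choice(q, size=spec.planted_edges, replace=False))
    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])

    if spec.mode == "features":
        feats = rng.normal(0.0, spec.noise_sd, size=(n0 + n1, q))
        feats[:n0, planted] += spec.effect_size
    else:
        feats = _timeseries_features(spec, planted, rng, n0, n1)

    ds = FeatureDataset(feats, labels, edge_index_for(spec.n_rois), spec.n_rois,
                        ROIAtlas.generic(spec.n_rois))
    return ds, planted


def _timeseries_features(spec: SyntheticSpec, planted: np.ndarray,
                         rng: np.random.Generator, n0: int, n1: int) -> np.ndarray:
    """Simulate per-class MVN ROI series and correlate them.

    Patients get extra shared-factor coupling on planted ROI pairs so their
    population correlation on those edges exceeds the control value by
    roughly ``effect_size`` (capped below 1).
    """
    n = spec.n_rois
    pairs = [edge_index_for(n)[j] for j in planted]
    rho = min(0.95, spec.effect_size)  # target correlation bump on planted edges
    rows = []
    for lab, count in ((0, n0), (1, n1)):
        for _ in range(count):
            ts = rng.normal(size=(spec.timeseries_length, n))
            if lab == 0 and rho > 0:
                for a, b in pairs:
                    shared = rng.normal(size=spec.timeseries_length)
                    w = np.sqrt(rho)
                    ts[:, a] = w * shared + np.sqrt(1 - rho) * ts[:, a]
                    ts[:, b] = w * shared + np.sqrt(1 - rho) * ts[:, b]
            cm = compute_fc_matrix(ts)
            rows.append(vectorize_upper(cm)[0])
    return np.vstack(rows)
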