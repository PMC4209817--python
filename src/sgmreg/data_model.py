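"""Containers and I/O for multi-study omics collections.

A *study collection* holds ``T`` independent datasets collected at ``K``
omics levels (e.g. SNP genotypes and gene expression), each with its own
subjects.  Features in every dataset are annotated to a shared gene
universe; genes define the (non-overlapping) groups used by the sparse
group penalties and the gene-level association test.

On-disk formats are plain text: feature matrices and phenotypes are
tab-separated tables, the feature-to-gene annotation is a three-column
TSV, and the study manifest is a small YAML document.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsDataset",
    "StudyCollection",
    "GeneGroupIndex",
    "CoefficientStack",
    "normalize_features",
    "platform_weights",
    "build_collection",
    "build_gene_index",
    "load_study_collection",
    "write_study_collection",
]


def normalize_features(X: np.ndarray, return_params: bool = False, *,
                       feature_ids: Sequence[str] | None = None,
                       allow_constant: bool = False):
    """Standardize every column to zero mean and unit standard deviation.

    Uses the sample convention (``ddof=1``).  Constant columns are an
    error (they carry no signal and break the scaling) unless
    ``allow_constant`` is set, in which case they are centered and left
    at unit scale — used internally by cross-validation refits where a
    rare fold may make a low-frequency genotype column constant.

    Returns the standardized matrix, and ``(means, sds)`` when
    ``return_params`` so held-out samples can be mapped through the same
    transformation.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values; "
                         "missing entries are not supported")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    const = sds <= 0
    if const.any():
        if not allow_constant:
            idx = int(np.flatnonzero(const)[0])
            name = feature_ids[idx] if feature_ids is not None else f"column {idx}"
            raise ValueError(f"constant feature cannot be normalized: {name}")
        sds = np.where(const, 1.0, sds)
    Z = (X - means) / sds
    if return_params:
        return Z, (means, sds)
    return Z


def platform_weights(sample_sizes: Sequence[int]) -> np.ndarray:
    """Sample-size weights ``delta_j = n_j / sum(n)`` for one omics level.

    Larger studies get proportionally more weight in the multitask loss;
    the weights across all platforms of one level sum to one.
    """
    n = np.asarray(sample_sizes, dtype=float)
    if n.size == 0:
        raise ValueError("need at least one dataset per level")
    if np.any(n < 1):
        raise ValueError("sample sizes must be >= 1")
    return n / n.sum()


@dataclass
class OmicsDataset:
    """One study: a feature matrix, a phenotype, and its weighting labels.

    ``X`` is stored column-standardized.  ``feature_genes`` gives the gene
    each column is annotated to (parallel to ``feature_ids``).
    """

    dataset_id: str
    level: int
    platform: int
    X: np.ndarray
    Y: np.ndarray
    feature_ids: list[str]
    feature_genes: list[str]
    sample_ids: list[str] | None = None
    level_weight: float = 1.0      # omega_k
    platform_weight: float = 1.0   # delta_j

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"{self.dataset_id}: X has {self.X.shape[0]} rows but Y has "
                f"{self.Y.shape[0]} entries")
        if self.X.shape[1] != len(self.feature_ids):
            raise ValueError(f"{self.dataset_id}: feature_ids length mismatch")
        if len(self.feature_genes) != len(self.feature_ids):
            raise ValueError(f"{self.dataset_id}: feature_genes length mismatch")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError(f"{self.dataset_id}: duplicate feature ids")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def loss_weight(self) -> float:
        """Combined task weight omega_k * delta_j in the multitask loss."""
        return self.level_weight * self.platform_weight


@dataclass
class StudyCollection:
    """An ordered list of datasets sharing one gene universe."""

    datasets: list[OmicsDataset]

    def __post_init__(self):
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate dataset ids in collection")

    @property
    def n_tasks(self) -> int:
        return len(self.datasets)

    @property
    def levels(self) -> list[int]:
        return sorted({d.level for d in self.datasets})

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def total_dim(self) -> int:
        return sum(d.n_features for d in self.datasets)

    @property
    def task_offsets(self) -> np.ndarray:
        """Start position of each dataset's block in the stacked vector."""
        dims = [d.n_features for d in self.datasets]
        return np.concatenate([[0], np.cumsum(dims)[:-1]]).astype(int)

    def subset(self, level: int | None = None,
               dataset_ids: Sequence[str] | None = None) -> "StudyCollection":
        """A new collection restricted by level or explicit ids.

        Platform weights are recomputed within the surviving levels.
        """
        kept = [d for d in self.datasets
                if (level is None or d.level == level)
                and (dataset_ids is None or d.dataset_id in set(dataset_ids))]
        if not kept:
            raise ValueError("subset selects no datasets")
        import copy
        kept = [copy.copy(d) for d in kept]
        _assign_platform_weights(kept)
        return StudyCollection(kept)


def _assign_platform_weights(datasets: list[OmicsDataset]) -> None:
    for lev in sorted({d.level for d in datasets}):
        members = [d for d in datasets if d.level == lev]
        w = platform_weights([d.n_samples for d in members])
        for d, wj in zip(members, w):
            d.platform_weight = float(wj)


@dataclass
class GeneGroupIndex:
    """Maps genes to feature positions, per dataset and in the stacked vector.

    Each gene forms one group spanning all tasks: its stacked index set
    concatenates its column positions across every dataset.  Groups are
    non-overlapping and cover every feature of every dataset.
    """

    gene_ids: list[str]
    membership: dict[tuple[str, str], np.ndarray]   # (gene, dataset_id) -> cols
    stacked_slices: dict[str, np.ndarray]           # gene -> stacked indices
    total_dim: int

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def validate_partition(self) -> None:
        """Assert groups partition the stacked coefficient index set."""
        all_idx = np.concatenate([self.stacked_slices[g] for g in self.gene_ids])
        if len(all_idx) != self.total_dim or len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("gene groups do not partition the stacked vector")
        if all_idx.min() != 0 or all_idx.max() != self.total_dim - 1:
            raise ValueError("gene groups do not cover the stacked vector")


def build_gene_index(collection: StudyCollection) -> GeneGroupIndex:
    """Build the gene grouping from each dataset's per-column gene labels."""
    offsets = collection.task_offsets
    gene_ids: list[str] = []
    seen = set()
    for d in collection.datasets:
        for g in d.feature_genes:
            if g not in seen:
                seen.add(g)
                gene_ids.append(g)
    membership: dict[tuple[str, str], np.ndarray] = {}
    stacked: dict[str, list[int]] = {g: [] for g in gene_ids}
    for off, d in zip(offsets, collection.datasets):
        genes = np.asarray(d.feature_genes)
        for g in np.unique(genes):
            cols = np.flatnonzero(genes == g)
            membership[(str(g), d.dataset_id)] = cols
            stacked[str(g)].extend((off + cols).tolist())
    slices = {g: np.asarray(v, dtype=int) for g, v in stacked.items()}
    idx = GeneGroupIndex(gene_ids=gene_ids, membership=membership,
                         stacked_slices=slices, total_dim=collection.total_dim)
    idx.validate_partition()
    return idx


@dataclass
class CoefficientStack:
    """The stacked multitask coefficient vector with per-task views."""

    values: np.ndarray
    task_offsets: np.ndarray
    task_dims: np.ndarray
    dataset_ids: list[str]

    @classmethod
    def zeros(cls, collection: StudyCollection) -> "CoefficientStack":
        dims = np.array([d.n_features for d in collection.datasets])
        return cls(values=np.zeros(int(dims.sum())),
                   task_offsets=collection.task_offsets,
                   task_dims=dims,
                   dataset_ids=[d.dataset_id for d in collection.datasets])

    def task_view(self, i: int) -> np.ndarray:
        off, dim = int(self.task_offsets[i]), int(self.task_dims[i])
        return self.values[off:off + dim]

    def gene_task_view(self, gene: str, i: int,
                       groups: GeneGroupIndex) -> np.ndarray:
        """Gene ``gene``'s coefficients within task ``i`` (may be empty)."""
        key = (gene, self.dataset_ids[i])
        cols = groups.membership.get(key)
        if cols is None or len(cols) == 0:
            return np.empty(0)
        return self.task_view(i)[cols]

    def copy(self) -> "CoefficientStack":
        return CoefficientStack(self.values.copy(), self.task_offsets,
                                self.task_dims, list(self.dataset_ids))


def build_collection(datasets: list[OmicsDataset], *,
                     normalize: bool = True) -> StudyCollection:
    """Assemble a collection: standardize features, set platform weights."""
    for d in datasets:
        if normalize:
            d.X = normalize_features(d.X, feature_ids=d.feature_ids)
        if not np.all(np.isfinite(d.Y)):
            raise ValueError(f"{d.dataset_id}: non-finite phenotype values")
    _assign_platform_weights(datasets)
    return StudyCollection(datasets)


# ---------------------------------------------------------------------------
# On-disk formats


def _read_feature_matrix(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns], \
        [str(i) for i in df.index]


def _read_phenotype(path: Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise ValueError(f"phenotype file {path} must have two columns "
                         "(sample_id, value)")
    return pd.Series(df.iloc[:, 1].to_numpy(dtype=float),
                     index=df.iloc[:, 0].astype(str))


def load_study_collection(manifest_path, annotation_path):
    """Load a study collection and its gene index from disk.

    The manifest is YAML with a top-level ``datasets`` list; each entry
    has ``dataset_id``, ``level``, ``platform``, ``X_path`` and
    ``Y_path`` (paths relative to the manifest).  The annotation is a
    three-column TSV (feature_id, dataset_id, gene_id).  Features with
    no annotation are dropped with a logged count; duplicate
    (feature_id, dataset_id) pairs are fatal.

    Returns ``(StudyCollection, GeneGroupIndex)``.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    if not manifest or "datasets" not in manifest:
        raise ValueError("manifest must contain a 'datasets' list")

    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    ann.columns = [c.lower() for c in ann.columns]
    required = {"feature_id", "dataset_id", "gene_id"}
    if not required.issubset(ann.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    if ann.duplicated(["feature_id", "dataset_id"]).any():
        dup = ann[ann.duplicated(["feature_id", "dataset_id"])].iloc[0]
        raise ValueError("duplicate annotation for feature "
                         f"{dup['feature_id']} in dataset {dup['dataset_id']}")
    ann_map = {(r.feature_id, r.dataset_id): r.gene_id
               for r in ann.itertuples(index=False)}

    base = manifest_path.parent
    datasets = []
    for entry in manifest["datasets"]:
        did = str(entry["dataset_id"])
        X, feat_ids, sample_ids = _read_feature_matrix(base / entry["X_path"])
        pheno = _read_phenotype(base / entry["Y_path"])
        try:
            Y = pheno.loc[sample_ids].to_numpy()
        except KeyError as exc:
            raise ValueError(f"{did}: phenotype missing for some samples") from exc
        keep, genes = [], []
        for j, f in enumerate(feat_ids):
            g = ann_map.get((f, did))
            if g is None:
                continue
            keep.append(j)
            genes.append(g)
        dropped = len(feat_ids) - len(keep)
        if dropped:
            logger.warning("%s: dropping %d unannotated feature(s)", did, dropped)
        if not keep:
            raise ValueError(f"{did}: no annotated features remain")
        datasets.append(OmicsDataset(
            dataset_id=did, level=int(entry["level"]),
            platform=int(entry.get("platform", 0)),
            X=X[:, keep], Y=Y,
            feature_ids=[feat_ids[j] for j in keep],
            feature_genes=genes, sample_ids=sample_ids,
            level_weight=float(entry.get("level_weight", 1.0))))
    collection = build_collection(datasets)
    groups = build_gene_index(collection)
    return collection, groups


def write_study_collection(collection: StudyCollection, out_dir, *,
                           manifest_name: str = "manifest.yaml",
                           annotation_name: str = "annotation.tsv") -> Path:
    """Write matrices, phenotypes, annotation and manifest to ``out_dir``.

    Matrices are written as loaded/stored (standardized); loading the
    result reproduces the collection (standardization is idempotent up
    to floating error).  Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries, ann_rows = [], []
    for d in collection.datasets:
        samples = d.sample_ids or [f"s{i}" for i in range(d.n_samples)]
        xp, yp = f"{d.dataset_id}_X.tsv", f"{d.dataset_id}_Y.tsv"
        pd.DataFrame(d.X, index=samples, columns=d.feature_ids).to_csv(
            out / xp, sep="\t", index_label="sample_id")
        pd.DataFrame({"sample_id": samples, "value": d.Y}).to_csv(
            out / yp, sep="\t", index=False)
        entries.append({"dataset_id": d.dataset_id, "level": d.level,
                        "platform": d.platform, "X_path": xp, "Y_path": yp,
                        "level_weight": d.level_weight})
        for f, g in zip(d.feature_ids, d.feature_genes):
            ann_rows.append((f, d.dataset_id, g))
    pd.DataFrame(ann_rows, columns=["feature_id", "dataset_id", "gene_id"]) \
        .to_csv(out / annotation_name, sep="\t", index=False)
    manifest_path = out / manifest_name
    with open(manifest_path, "w") as fh:
        yaml.safe_dump({"datasets": entries}, fh, sort_keys=False)
    return manifest_path
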