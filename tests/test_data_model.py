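import numpy as np
import pandas as pd
import pytest

from sgmreg.data_model import (CoefficientStack, OmicsDataset,
                               build_collection, build_gene_index,
                               load_study_collection, normalize_features,
                               platform_weights, write_study_collection)


def make_dataset(did="d0", level=0, n=8, d=4, seed=0, genes=None):
    rng = np.random.default_rng(seed)
    return OmicsDataset(
        dataset_id=did, level=level, platform=0,
        X=rng.standard_normal((n, d)), Y=rng.standard_normal(n),
        feature_ids=[f"{did}_f{j}" for j in range(d)],
        feature_genes=genes or [f"g{j % 2}" for j in range(d)])


@pytest.mark.parametrize("sizes,expected", [
    ((600, 400, 200), (0.5, 1 / 3, 1 / 6)),
    ((30,), (1.0,)),
    ((50, 50), (0.5, 0.5)),
    ((600, 200), (0.75, 0.25)),
])
def test_platform_weights(sizes, expected):
    np.testing.assert_allclose(platform_weights(sizes), expected)


def test_platform_weights_empty_is_error():
    with pytest.raises(ValueError):
        platform_weights([])


def test_normalize_features_basic():
    Z = normalize_features(np.array([[1.0], [2.0], [3.0]]))
    # sample-sd convention (ddof=1)
    np.testing.assert_allclose(Z.ravel(), [-1.0, 0.0, 1.0])
    assert abs(Z.mean()) < 1e-12


def test_normalize_is_idempotent():
    rng = np.random.default_rng(1)
    Z = normalize_features(rng.standard_normal((20, 5)))
    np.testing.assert_allclose(normalize_features(Z), Z, atol=1e-12)


def test_normalize_rejects_constant_column_by_name():
    X = np.column_stack([np.arange(4.0), np.zeros(4)])
    with pytest.raises(ValueError, match="snpB"):
        normalize_features(X, feature_ids=["snpA", "snpB"])


def test_normalize_rejects_missing_values():
    X = np.array([[1.0, np.nan], [2.0, 3.0], [0.0, 1.0]])
    with pytest.raises(ValueError, match="non-finite"):
        normalize_features(X)


def test_collection_weights_and_index():
    ds = [make_dataset("a", 0, n=12, seed=1), make_dataset("b", 0, n=4, seed=2),
          make_dataset("c", 1, n=6, seed=3)]
    col = build_collection(ds)
    assert col.n_tasks == 3 and col.n_levels == 2
    np.testing.assert_allclose(
        [d.platform_weight for d in col.datasets], [0.75, 0.25, 1.0])
    groups = build_gene_index(col)
    groups.validate_partition()
    assert sum(len(groups.stacked_slices[g]) for g in groups.gene_ids) \
        == col.total_dim


def test_coefficient_stack_views():
    ds = [make_dataset("a", 0, d=4, seed=1), make_dataset("b", 1, d=3, seed=2,
          genes=["g0", "g1", "g0"])]
    col = build_collection(ds)
    groups = build_gene_index(col)
    C = CoefficientStack.zeros(col)
    C.values[:] = np.arange(7.0)
    np.testing.assert_allclose(C.task_view(1), [4, 5, 6])
    np.testing.assert_allclose(C.gene_task_view("g0", 1, groups), [4, 6])
    # stacked gene slice equals concatenation of per-task views
    stacked = C.values[groups.stacked_slices["g0"]]
    manual = np.concatenate([C.gene_task_view("g0", 0, groups),
                             C.gene_task_view("g0", 1, groups)])
    np.testing.assert_allclose(np.sort(stacked), np.sort(manual))


def test_roundtrip_write_load(tmp_path):
    ds = [make_dataset("a", 0, n=10, seed=1), make_dataset("b", 1, n=6, seed=2)]
    col = build_collection(ds)
    manifest = write_study_collection(col, tmp_path)
    loaded, groups = load_study_collection(manifest, tmp_path / "annotation.tsv")
    assert loaded.n_tasks == 2
    for orig, new in zip(col.datasets, loaded.datasets):
        np.testing.assert_allclose(new.X, orig.X, atol=1e-12)
        np.testing.assert_allclose(new.Y, orig.Y, atol=1e-12)
        assert new.feature_genes == orig.feature_genes
    deltas = {}
    for d in loaded.datasets:
        deltas.setdefault(d.level, 0.0)
        deltas[d.level] += d.platform_weight
    assert all(abs(v - 1) < 1e-12 for v in deltas.values())


def test_load_drops_unannotated_and_rejects_duplicates(tmp_path):
    ds = [make_dataset("a", 0, n=6, seed=5)]
    col = build_collection(ds)
    write_study_collection(col, tmp_path)
    ann = pd.read_csv(tmp_path / "annotation.tsv", sep="\t")
    # drop the annotation of one feature -> it is dropped with a warning
    ann.iloc[1:].to_csv(tmp_path / "annotation.tsv", sep="\t", index=False)
    loaded, _ = load_study_collection(tmp_path / "manifest.yaml",
                                      tmp_path / "annotation.tsv")
    assert loaded.datasets[0].n_features == col.datasets[0].n_features - 1
    # duplicated (feature_id, dataset_id) is fatal
    dup = pd.concat([ann, ann.iloc[[0]]])
    dup.to_csv(tmp_path / "annotation.tsv", sep="\t", index=False)
    with pytest.raises(ValueError, match="duplicate"):
        load_study_collection(tmp_path / "manifest.yaml",
                              tmp_path / "annotation.tsv")


def test_missing_file_is_fatal(tmp_path):
    with pytest.raises(FileNotFoundError):
        load_study_collection(tmp_path / "nope.yaml", tmp_path / "ann.tsv")


def test_subset_recomputes_weights():
    ds = [make_dataset("a", 0, n=12, seed=1), make_dataset("b", 0, n=4, seed=2),
          make_dataset("c", 1, n=6, seed=3)]
    col = build_collection(ds)
    sub = col.subset(level=0)
    assert [d.dataset_id for d in sub.datasets] == ["a", "b"]
    np.testing.assert_allclose([d.platform_weight for d in sub.datasets],
                               [0.75, 0.25])
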