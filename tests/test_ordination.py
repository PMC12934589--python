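import itertools

import numpy as np
import pandas as pd
import pytest

import oralpair as op
from oralpair.ordination import (
    DistanceMatrix,
    distance_matrix,
    hierarchical_cluster,
    ordination_sweep,
    pcoa,
    silhouette_by_group,
    spearman_axis_vs_library,
)
from oralpair.transforms import AbundanceMatrix, tss


def _am(values, transform="raw"):
    values = np.asarray(values, dtype=float)
    return AbundanceMatrix(
        values,
        [f"t{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        transform,
    )


def _dm(values):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix([f"s{j}" for j in range(values.shape[0])], values, "euclidean")


def test_distance_examples():
    identical = _am([[1, 1], [2, 2]])
    for metric in ("bray_curtis", "jaccard", "euclidean"):
        assert distance_matrix(identical, metric).values[0, 1] == pytest.approx(0.0)
    disjoint = _am([[1, 0], [0, 1]])
    assert distance_matrix(disjoint, "bray_curtis").values[0, 1] == pytest.approx(1.0)
    assert distance_matrix(disjoint, "jaccard").values[0, 1] == pytest.approx(1.0)
    hand = _am([[2, 1], [2, 3]])
    assert distance_matrix(hand, "bray_curtis").values[0, 1] == pytest.approx(0.25)


def test_distance_invariants_and_errors():
    rng = np.random.default_rng(0)
    am = _am(rng.integers(0, 20, size=(10, 6)))
    for metric in ("bray_curtis", "jaccard", "euclidean"):
        d = distance_matrix(am, metric).values
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        assert np.all(np.diag(d) == 0)
        if metric != "euclidean":
            assert d.min() >= 0 and d.max() <= 1
    with pytest.raises(ValueError, match="all-zero pair"):
        distance_matrix(_am([[0, 0, 1], [0, 0, 2]]), "bray_curtis")
    with pytest.raises(ValueError, match="non-negative"):
        distance_matrix(_am([[-1, 1]]), "bray_curtis")


def test_pcoa_two_points():
    d = np.array([[0.0, 3.0], [3.0, 0.0]])
    res = pcoa(_dm(d), n_axes=1)
    np.testing.assert_allclose(np.abs(res.coordinates[:, 0]), 1.5, atol=1e-12)
    assert res.coordinates[:, 0].sum() == pytest.approx(0.0, abs=1e-12)


def test_pcoa_equals_pca_on_euclidean_distances():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(12, 5))
    Xc = X - X.mean(axis=0)
    am = AbundanceMatrix(Xc.T, [f"t{i}" for i in range(5)], [f"s{j}" for j in range(12)], "raw")
    d = distance_matrix(am, "euclidean")
    res = pcoa(d, n_axes=3)
    # PCA scores via SVD
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * S
    for j in range(3):
        a, b = res.coordinates[:, j], scores[:, j]
        assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8


def test_pcoa_matches_skbio():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(2)
    am = _am(rng.integers(1, 50, size=(15, 8)))
    d = distance_matrix(tss(op.CountTable(am.taxa, am.samples, am.values.astype(int))), "bray_curtis")
    res = pcoa(d, n_axes=2)
    ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d.values, ids=d.samples))
    ref_coords = ref.samples.to_numpy()[:, :2]
    for j in range(2):
        a, b = res.coordinates[:, j], ref_coords[:, j]
        assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8


def test_pcoa_collinear_points_single_positive_eigenvalue():
    pts = np.array([0.0, 1.0, 3.0])
    D = np.abs(pts[:, None] - pts[None, :])
    res = pcoa(_dm(D), n_axes=2)
    pos = res.eigenvalues > 1e-10
    assert pos.sum() == 1
    assert res.percent_variance[0] == pytest.approx(100.0)
    assert res.truncated


def test_pcoa_reproduces_distances():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(9, 4))
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    res = pcoa(_dm(D), n_axes=9)
    C = res.coordinates
    D2 = np.sqrt(((C[:, None, :] - C[None, :, :]) ** 2).sum(-1))
    np.testing.assert_allclose(D2, D, atol=1e-8)


def _direct_silhouette(D, labels):
    labels = np.array(labels)
    out = {}
    svals = np.zeros(len(labels))
    for i in range(len(labels)):
        own = labels == labels[i]
        if own.sum() == 1:
            svals[i] = 0.0
            continue
        a = D[i, own].sum() / (own.sum() - 1)
        b = min(D[i, labels == g].mean() for g in set(labels) if g != labels[i])
        svals[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    for g in set(labels):
        out[g] = float(np.median(svals[labels == g]))
    return out


def test_silhouette_hand_example_and_degenerate():
    # two groups: within-distance 0.1, between 10 -> s = 9.9/10 = 0.99
    D = np.array(
        [
            [0, 0.1, 10, 10],
            [0.1, 0, 10, 10],
            [10, 10, 0, 0.1],
            [10, 10, 0.1, 0],
        ]
    )
    d = _dm(D)
    sil = silhouette_by_group(d, {"s0": "a", "s1": "a", "s2": "b", "s3": "b"})
    assert sil["a"] == pytest.approx(0.99) and sil["b"] == pytest.approx(0.99)
    coincident = _dm(np.zeros((4, 4)))
    sil0 = silhouette_by_group(coincident, {"s0": "a", "s1": "a", "s2": "b", "s3": "b"})
    assert sil0 == {"a": 0.0, "b": 0.0}
    with pytest.raises(ValueError):
        silhouette_by_group(d, {s: "same" for s in d.samples})


def test_silhouette_matches_direct_definition_and_sklearn():
    from sklearn.metrics import silhouette_samples

    rng = np.random.default_rng(4)
    X = rng.normal(size=(20, 3))
    labels = ["a"] * 8 + ["b"] * 7 + ["c"] * 5
    D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    d = DistanceMatrix([f"s{i}" for i in range(20)], D, "euclidean")
    ours = silhouette_by_group(d, dict(zip(d.samples, labels)))
    direct = _direct_silhouette(D, labels)
    for g in direct:
        assert ours[g] == pytest.approx(direct[g], abs=1e-12)
    ref = silhouette_samples(D, labels, metric="precomputed")
    lab = np.array(labels)
    for g in set(labels):
        assert ours[g] == pytest.approx(float(np.median(ref[lab == g])), abs=1e-12)


def test_silhouette_random_labels_near_zero():
    rng = np.random.default_rng(5)
    meds = []
    for _ in range(20):
        X = rng.normal(size=(16, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        labels = rng.permutation(["a"] * 8 + ["b"] * 8)
        d = DistanceMatrix([f"s{i}" for i in range(16)], D, "euclidean")
        sil = silhouette_by_group(d, dict(zip(d.samples, labels)))
        meds.extend(sil.values())
    assert np.abs(np.median(meds)) < 0.2


def _md_for(samples, libs, types=None):
    types = types or ["plaque" if i % 2 == 0 else "abscess" for i in range(len(samples))]
    return op.SampleMetadata(
        pd.DataFrame(
            {
                "patient_id": [f"p{i//2}" for i in range(len(samples))],
                "specimen_type": types,
                "library_size": libs,
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )


def test_spearman_examples():
    coords = np.arange(6, dtype=float)[:, None]
    res = op.OrdinationResult([f"s{i}" for i in range(6)], coords, np.ones(1), np.ones(1))
    md = _md_for(res.samples, [10, 20, 30, 40, 50, 60])
    assert spearman_axis_vs_library(res, md) == pytest.approx(1.0)
    md_desc = _md_for(res.samples, [60, 50, 40, 30, 20, 10])
    assert spearman_axis_vs_library(res, md_desc) == pytest.approx(-1.0)
    coords4 = np.array([1.0, 2.0, 3.0, 4.0])[:, None]
    res4 = op.OrdinationResult([f"s{i}" for i in range(4)], coords4, np.ones(1), np.ones(1))
    md4 = _md_for(res4.samples, [20, 10, 40, 30])
    assert spearman_axis_vs_library(res4, md4) == pytest.approx(0.6)
    md_const = _md_for(res4.samples, [10, 10, 10, 10])
    assert np.isnan(spearman_axis_vs_library(res4, md_const))


def test_sweep_single_combination_and_depth_confounding(standard_cohort):
    ct, md, tax, truth = standard_cohort
    one = ordination_sweep(ct, md, transforms=("tss",), metrics=("bray_curtis",))
    assert one.loc[0, "top"] and one.loc[0, "rank"] == 1
    # raw euclidean axis 1 tracks sequencing depth; tss/bray should outrank it
    table = ordination_sweep(ct, md, transforms=("tss", "raw"), metrics=("bray_curtis", "euclidean"))
    table = table.set_index(["transform", "metric"])
    assert (
        table.loc[("tss", "bray_curtis"), "rank"]
        < table.loc[("raw", "euclidean"), "rank"]
    )
    assert (
        table.loc[("raw", "euclidean"), "abs_rho"]
        > table.loc[("tss", "bray_curtis"), "abs_rho"]
    )


def test_sweep_skips_invalid_combinations(standard_cohort):
    ct, md, tax, truth = standard_cohort
    table = ordination_sweep(ct, md, transforms=("tss", "clr"), metrics=("bray_curtis",))
    skipped = table[(table["transform"] == "clr") & (table["metric"] == "bray_curtis")]
    assert len(skipped) == 1 and skipped.iloc[0]["skipped"] != ""


def _brute_average_linkage(D):
    """Exhaustive average-linkage merge list on a small distance matrix."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            h = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or h < best[0] - 1e-15:
                best = (h, a, b)
        h, a, b = best
        merges.append((a, b, h, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def test_hierarchical_cluster_trivia_and_oracle():
    # proportional columns are identical after TSS -> distance 0, merged first
    vals0 = np.array([[1.0, 2.0, 10.0], [2.0, 4.0, 1.0], [3.0, 6.0, 5.0]])
    am = _am(vals0 / vals0.sum(axis=0), "tss")
    Z, ids = hierarchical_cluster(am)
    assert set(Z[0, :2].astype(int)) == {0, 1}
    assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
    # anti-correlated pair -> distance 2
    am2 = _am(np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]]), "tss")
    L = np.log(am2.values + am2.values[am2.values > 0].min() / 2)
    r = np.corrcoef(L.T)[0, 1]
    assert 1 - r == pytest.approx(2.0, abs=0.2)  # near-perfect anticorrelation
    # oracle on a 5-sample fixture
    rng = np.random.default_rng(6)
    vals = rng.uniform(0.01, 1, size=(8, 5))
    vals /= vals.sum(axis=0)
    am3 = _am(vals, "tss")
    Z3, _ = hierarchical_cluster(am3)
    pseudo = vals[vals > 0].min() / 2
    L3 = np.log(vals + pseudo)
    D = 1 - np.corrcoef(L3.T)
    np.fill_diagonal(D, 0)
    merges = _brute_average_linkage(np.clip(D, 0, None))
    for row, (a, b, h, size) in zip(Z3, merges):
        assert {int(row[0]), int(row[1])} == {a, b}
        assert row[2] == pytest.approx(h, abs=1e-10)
        assert int(row[3]) == size
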