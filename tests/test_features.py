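import json

import numpy as np
import pytest
import scipy.linalg

from connsearch.features import (FeatureMatrix, FeaturePipeline,
                                 GeometricMeanError, Scaler, TangentReference,
                                 assemble_feature_set, edge_names,
                                 estimate_covariance, geometric_mean,
                                 invsqrtm_spd, logm_spd, tangent_embed,
                                 tangent_unembed, unvectorize_upper,
                                 vectorize_upper)

from conftest import labels_and_sex, random_spd


# ---------------------------------------------------------------------------
# covariance estimation
# ---------------------------------------------------------------------------

def test_covariance_full_shrinkage_is_diagonal():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((50, 6))
    C = estimate_covariance(X, shrinkage=1.0)
    off = C[~np.eye(6, dtype=bool)]
    assert np.all(off == 0)
    assert np.all(np.diag(C) > 0)


def test_covariance_zero_shrinkage_is_empirical():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((40, 4))
    C = estimate_covariance(X, shrinkage=0.0)
    assert np.allclose(C, np.cov(X, rowvar=False), atol=1e-12)


def test_covariance_auto_recovers_truth_on_long_series():
    rng = np.random.default_rng(2)
    L = np.linalg.cholesky(np.array([[1.0, 0.5], [0.5, 1.0]]))
    X = rng.standard_normal((20000, 2)) @ L.T
    C = estimate_covariance(X, shrinkage="auto")
    assert C[0, 1] == pytest.approx(0.5, abs=0.05)


def test_covariance_auto_spd_when_underdetermined():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((10, 20))   # T < R: empirical covariance singular
    C = estimate_covariance(X, shrinkage="auto")
    assert np.linalg.eigvalsh(C).min() > 0


def test_covariance_constant_roi_error_names_roi():
    X = np.ones((30, 3))
    X[:, 0] = np.arange(30)
    X[:, 2] = np.random.default_rng(0).standard_normal(30)
    with pytest.raises(ValueError, match="ROI 1"):
        estimate_covariance(X)


# ---------------------------------------------------------------------------
# geometric mean
# ---------------------------------------------------------------------------

def test_geometric_mean_singleton_and_idempotent():
    rng = np.random.default_rng(4)
    A = random_spd(rng, 5)
    assert np.allclose(geometric_mean([A]), A)
    G = geometric_mean([A, A, A])
    assert np.allclose(G, A, atol=1e-6)


def test_geometric_mean_commuting_closed_form():
    # for commuting matrices the geometric mean is elementwise on the
    # shared eigenbasis: gm(diag(a), diag(b)) = diag(sqrt(ab))
    A = np.diag([1.0, 4.0])
    B = np.diag([4.0, 1.0])
    assert np.allclose(geometric_mean([A, B]), np.diag([2.0, 2.0]), atol=1e-10)
    A2 = np.diag([2.0, 8.0])
    B2 = np.diag([8.0, 2.0])
    assert np.allclose(geometric_mean([A2, B2]), np.diag([4.0, 4.0]), atol=1e-9)


def test_geometric_mean_residual_below_tolerance():
    rng = np.random.default_rng(5)
    mats = [random_spd(rng, 4) for _ in range(7)]
    G, iters = geometric_mean(mats, tol=1e-7, return_info=True)
    W = invsqrtm_spd(G)
    resid = np.linalg.norm(np.mean([logm_spd(W @ C @ W) for C in mats], axis=0),
                           "fro")
    assert resid <= 1e-7
    assert iters >= 1


def test_geometric_mean_affine_invariance():
    # gm(M C_i M^T) = M gm(C_i) M^T for any invertible M
    rng = np.random.default_rng(6)
    mats = [random_spd(rng, 3) for _ in range(5)]
    M = rng.standard_normal((3, 3)) + 3 * np.eye(3)
    G = geometric_mean(mats, tol=1e-10)
    G2 = geometric_mean([M @ C @ M.T for C in mats], tol=1e-10)
    assert np.allclose(G2, M @ G @ M.T, atol=1e-6)


def test_geometric_mean_nonconvergence_raises_with_residual():
    rng = np.random.default_rng(7)
    mats = [random_spd(rng, 4, cond=50) for _ in range(6)]
    with pytest.raises(GeometricMeanError) as exc:
        geometric_mean(mats, tol=1e-12, max_iter=1)
    assert exc.value.residual > 0
    assert exc.value.iterations == 1


# ---------------------------------------------------------------------------
# tangent embedding
# ---------------------------------------------------------------------------

def test_tangent_embed_at_reference_is_zero():
    rng = np.random.default_rng(8)
    G = random_spd(rng, 4)
    ref = TangentReference(mean=G, whitener=invsqrtm_spd(G))
    assert np.allclose(tangent_embed(G, ref), 0, atol=1e-12)


def test_tangent_embed_identity_reference_closed_form():
    ref = TangentReference(mean=np.eye(2), whitener=np.eye(2))
    C = np.diag([np.e, np.e ** 2])
    assert np.allclose(tangent_embed(C, ref), np.diag([1.0, 2.0]), atol=1e-12)


def test_tangent_embed_matches_scipy_logm_oracle():
    rng = np.random.default_rng(9)
    for _ in range(20):
        n = int(rng.integers(2, 9))
        G = random_spd(rng, n)
        C = random_spd(rng, n)
        ref = TangentReference(mean=G, whitener=invsqrtm_spd(G))
        W = ref.whitener
        oracle = scipy.linalg.logm(W @ C @ W)
        assert np.allclose(tangent_embed(C, ref), oracle.real, atol=1e-8)


def test_tangent_roundtrip():
    rng = np.random.default_rng(10)
    G = random_spd(rng, 5)
    C = random_spd(rng, 5)
    ref = TangentReference(mean=G, whitener=invsqrtm_spd(G))
    assert np.allclose(tangent_unembed(tangent_embed(C, ref), ref), C, atol=1e-8)


def test_tangent_embed_dimension_mismatch():
    rng = np.random.default_rng(11)
    ref = TangentReference.fit([random_spd(rng, 3) for _ in range(3)])
    with pytest.raises(ValueError):
        tangent_embed(random_spd(rng, 4), ref)


def test_embeddings_at_own_mean_average_to_zero():
    # defining property of the Frechet mean: whitened logs average to zero
    rng = np.random.default_rng(12)
    mats = [random_spd(rng, 4) for _ in range(6)]
    ref = TangentReference.fit(mats, tol=1e-9)
    mean_emb = np.mean([tangent_embed(C, ref) for C in mats], axis=0)
    assert np.linalg.norm(mean_emb, "fro") < 1e-7


def test_tangent_reference_json_roundtrip_and_checksum():
    rng = np.random.default_rng(13)
    ref = TangentReference.fit([random_spd(rng, 3) for _ in range(4)])
    ref2 = TangentReference.from_json(ref.to_json())
    assert np.allclose(ref.mean, ref2.mean)
    assert ref.checksum == ref2.checksum


# ---------------------------------------------------------------------------
# vectorization and assembly
# ---------------------------------------------------------------------------

def test_vectorize_upper_lengths():
    rng = np.random.default_rng(14)
    for n, expected in [(3, 3), (16, 120), (64, 2016), (122, 7381)]:
        M = random_spd(rng, min(n, 30)) if n <= 30 else None
        if M is None:
            A = rng.standard_normal((n, n))
            M = A + A.T
        assert vectorize_upper(M).size == expected


def test_vectorize_upper_ordering_and_roundtrip():
    M = np.array([[0.0, 1.0, 2.0],
                  [1.0, 0.0, 3.0],
                  [2.0, 3.0, 0.0]])
    v = vectorize_upper(M)
    assert np.array_equal(v, [1.0, 2.0, 3.0])
    assert edge_names(3) == ["edge_0_1", "edge_0_2", "edge_1_2"]
    back = unvectorize_upper(v, 3)
    assert np.array_equal(back, M)


def test_vectorize_upper_rejects_asymmetry():
    M = np.arange(9.0).reshape(3, 3)
    with pytest.raises(ValueError):
        vectorize_upper(M)


def test_assemble_combined_arithmetic():
    rng = np.random.default_rng(15)
    n, R, n_anat = 10, 10, 7
    edges = FeatureMatrix(rng.standard_normal((n, R * (R - 1) // 2)),
                          edge_names(R), ["edge"] * (R * (R - 1) // 2))
    anat = FeatureMatrix(rng.standard_normal((n, n_anat)),
                         [f"anat_{i}" for i in range(n_anat)],
                         ["anat"] * n_anat)
    sex = rng.integers(0, 2, n)
    site = np.array(["a", "b"] * 5)
    X = assemble_feature_set("combined", edges=edges, anat=anat, sex=sex,
                             site=site, site_categories=["a", "b", "c"])
    assert X.n_features == 45 + 7 + 1 + 3
    assert X.names[:45] == edge_names(R)
    assert list(X.kinds).count("edge") == 45
    assert list(X.kinds).count("anat") == 7
    assert list(X.kinds).count("covariate") == 4

    X_anat = assemble_feature_set("anatomical", anat=anat, sex=sex, site=site)
    assert X_anat.n_features == 7 + 1 + 2   # two observed site categories


def test_assemble_misalignment_and_missing_blocks():
    rng = np.random.default_rng(16)
    edges = FeatureMatrix(rng.standard_normal((4, 3)), edge_names(3),
                          ["edge"] * 3)
    anat = FeatureMatrix(rng.standard_normal((5, 2)), ["anat_0", "anat_1"],
                         ["anat"] * 2)
    with pytest.raises(ValueError, match="misalignment"):
        assemble_feature_set("combined", edges=edges, anat=anat)
    with pytest.raises(ValueError):
        assemble_feature_set("functional", edges=None)


def test_assemble_unseen_site_warns_and_zero_row():
    rng = np.random.default_rng(17)
    edges = FeatureMatrix(rng.standard_normal((2, 3)), edge_names(3),
                          ["edge"] * 3)
    with pytest.warns(UserWarning, match="unseen site"):
        X = assemble_feature_set("functional", edges=edges,
                                 site=np.array(["a", "z"]),
                                 site_categories=["a", "b"])
    site_cols = [i for i, n in enumerate(X.names) if n.startswith("site_")]
    assert np.array_equal(X.data[1, site_cols], [0.0, 0.0])
    assert np.array_equal(X.data[0, site_cols], [1.0, 0.0])


# ---------------------------------------------------------------------------
# scaler
# ---------------------------------------------------------------------------

def test_scaler_standardizes_fit_rows_only():
    rng = np.random.default_rng(18)
    X = rng.standard_normal((30, 4)) * 5 + 2
    fit_rows = np.arange(20)
    sc = Scaler.fit(X, fit_rows=fit_rows)
    Z = sc.transform(X)
    assert np.allclose(Z[fit_rows].mean(axis=0), 0, atol=1e-12)
    assert np.allclose(Z[fit_rows].std(axis=0), 1, atol=1e-12)
    # held-out rows use the frozen statistics, not their own
    assert not np.allclose(Z[20:].mean(axis=0), 0, atol=0.01)


def test_scaler_constant_column_centered_not_divided():
    X = np.ones((10, 2))
    X[:, 1] = np.arange(10)
    sc = Scaler.fit(X)
    Z = sc.transform(X)
    assert sc.constant_mask.tolist() == [True, False]
    assert np.allclose(Z[:, 0], 0)
    assert np.all(np.isfinite(Z))


def test_scaler_json_roundtrip():
    rng = np.random.default_rng(19)
    sc = Scaler.fit(rng.standard_normal((12, 3)))
    sc2 = Scaler.from_json(sc.to_json())
    assert sc.checksum == sc2.checksum
    X = rng.standard_normal((4, 3))
    assert np.allclose(sc.transform(X), sc2.transform(X))


# ---------------------------------------------------------------------------
# feature matrix serialization
# ---------------------------------------------------------------------------

def test_feature_matrix_csv_roundtrip(tmp_path):
    rng = np.random.default_rng(20)
    X = FeatureMatrix(rng.standard_normal((5, 4)),
                      ["edge_0_1", "edge_0_2", "anat_0", "sex"],
                      ["edge", "edge", "anat", "covariate"],
                      subject_ids=[f"s{i}" for i in range(5)])
    path = tmp_path / "feat.csv"
    X.to_csv(path)
    X2 = FeatureMatrix.from_csv(path)
    assert np.allclose(X.data, X2.data)
    assert X2.names == X.names
    assert list(X2.kinds) == list(X.kinds)
    assert list(X2.subject_ids) == list(X.subject_ids)


def test_feature_matrix_columns_of_kind():
    X = FeatureMatrix(np.zeros((2, 3)), ["a", "b", "c"],
                      ["edge", "anat", "edge"])
    assert X.columns_of_kind("edge").tolist() == [0, 2]


# ---------------------------------------------------------------------------
# end-to-end pipeline freezing
# ---------------------------------------------------------------------------

def test_pipeline_frozen_checksum_and_namespace(small_cohort):
    _, subjects, _ = small_cohort
    y, sex = labels_and_sex(subjects)
    pipe = FeaturePipeline(subjects, "combined").fit(np.arange(40))
    c1 = pipe.checksum
    X = pipe.transform(np.arange(40, 60))
    assert pipe.checksum == c1                 # transform never refits
    ext = pipe.transform_cohort(subjects[40:])
    assert np.allclose(ext.data, X.data)       # same subjects, same mapping
    assert pipe.checksum == c1
    assert X.names == pipe.feature_names


def test_pipeline_requires_fit(small_cohort):
    _, subjects, _ = small_cohort
    pipe = FeaturePipeline(subjects, "anatomical")
    with pytest.raises(RuntimeError, match="not fitted"):
        pipe.transform(np.arange(5))


def test_pipeline_feature_count_arithmetic(small_cohort):
    spec, subjects, _ = small_cohort
    R, n_anat = spec.n_rois, spec.n_anat
    n_sites = len({s.site for s in subjects})
    pipe = FeaturePipeline(subjects, "combined").fit(np.arange(50))
    X = pipe.transform(np.arange(10))
    assert X.n_features == R * (R - 1) // 2 + n_anat + 1 + n_sites
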