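import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from connsearch import zoo
from connsearch.features import FeatureMatrix
from connsearch.importance import (ImportanceRecord, NullDistribution,
                                   build_null, consensus_rank, direction_mark,
                                   permutation_importance, significance)

from conftest import brute_force_by


def _informative_data(rng, n=120, p=20, informative=0):
    """Only column `informative` predicts y; everything else is noise."""
    X = rng.standard_normal((n, p))
    y = (X[:, informative] + 0.3 * rng.standard_normal(n) > 0).astype(int)
    names = [f"f{i}" for i in range(p)]
    return FeatureMatrix(X, names, ["edge"] * p), y


def _logistic(seed=0):
    return zoo.ModelConfig("logistic_ridge", {"C": 1.0, "max_iter": 10000},
                           0, seed)


def test_single_informative_feature_dominates():
    rng = np.random.default_rng(0)
    X, y = _informative_data(rng)
    tr, te = np.arange(80), np.arange(80, 120)
    model = zoo.fit(_logistic(), X.rows(tr), y[tr])
    recs = permutation_importance(model, X.rows(te), y[te], seed=0)
    assert len(recs) == 20
    for r in recs:
        assert r.reps.size == 64
    best = max(recs, key=lambda r: r.mean_importance)
    assert best.feature == "f0"
    assert best.z >= 3.0
    assert best.mean_importance > 0.05


def test_z_scores_normalized_across_features():
    rng = np.random.default_rng(1)
    X, y = _informative_data(rng)
    model = zoo.fit(_logistic(), X, y)
    recs = permutation_importance(model, X, y, seed=1)
    zs = np.array([r.z for r in recs])
    assert zs.mean() == pytest.approx(0.0, abs=1e-8)
    assert zs.std() == pytest.approx(1.0, abs=1e-8)


def test_importance_order_invariance():
    # a feature's repetition values do not depend on which other features
    # are analyzed or in what order
    rng = np.random.default_rng(2)
    X, y = _informative_data(rng)
    model = zoo.fit(_logistic(), X, y)
    full = {r.feature: r for r in permutation_importance(model, X, y, seed=5)}
    subset = permutation_importance(model, X, y, seed=5,
                                    features=["f3", "f0"])
    for r in subset:
        assert np.array_equal(r.reps, full[r.feature].reps)
        assert r.mean_importance == full[r.feature].mean_importance


def test_importance_rejects_too_few_reps():
    rng = np.random.default_rng(3)
    X, y = _informative_data(rng, n=30)
    model = zoo.fit(_logistic(), X, y)
    with pytest.raises(ValueError):
        permutation_importance(model, X, y, n_reps=1)


def test_null_unbiased_and_deterministic():
    rng = np.random.default_rng(4)
    X = FeatureMatrix(rng.standard_normal((60, 5)),
                      [f"f{i}" for i in range(5)], ["edge"] * 5)
    y = np.array([0, 1] * 30)
    tr, te = np.arange(40), np.arange(40, 60)
    null = build_null(_logistic(), X.rows(tr), y[tr], X.rows(te), y[te],
                      n_label_perms=10, n_reps=16, seed=0)
    assert null.mean_matrix.shape == (10, 5)
    se = null.values.std() / np.sqrt(null.values.size)
    assert abs(null.values.mean()) < 2 * se + 1e-3
    null2 = build_null(_logistic(), X.rows(tr), y[tr], X.rows(te), y[te],
                       n_label_perms=10, n_reps=16, seed=0)
    assert np.array_equal(null.mean_matrix, null2.mean_matrix)
    assert np.array_equal(null.values, null2.values)


def test_importance_mean_sd_shrinks_with_reps():
    # within one model fit the repetition importances are independent, so
    # the sd of a mean over n of them scales ~1/sqrt(n): means of groups of
    # 4 must spread about twice as wide as means of groups of 16
    rng = np.random.default_rng(5)
    X, y = _informative_data(rng)
    model = zoo.fit(_logistic(), X, y)
    recs = permutation_importance(model, X, y, n_reps=64, seed=9)
    ratios = []
    for r in recs[:10]:
        g4 = r.reps.reshape(16, 4).mean(axis=1).std(ddof=1)
        g16 = r.reps.reshape(4, 16).mean(axis=1).std(ddof=1)
        if g16 > 0:
            ratios.append(g4 / g16)
    ratio = float(np.median(ratios))
    assert 1.3 < ratio < 3.0    # ideal 2.0, wide Monte-Carlo tolerance


def test_significance_by_against_brute_force_oracle():
    rng = np.random.default_rng(6)
    for _ in range(200):
        m = int(rng.integers(1, 50))
        p = rng.uniform(size=m) ** 2
        reject, q, _, _ = multipletests(p, alpha=0.05, method="fdr_by")
        o_reject, o_q = brute_force_by(p, alpha=0.05)
        assert np.allclose(q, o_q, atol=1e-12)
        assert np.array_equal(reject, o_reject)


def test_significance_hand_case_m_equals_1():
    # BY with m=1 reduces to p <= rate (c(1) = 1)
    rec = ImportanceRecord("f0", reps=np.array([0.2, 0.21, 0.19, 0.2]),
                           mean_importance=0.2, z=0.0)
    null = NullDistribution(
        mean_matrix=np.array([[0.0], [0.001], [-0.001], [0.0005], [-0.0005]]),
        features=["f0"], values=np.zeros(5), n_label_perms=5, n_reps=4, seed=0)
    out = significance([rec], null, fdr_rate=0.01)
    n = null.mean_matrix[:, 0]
    t = (0.2 - n.mean()) / (n.std(ddof=1) * np.sqrt(1 + 1 / 5))
    expected_p = stats.t.sf(t, df=4)
    assert out[0].p == pytest.approx(expected_p, abs=1e-12)
    assert out[0].q == pytest.approx(min(1.0, expected_p), abs=1e-12)
    assert out[0].significant == (expected_p <= 0.01)


def test_significance_all_p_one_none_significant():
    recs = [ImportanceRecord(f"f{i}", reps=np.zeros(4), mean_importance=0.0,
                             z=0.0) for i in range(3)]
    null = NullDistribution(mean_matrix=np.zeros((5, 3)),
                            features=["f0", "f1", "f2"], values=np.zeros(5),
                            n_label_perms=5, n_reps=4, seed=0)
    out = significance(recs, null)
    for r in out:
        assert r.p == 1.0
        assert r.degenerate
        assert not r.significant


def test_significance_requires_matching_namespace():
    rec = ImportanceRecord("missing", reps=np.ones(4), mean_importance=1.0,
                           z=0.0)
    null = NullDistribution(mean_matrix=np.zeros((5, 1)), features=["f0"],
                            values=np.zeros(5), n_label_perms=5, n_reps=4,
                            seed=0)
    with pytest.raises(ValueError, match="missing"):
        significance([rec], null)


# ---------------------------------------------------------------------------
# consensus and direction
# ---------------------------------------------------------------------------

def _records_from_z(zmap):
    return [ImportanceRecord(name, reps=np.zeros(4), mean_importance=z, z=z)
            for name, z in zmap.items()]


def test_consensus_flags_and_ranking():
    names = [f"f{i}" for i in range(6)]
    per_model = []
    for m in range(5):
        zmap = {n: float(i) for i, n in enumerate(names)}
        zmap["f5"] = 10.0                     # star: z >= 3 in all models
        zmap["f4"] = 9.0 if m > 0 else 1.0    # diamond: 4 of 5
        zmap["f3"] = 8.0 if m > 1 else 1.0    # neither: 3 of 5
        per_model.append(_records_from_z(zmap))
    out = consensus_rank(per_model, top_k=3)
    assert [c.feature for c in out] == ["f5", "f4", "f3"]
    assert out[0].star and not out[0].diamond
    assert out[1].diamond and not out[1].star
    assert not out[2].star and not out[2].diamond
    assert out[0].median_z == 10.0


def test_consensus_requires_shared_namespace_and_2_models():
    a = _records_from_z({"f0": 1.0})
    b = _records_from_z({"f1": 1.0})
    with pytest.raises(ValueError, match="namespace"):
        consensus_rank([a, b])
    with pytest.raises(ValueError, match="2 models"):
        consensus_rank([a])


def test_consensus_median_is_componentwise():
    names = ["a", "b"]
    per_model = [_records_from_z({"a": z, "b": -z}) for z in (1.0, 2.0, 5.0)]
    out = consensus_rank(per_model, top_k=2)
    assert out[0].feature == "a"
    assert out[0].median_z == 2.0
    assert out[1].median_z == -2.0


def test_direction_mark_signs_and_welch_oracle():
    rng = np.random.default_rng(7)
    n = 40
    y = np.array([0, 1] * (n // 2))
    base = rng.standard_normal(n)
    X = FeatureMatrix(np.column_stack([base + 2.0 * y, base - 2.0 * y, base]),
                      ["up", "down", "flat"], ["edge"] * 3)
    assert direction_mark(X, y, "up")[0] == "+"
    assert direction_mark(X, y, "down")[0] == "-"
    assert direction_mark(X, y, "flat")[0] == "o"
    # Welch p matches scipy on the same split
    _, p = direction_mark(X, y, "up")
    a, b = X.data[y == 1, 0], X.data[y == 0, 0]
    assert p == pytest.approx(
        stats.ttest_ind(a, b, equal_var=False).pvalue, abs=1e-12)


def test_direction_mark_identical_groups_is_o():
    X = FeatureMatrix(np.tile(np.arange(10.0), (2, 1)).T.reshape(10, 2),
                      ["a", "b"], ["edge"] * 2)
    y = np.array([0, 1] * 5)
    mark, p = direction_mark(X, y, "a")
    assert mark == "o"
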