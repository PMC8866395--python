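import numpy as np
import pytest

from connsearch import zoo
from connsearch.search import (SearchRecord, SplitPlan, landscape_kde,
                               make_split_plan, run_search)

from conftest import labels_and_sex

CHEAP_FAMILIES = ["naive_bayes", "logistic_ridge"]
CHEAP_SPACES = zoo.default_spaces()


# ---------------------------------------------------------------------------
# split plan
# ---------------------------------------------------------------------------

def _balanced_labels(n=100):
    rng = np.random.default_rng(0)
    y = np.array([0, 1] * (n // 2))
    sex = np.array([0, 0, 1, 1] * (n // 4))
    perm = rng.permutation(n)
    return y[perm], sex[perm]


def test_split_plan_exact_cell_counts():
    # n=100 balanced on diagnosis x sex: 25 per cell, 20% test -> 5 per cell
    y, sex = _balanced_labels(100)
    plan = make_split_plan(y, sex, seed=0)
    assert plan.test_idx.size == 20
    assert plan.train_idx.size == 80
    for lab in (0, 1):
        for sx in (0, 1):
            cell = (y[plan.test_idx] == lab) & (sex[plan.test_idx] == sx)
            assert cell.sum() == 5


def test_split_plan_partitions_are_disjoint_and_exhaustive():
    y, sex = _balanced_labels(100)
    plan = make_split_plan(y, sex, seed=1)
    assert np.intersect1d(plan.train_idx, plan.test_idx).size == 0
    assert np.array_equal(np.sort(np.concatenate([plan.train_idx, plan.test_idx])),
                          np.arange(100))
    all_val = np.sort(np.concatenate([va for _, va in plan.folds]))
    assert np.array_equal(all_val, plan.train_idx)
    sizes = [va.size for _, va in plan.folds]
    assert max(sizes) - min(sizes) <= 1
    for tr, va in plan.folds:
        assert np.intersect1d(tr, va).size == 0
        assert np.array_equal(np.sort(np.concatenate([tr, va])), plan.train_idx)


def test_split_plan_deterministic_checksum():
    y, sex = _balanced_labels(60)
    a = make_split_plan(y, sex, seed=3)
    b = make_split_plan(y, sex, seed=3)
    c = make_split_plan(y, sex, seed=4)
    assert a.checksum == b.checksum
    assert a.checksum != c.checksum


def test_split_plan_small_stratum_fallback_warns():
    y = np.array([0, 1] * 25)
    sex = np.zeros(50, int)
    sex[0] = 1   # a singleton diagnosis-by-sex cell
    with pytest.warns(UserWarning, match="falling back"):
        plan = make_split_plan(y, sex, seed=0)
    assert plan.stratify_on == ("diagnosis",)


def test_split_plan_json_roundtrip(tmp_path):
    y, sex = _balanced_labels(40)
    plan = make_split_plan(y, sex, seed=5)
    path = tmp_path / "plan.json"
    plan.save(path)
    loaded = SplitPlan.load(path)
    assert loaded.checksum == plan.checksum
    assert np.array_equal(loaded.train_idx, plan.train_idx)


def test_split_plan_rejects_tiny_cohorts():
    with pytest.raises(ValueError):
        make_split_plan(np.array([0, 1] * 5))


# ---------------------------------------------------------------------------
# run_search
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_search(small_cohort):
    _, subjects, _ = small_cohort
    y, sex = labels_and_sex(subjects)
    plan = make_split_plan(y, sex, seed=0)
    result = run_search(subjects, CHEAP_FAMILIES,
                        ["functional", "anatomical"], plan,
                        n_configs=3, seed=0)
    return plan, result


def test_search_bookkeeping(small_search):
    plan, result = small_search
    cv_records = [r for r in result.records if not r.selected]
    assert len(cv_records) == 2 * 2 * 3
    selected = [r for r in result.records if r.selected]
    assert len(selected) == 2 * 2
    assert result.matrix.shape == (2, 2)
    assert not result.matrix.isna().any().any()


def test_search_fairness_shared_plan(small_search):
    plan, result = small_search
    assert {r.plan_checksum for r in result.records} == {plan.checksum}


def test_search_selection_is_best_cv(small_search):
    _, result = small_search
    for (family, mode) in result.best_models:
        combo = [r for r in result.records
                 if r.family == family and r.feature_set == mode]
        sel = [r for r in combo if r.selected]
        assert len(sel) == 1
        best_cv = max(r.mean_cv_auroc for r in combo if not r.selected)
        assert sel[0].mean_cv_auroc == best_cv


def test_search_journal_resume(tmp_path, small_cohort):
    _, subjects, _ = small_cohort
    y, sex = labels_and_sex(subjects)
    plan = make_split_plan(y, sex, seed=0)
    out = tmp_path / "run"
    r1 = run_search(subjects, ["naive_bayes"], ["anatomical"], plan,
                    n_configs=2, seed=0, out_dir=str(out))
    journal = (out / "search_records.jsonl").read_text()
    r2 = run_search(subjects, ["naive_bayes"], ["anatomical"], plan,
                    n_configs=2, seed=0, out_dir=str(out))
    # resume reuses journalled configs rather than re-journalling them
    assert (out / "search_records.jsonl").read_text() == journal
    assert [rec.to_dict() for rec in r1.records] == \
        [rec.to_dict() for rec in r2.records]


def test_search_brainnet_skips_non_square_modes(small_cohort):
    _, subjects, _ = small_cohort
    y, sex = labels_and_sex(subjects)
    plan = make_split_plan(y, sex, seed=0)
    from connsearch.nn import TrainingOptions
    result = run_search(subjects, ["brainnet_cnn"], ["anatomical"], plan,
                        n_configs=1, seed=0,
                        options=TrainingOptions(epochs=1))
    assert result.matrix.isna().all().all()
    assert result.records == []


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def _records_with_optimum(center=3.0, n=120, noise=0.02, lo=1, hi=5, seed=0):
    """SearchRecords whose CV AUROC peaks at hidden_layers = center."""
    rng = np.random.default_rng(seed)
    space = {"dfnn": {"hidden_layers": zoo.Dimension(lo, hi, "uniform", "int"),
                      "l2": zoo.Dimension(1e-4, 2e-2, "log")}}
    records = []
    for i in range(n):
        cfg = zoo.sample_config("dfnn", rng, draw_index=i, spaces=space)
        layers = cfg.values["hidden_layers"]
        perf = 0.8 - 0.05 * (layers - center) ** 2 + noise * rng.standard_normal()
        records.append(SearchRecord(family="dfnn", feature_set="functional",
                                    draw_index=i, config=cfg,
                                    mean_cv_auroc=float(perf)))
    return records, space


def test_landscape_peak_recovers_construction_optimum():
    records, space = _records_with_optimum()
    est = landscape_kde(records, ["hidden_layers"], spaces=space)
    assert not est.degenerate
    assert not est.boundary_flag
    assert abs(est.peak["hidden_layers"] - 3.0) <= 0.5
    assert est.n_top == int(np.ceil(0.2 * len(records)))


def test_landscape_boundary_flag_when_optimum_at_edge():
    records, space = _records_with_optimum(center=5.0)
    est = landscape_kde(records, ["hidden_layers"], spaces=space)
    assert est.boundary_flag


def test_landscape_degenerate_identical_performance():
    records, space = _records_with_optimum(noise=0.0)
    for r in records:
        r.mean_cv_auroc = 0.7
    est = landscape_kde(records, ["hidden_layers"], spaces=space)
    assert est.degenerate
    assert est.peak is None


def test_landscape_requires_enough_records_and_known_dims():
    records, space = _records_with_optimum(n=5)
    with pytest.raises(ValueError, match="at least 10"):
        landscape_kde(records, ["hidden_layers"], spaces=space)
    records, space = _records_with_optimum(n=20)
    with pytest.raises(KeyError):
        landscape_kde(records, ["nonexistent"], spaces=space)


def test_landscape_log_dim_analyzed_on_log_scale():
    # performance peaked at l2 = 1e-3 (center of the log range is ~1.4e-3)
    rng = np.random.default_rng(1)
    space = {"dfnn": {"l2": zoo.Dimension(1e-4, 1e-2, "log")}}
    records = []
    for i in range(150):
        cfg = zoo.sample_config("dfnn", rng, draw_index=i, spaces=space)
        log_l2 = np.log10(cfg.values["l2"])
        perf = 0.8 - 0.1 * (log_l2 + 3.0) ** 2 + 0.02 * rng.standard_normal()
        records.append(SearchRecord(family="dfnn", feature_set="functional",
                                    draw_index=i, config=cfg,
                                    mean_cv_auroc=float(perf)))
    est = landscape_kde(records, ["l2"], spaces=space)
    assert abs(np.log10(est.peak["l2"]) + 3.0) < 0.5
    assert not est.boundary_flag
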