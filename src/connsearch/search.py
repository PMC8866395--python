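"""Fairness-preserving model search: frozen stratified splits, random
hyperparameter search with 3-fold cross-validation, held-out test
evaluation, and kernel-density landscape analysis of the search records.

Every family consumes the identical SplitPlan (train/test partition and CV
folds stratified jointly on diagnosis and sex), so performance differences
cannot come from partitioning luck. Within each CV fold the tangent
reference and scaler are refit on that fold's training portion only; the
test evaluation refits them on the full training set (no leakage in either
place).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import zoo
from .features import FEATURE_MODES, FeaturePipeline
from .metrics import compute_auroc

__all__ = [
    "SplitPlan", "make_split_plan", "SearchRecord", "SearchResult",
    "run_search", "LandscapeEstimate", "landscape_kde",
]


# ---------------------------------------------------------------------------
# Split plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    train_idx: np.ndarray
    test_idx: np.ndarray
    folds: tuple          # k pairs of (fold_train_idx, fold_val_idx), absolute
    stratify_on: tuple
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    @property
    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(np.sort(self.train_idx).astype(np.int64).tobytes())
        h.update(np.sort(self.test_idx).astype(np.int64).tobytes())
        for tr, va in self.folds:
            h.update(np.sort(tr).astype(np.int64).tobytes())
            h.update(np.sort(va).astype(np.int64).tobytes())
        return h.hexdigest()

    def to_json(self) -> str:
        return json.dumps({
            "train_idx": self.train_idx.tolist(),
            "test_idx": self.test_idx.tolist(),
            "folds": [[tr.tolist(), va.tolist()] for tr, va in self.folds],
            "stratify_on": list(self.stratify_on),
            "seed": self.seed, "version": 1})

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        d = json.loads(text)
        return cls(np.array(d["train_idx"], int), np.array(d["test_idx"], int),
                   tuple((np.array(tr, int), np.array(va, int)) for tr, va in d["folds"]),
                   tuple(d["stratify_on"]), d["seed"])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "SplitPlan":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _largest_remainder_counts(sizes: np.ndarray, frac: float, total: int) -> np.ndarray:
    """Per-stratum test counts summing to `total`, proportions within one."""
    quotas = sizes * frac
    base = np.floor(quotas).astype(int)
    short = total - base.sum()
    order = np.argsort(-(quotas - base))
    counts = base.copy()
    for i in order[:short]:
        counts[i] += 1
    return counts


def make_split_plan(labels, sex=None, train_frac: float = 0.8, k: int = 3,
                    seed: int = 0) -> SplitPlan:
    """Frozen 80/20 split plus k CV folds, stratified on diagnosis and sex.

    Per-stratum proportions are preserved within one subject in every
    partition; overall fold sizes differ by at most one. Strata too small
    to stratify (fewer than 2*k members) trigger a warning and a fallback
    to diagnosis-only stratification.
    """
    labels = np.asarray(labels, int)
    n = labels.size
    if n < 10 * k:
        raise ValueError(f"need at least {10 * k} subjects for a {k}-fold plan")
    stratify_on = ("diagnosis",)
    strata = labels.copy()
    if sex is not None:
        sex = np.asarray(sex, int)
        joint = labels * 2 + sex
        counts = np.bincount(joint)
        if np.all(counts[counts > 0] >= 2 * k):
            strata = joint
            stratify_on = ("diagnosis", "sex")
        else:
            warnings.warn("a diagnosis-by-sex stratum is too small to stratify; "
                          "falling back to diagnosis-only stratification",
                          UserWarning, stacklevel=2)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    stratum_values = np.unique(strata)
    groups = [rng.permutation(np.flatnonzero(strata == s)) for s in stratum_values]
    sizes = np.array([g.size for g in groups])

    n_test = int(round(n * (1.0 - train_frac)))
    test_counts = _largest_remainder_counts(sizes, 1.0 - train_frac, n_test)
    test_parts, train_parts = [], []
    for g, c in zip(groups, test_counts):
        test_parts.append(g[:c])
        train_parts.append(g[c:])
    test_idx = np.sort(np.concatenate(test_parts))
    train_groups = [rng.permutation(g) for g in train_parts]

    # deal each stratum cyclically across folds with a rotating offset so
    # overall fold sizes stay within one of each other
    fold_members = [[] for _ in range(k)]
    offset = 0
    for g in train_groups:
        for j, idx in enumerate(g):
            fold_members[(offset + j) % k].append(idx)
        offset = (offset + g.size) % k
    folds = []
    all_train = np.sort(np.concatenate([np.array(m, int) for m in fold_members]))
    for f in range(k):
        va = np.sort(np.array(fold_members[f], int))
        tr = np.setdiff1d(all_train, va)
        folds.append((tr, va))
    return SplitPlan(train_idx=all_train, test_idx=test_idx, folds=tuple(folds),
                     stratify_on=stratify_on, seed=seed)


# ---------------------------------------------------------------------------
# Search records
# ---------------------------------------------------------------------------

@dataclass
class SearchRecord:
    family: str
    feature_set: str
    draw_index: int
    config: zoo.ModelConfig
    fold_aurocs: list | None = None
    mean_cv_auroc: float | None = None
    test_auroc: float | None = None
    selected: bool = False
    plan_checksum: str = ""
    error: str | None = None

    def to_dict(self) -> dict:
        return {"family": self.family, "feature_set": self.feature_set,
                "draw_index": self.draw_index, "config": self.config.to_dict(),
                "fold_aurocs": self.fold_aurocs, "mean_cv_auroc": self.mean_cv_auroc,
                "test_auroc": self.test_auroc, "selected": self.selected,
                "plan_checksum": self.plan_checksum, "error": self.error}

    @classmethod
    def from_dict(cls, d: dict) -> "SearchRecord":
        d = dict(d)
        d["config"] = zoo.ModelConfig.from_dict(d["config"])
        return cls(**d)


@dataclass
class SearchResult:
    records: list
    matrix: pd.DataFrame                   # families x feature sets, test AUROC
    best_models: dict                      # (family, mode) -> TrainedModel
    pipelines: dict                        # mode -> FeaturePipeline fit on full train
    plan: SplitPlan

    def matrix_to_csv(self, path) -> None:
        self.matrix.to_csv(path, index_label="family")


def _mode_index(mode: str) -> int:
    return FEATURE_MODES.index(mode)


def _family_index(family: str) -> int:
    return list(zoo.FAMILIES).index(family)


def fit_on_training_set(config, X_train, y_train, seed: int = 0, options=None):
    """Refit a configuration on the full training rows for final evaluation.

    Deep families keep the early-stopping regime they were selected under by
    monitoring an internal 10% sliver of the training rows (never the test
    set); classical families fit directly.
    """
    if zoo.CATEGORY_OF[config.family] == "deep":
        n_tr = X_train.n_subjects
        sl_rng = np.random.default_rng(np.random.SeedSequence([seed, 777]))
        order = sl_rng.permutation(n_tr)
        n_val = max(2, int(round(0.1 * n_tr)))
        val_rows, fit_rows = order[:n_val], order[n_val:]
        y_train = np.asarray(y_train)
        return zoo.fit(config, X_train.rows(fit_rows), y_train[fit_rows],
                       validation=(X_train.rows(val_rows), y_train[val_rows]),
                       options=options)
    return zoo.fit(config, X_train, y_train, options=options)


def run_search(cohort, families, feature_modes, plan: SplitPlan,
               n_configs: int = 50, seed: int = 0, spaces: dict | None = None,
               out_dir: str | None = None, embed_scope: str = "fold",
               options=None, shrinkage="auto") -> SearchResult:
    """Random search over every (family x feature set) combination.

    For each combination, ``n_configs`` configurations are drawn and scored
    by mean validation AUROC over the plan's CV folds; the best (ties to the
    smaller draw index) is refit on the full training set and evaluated once
    on the held-out test set. Per-config results stream to an append-only
    JSONL journal under ``out_dir`` and finished configs are skipped on
    resume. Failed fits are recorded and the search continues.

    ``embed_scope='fold'`` (default) refits the tangent reference and scaler
    inside each CV fold; ``'global'`` reuses the full-training-set artifacts
    for fold scoring as well.
    """
    if embed_scope not in ("fold", "global"):
        raise ValueError("embed_scope must be 'fold' or 'global'")
    cohort = list(cohort)
    y = np.array([s.diagnosis for s in cohort], int)

    journal_path = os.path.join(out_dir, "search_records.jsonl") if out_dir else None
    done: dict[tuple, SearchRecord] = {}
    if journal_path and os.path.exists(journal_path):
        with open(journal_path) as fh:
            for line in fh:
                rec = SearchRecord.from_dict(json.loads(line))
                done[(rec.family, rec.feature_set, rec.draw_index, rec.selected)] = rec

    def journal(rec: SearchRecord):
        if journal_path:
            os.makedirs(out_dir, exist_ok=True)
            with open(journal_path, "a") as fh:
                fh.write(json.dumps(rec.to_dict()) + "\n")

    # ---- shared per-mode feature data (fairness across families) ----------
    from .features import estimate_covariance
    needs_cov = any(m != "anatomical" for m in feature_modes)
    covs = ([estimate_covariance(s.timeseries, shrinkage) for s in cohort]
            if needs_cov else None)

    mode_data = {}
    for mode in feature_modes:
        mode_covs = covs if mode != "anatomical" else None
        full = FeaturePipeline(cohort, mode, shrinkage=shrinkage,
                               covariances=mode_covs).fit(plan.train_idx)
        fold_sets = []
        for tr, va in plan.folds:
            if embed_scope == "fold":
                pf = FeaturePipeline(cohort, mode, shrinkage=shrinkage,
                                     covariances=mode_covs,
                                     site_categories=full.site_categories).fit(tr)
            else:
                pf = full
            fold_sets.append((pf.transform(tr), y[tr], pf.transform(va), y[va]))
        mode_data[mode] = {
            "folds": fold_sets,
            "X_train": full.transform(plan.train_idx), "y_train": y[plan.train_idx],
            "X_test": full.transform(plan.test_idx), "y_test": y[plan.test_idx],
            "pipeline": full,
        }

    records: list[SearchRecord] = []
    best_models: dict = {}
    matrix = pd.DataFrame(index=list(families), columns=list(feature_modes), dtype=float)

    for family in families:
        for mode in feature_modes:
            if zoo.FAMILIES[family].square_input and mode != "functional":
                matrix.loc[family, mode] = np.nan
                continue
            rng = np.random.default_rng(np.random.SeedSequence(
                [seed, _family_index(family), _mode_index(mode)]))
            configs = [zoo.sample_config(family, rng, draw_index=i, spaces=spaces)
                       for i in range(n_configs)]
            data = mode_data[mode]
            combo_records = []
            for cfg in configs:
                key = (family, mode, cfg.draw_index, False)
                if key in done:
                    combo_records.append(done[key])
                    continue
                rec = SearchRecord(family=family, feature_set=mode,
                                   draw_index=cfg.draw_index, config=cfg,
                                   plan_checksum=plan.checksum)
                try:
                    folds = []
                    for X_tr, y_tr, X_va, y_va in data["folds"]:
                        m = zoo.fit(cfg, X_tr, y_tr, validation=(X_va, y_va),
                                    options=options)
                        folds.append(compute_auroc(zoo.predict_score(m, X_va), y_va))
                    rec.fold_aurocs = [float(a) for a in folds]
                    rec.mean_cv_auroc = float(np.mean(folds))
                except zoo.InputCompatibilityError:
                    raise
                except Exception as exc:   # noqa: BLE001 - searches must survive
                    rec.error = f"{type(exc).__name__}: {exc}"
                journal(rec)
                combo_records.append(rec)
            records.extend(combo_records)

            ok = [r for r in combo_records if r.mean_cv_auroc is not None]
            if not ok:
                matrix.loc[family, mode] = np.nan
                continue
            best = max(ok, key=lambda r: (r.mean_cv_auroc, -r.draw_index))
            sel_key = (family, mode, best.draw_index, True)
            model = fit_on_training_set(best.config, data["X_train"],
                                        data["y_train"], seed=seed,
                                        options=options)
            test_auroc = compute_auroc(zoo.predict_score(model, data["X_test"]),
                                       data["y_test"])
            if sel_key in done:
                sel = done[sel_key]
            else:
                sel = SearchRecord(family=family, feature_set=mode,
                                   draw_index=best.draw_index, config=best.config,
                                   fold_aurocs=best.fold_aurocs,
                                   mean_cv_auroc=best.mean_cv_auroc,
                                   test_auroc=float(test_auroc), selected=True,
                                   plan_checksum=plan.checksum)
                journal(sel)
            records.append(sel)
            best_models[(family, mode)] = model
            matrix.loc[family, mode] = sel.test_auroc

    return SearchResult(records=records, matrix=matrix, best_models=best_models,
                        pipelines={m: mode_data[m]["pipeline"] for m in feature_modes},
                        plan=plan)


# ---------------------------------------------------------------------------
# Hyperparameter landscape
# ---------------------------------------------------------------------------

@dataclass
class LandscapeEstimate:
    dims: list
    grid: dict                   # dim -> axis values (original scale)
    top_density: np.ndarray | None
    bottom_density: np.ndarray | None
    peak: dict | None            # dim -> value at top-density argmax
    boundary_flag: bool
    degenerate: bool
    n_top: int = 0
    n_bottom: int = 0

    def peak_table(self) -> pd.DataFrame:
        rows = [{"dim": d, "peak": None if self.peak is None else self.peak[d],
                 "on_boundary": self.boundary_flag, "degenerate": self.degenerate}
                for d in self.dims]
        return pd.DataFrame(rows)


def landscape_kde(records, dims, quantile: float = 0.2, grid_size: int = 50,
                  spaces: dict | None = None,
                  boundary_frac: float = 0.05) -> LandscapeEstimate:
    """Kernel density estimates over hyperparameters for the top- vs
    bottom-performing quantiles of one family's search records.

    Log-uniform dimensions are analyzed on log10 scale; all dimensions are
    standardized before a Scott-rule Gaussian KDE. The returned peak is the
    argmax of the top-quantile density on a grid spanning the search range,
    flagged when it lies within ``boundary_frac`` of a range edge.
    """
    from scipy.stats import gaussian_kde

    recs = [r for r in records if r.mean_cv_auroc is not None and not r.selected]
    if len(recs) < 10:
        raise ValueError("need at least 10 scored records for a landscape")
    families = {r.family for r in recs}
    if len(families) != 1:
        raise ValueError("landscape_kde analyzes one family at a time")
    family = families.pop()
    space = (spaces or zoo.default_spaces())[family]
    for d in dims:
        if d not in space:
            raise KeyError(f"dimension '{d}' not in the {family} search space")

    n = len(recs)
    q_n = math.ceil(quantile * n)
    perf = np.array([r.mean_cv_auroc for r in recs])
    if perf.max() - perf.min() < 1e-12:
        return LandscapeEstimate(dims=list(dims), grid={}, top_density=None,
                                 bottom_density=None, peak=None,
                                 boundary_flag=False, degenerate=True,
                                 n_top=q_n, n_bottom=q_n)
    order = np.argsort(perf, kind="stable")
    bottom_ids, top_ids = order[:q_n], order[-q_n:]

    def _tf(dim: zoo.Dimension, v):
        return np.log10(v) if dim.scale == "log" else float(v)

    vals = np.array([[_tf(space[d], r.config.values[d]) for d in dims] for r in recs])
    mu, sd = vals.mean(axis=0), vals.std(axis=0)
    sd[sd < 1e-12] = 1.0
    Z = (vals - mu) / sd

    lo = np.array([_tf(space[d], space[d].lo) for d in dims])
    hi = np.array([_tf(space[d], space[d].hi) for d in dims])

    # dimensions where the whole top quantile sits at one value (common for
    # integer dims with a sharp optimum) make the KDE covariance singular;
    # their peak is that value and the KDE runs on the remaining dims
    top_vals = vals[top_ids]
    const_dims = [a for a in range(len(dims))
                  if np.ptp(top_vals[:, a]) < 1e-12]
    kde_dims = [a for a in range(len(dims)) if a not in const_dims]

    peak, boundary = {}, False
    grid_axes = {}

    def _boundary(raw_value: float, a: int) -> bool:
        span = hi[a] - lo[a]
        frac = (raw_value - lo[a]) / span if span > 0 else 0.5
        return frac <= boundary_frac or frac >= 1 - boundary_frac

    for a in const_dims:
        d = dims[a]
        raw = float(top_vals[0, a])
        peak[d] = float(10 ** raw) if space[d].scale == "log" else raw
        boundary = boundary or _boundary(raw, a)
        axis_raw = np.linspace(lo[a], hi[a], grid_size)
        grid_axes[d] = (10 ** axis_raw if space[d].scale == "log" else axis_raw)

    top_density = bottom_density = None
    if kde_dims:
        axes_z = [np.linspace((lo[a] - mu[a]) / sd[a], (hi[a] - mu[a]) / sd[a],
                              grid_size) for a in kde_dims]
        mesh = np.meshgrid(*axes_z, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh])
        try:
            kde_top = gaussian_kde(Z[np.ix_(top_ids, kde_dims)].T, bw_method="scott")
            top_density = kde_top(pts).reshape(mesh[0].shape)
        except np.linalg.LinAlgError:
            return LandscapeEstimate(dims=list(dims), grid={}, top_density=None,
                                     bottom_density=None, peak=None,
                                     boundary_flag=False, degenerate=True,
                                     n_top=q_n, n_bottom=q_n)
        try:
            kde_bot = gaussian_kde(Z[np.ix_(bottom_ids, kde_dims)].T,
                                   bw_method="scott")
            bottom_density = kde_bot(pts).reshape(mesh[0].shape)
        except np.linalg.LinAlgError:
            bottom_density = None

        idx = np.unravel_index(int(np.argmax(top_density)), top_density.shape)
        for pos, a in enumerate(kde_dims):
            d = dims[a]
            raw = axes_z[pos][idx[pos]] * sd[a] + mu[a]
            peak[d] = float(10 ** raw) if space[d].scale == "log" else float(raw)
            boundary = boundary or _boundary(raw, a)
            axis_raw = axes_z[pos] * sd[a] + mu[a]
            grid_axes[d] = (10 ** axis_raw if space[d].scale == "log" else axis_raw)

    return LandscapeEstimate(dims=list(dims), grid=grid_axes,
                             top_density=top_density, bottom_density=bottom_density,
                             peak=peak, boundary_flag=boundary, degenerate=False,
                             n_top=q_n, n_bottom=q_n)
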