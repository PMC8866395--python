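"""External-cohort transfer, supervised domain adaptation, and pre/post
importance concordance.

Transfer evaluation applies source-trained models to an external cohort
whose features were built with the *source* tangent reference and scaler —
enforced by checksum so no preprocessing statistic can leak from the new
cohort. Supervised domain adaptation then fine-tunes each model under
10-fold cross-validation: every fold tunes on a distinct 10% of the
external cohort (deep models warm-start with early stopping on a sliver of
the tuning split; classical models refit from scratch, flagged) and is
evaluated on the remaining 90%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import zoo
from .features import FeatureMatrix, FeaturePipeline
from .importance import ImportanceRecord
from .metrics import compute_auroc

__all__ = [
    "TransferResult", "AdaptationResult", "ConcordanceResult", "LeakageError",
    "build_external_features", "transfer_evaluate", "domain_adapt",
    "importance_concordance",
]


class LeakageError(RuntimeError):
    """Preprocessing artifacts do not match the frozen source artifacts."""


@dataclass
class TransferResult:
    per_model_auroc: list
    mean_auroc: float
    sd_auroc: float
    pipeline_checksum: str


@dataclass
class AdaptationResult:
    fold_auroc: list              # tuned AUROC per fold
    mean_auroc: float
    sd_auroc: float
    tune_frac: float
    refit_from_scratch: bool      # True for classical families (no warm start)
    skipped_folds: list = field(default_factory=list)


@dataclass
class ConcordanceResult:
    pearson: float
    spearman: float
    n_features: int
    features: list
    rule: str                     # 'union' | 'intersection'
    flagged: bool = False         # too few features for a defined correlation
    alternative: dict | None = None   # the other subset rule's numbers


def build_external_features(pipeline: FeaturePipeline, external_cohort,
                            expected_checksum: str | None = None
                            ) -> tuple[FeatureMatrix, np.ndarray]:
    """Project an external cohort through the frozen source pipeline.

    ``expected_checksum`` (recorded when the source models were trained)
    guards against a refit pipeline being passed by mistake.
    """
    if expected_checksum is not None and pipeline.checksum != expected_checksum:
        raise LeakageError("pipeline checksum differs from the artifacts the "
                           "source models were trained with")
    X = pipeline.transform_cohort(external_cohort)
    y = np.array([s.diagnosis for s in external_cohort], int)
    return X, y


def transfer_evaluate(models: list[zoo.TrainedModel], X_ext: FeatureMatrix,
                      y_ext, pipeline: FeaturePipeline | None = None,
                      expected_checksum: str | None = None) -> TransferResult:
    """AUROC of each source-trained model on the external cohort, no tuning."""
    if pipeline is not None and expected_checksum is not None \
            and pipeline.checksum != expected_checksum:
        raise LeakageError("external features must come from the frozen source "
                           "pipeline (checksum mismatch)")
    y_ext = np.asarray(y_ext, int)
    aurocs = [compute_auroc(zoo.predict_score(m, X_ext), y_ext) for m in models]
    return TransferResult(per_model_auroc=[float(a) for a in aurocs],
                          mean_auroc=float(np.mean(aurocs)),
                          sd_auroc=float(np.std(aurocs)),
                          pipeline_checksum="" if pipeline is None else pipeline.checksum)


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """k disjoint, exhaustive, label-stratified folds (each is a tuning set)."""
    members = [[] for _ in range(k)]
    offset = 0
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        for j, i in enumerate(idx):
            members[(offset + j) % k].append(i)
        offset = (offset + idx.size) % k
    return [np.sort(np.array(m, int)) for m in members]


def domain_adapt(model: zoo.TrainedModel, X_ext: FeatureMatrix, y_ext,
                 k: int = 10, tune_frac: float = 0.10, seed: int = 0,
                 epochs: int | None = None, options=None) -> AdaptationResult:
    """Supervised domain adaptation under k-fold cross-validation.

    The external cohort is split into k label-stratified folds; each fold in
    turn is the ``tune_frac`` tuning set (10% when k=10) and the remaining
    subjects form the test set, so every subject is tested exactly k-1
    times. Deep models fine-tune from their source weights on the full
    tuning split, with early stopping monitored on that same split (the
    tuning set is all the adaptation data there is; a further sub-split
    would leave too few subjects on either side); ``epochs=0`` is a no-op
    and reproduces the transfer scores. Classical models are refit from
    scratch on the tuning split (no warm start exists) and the result is
    flagged accordingly. Folds whose tuning split lacks a class are
    skipped and logged.
    """
    if abs(k * tune_frac - 1.0) > 1e-9:
        raise ValueError("tune_frac must equal 1/k so folds tile the cohort")
    y_ext = np.asarray(y_ext, int)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xDA]))
    folds = _stratified_folds(y_ext, k, rng)
    all_idx = np.arange(y_ext.size)

    fold_aurocs, skipped = [], []
    refit = not model.is_deep
    for f, tune_idx in enumerate(folds):
        test_idx = np.setdiff1d(all_idx, tune_idx)
        y_tune = y_ext[tune_idx]
        if len(np.unique(y_tune)) < 2:
            skipped.append(f)
            continue
        X_tune = X_ext.rows(tune_idx)
        X_test = X_ext.rows(test_idx)
        if model.is_deep:
            tuned = zoo.TrainedModel(
                family=model.family, config=model.config,
                estimator=model.estimator.clone(),
                feature_signature=model.feature_signature,
                n_rois=model.n_rois, edge_columns=model.edge_columns,
                covariate_columns=model.covariate_columns)
            from .zoo import _as_matrix, _brainnet_pack  # internal reuse
            df, _, _ = _as_matrix(X_tune)
            if model.n_rois is not None:
                df = _brainnet_pack(df, model.n_rois, model.edge_columns,
                                    model.covariate_columns)
            yt = y_tune.astype(float)
            tuned.estimator.fine_tune(df, yt, validation=(df, yt),
                                      epochs=epochs, seed=seed + 17 + f)
        else:
            tuned = zoo.fit(model.config, X_tune, y_tune, options=options)
        fold_aurocs.append(float(compute_auroc(zoo.predict_score(tuned, X_test),
                                               y_ext[test_idx])))
    return AdaptationResult(fold_auroc=fold_aurocs,
                            mean_auroc=float(np.mean(fold_aurocs)) if fold_aurocs else float("nan"),
                            sd_auroc=float(np.std(fold_aurocs)) if fold_aurocs else float("nan"),
                            tune_frac=tune_frac, refit_from_scratch=refit,
                            skipped_folds=skipped)


def importance_concordance(pre: list[ImportanceRecord], post: list[ImportanceRecord],
                           z_threshold: float = 3.0,
                           rule: str = "union") -> ConcordanceResult:
    """Pearson/Spearman correlation of mean importances over significant edges.

    Significance is z above ``z_threshold`` in either set ('union', the
    default) or in both ('intersection'); the alternative rule's numbers
    are reported alongside.
    """
    if rule not in ("union", "intersection"):
        raise ValueError("rule must be 'union' or 'intersection'")
    pre_map = {r.feature: r for r in pre}
    post_map = {r.feature: r for r in post}
    if set(pre_map) != set(post_map):
        raise ValueError("pre and post records do not share a feature namespace")

    def _subset(how: str) -> list:
        names = []
        for name in pre_map:
            a = pre_map[name].z > z_threshold
            b = post_map[name].z > z_threshold
            if (a or b) if how == "union" else (a and b):
                names.append(name)
        return names

    def _corr(names: list):
        if len(names) < 3:
            return float("nan"), float("nan"), True
        x = np.array([pre_map[n].mean_importance for n in names])
        yv = np.array([post_map[n].mean_importance for n in names])
        return (float(stats.pearsonr(x, yv).statistic),
                float(stats.spearmanr(x, yv).statistic), False)

    names = _subset(rule)
    pr, sp, flagged = _corr(names)
    other = "intersection" if rule == "union" else "union"
    o_names = _subset(other)
    o_pr, o_sp, o_flag = _corr(o_names)
    return ConcordanceResult(pearson=pr, spearman=sp, n_features=len(names),
                             features=names, rule=rule, flagged=flagged,
                             alternative={"rule": other, "pearson": o_pr,
                                          "spearman": o_sp,
                                          "n_features": len(o_names),
                                          "flagged": o_flag})
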