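"""Permutation feature importance, a label-permutation null, and consensus
biomarker ranking.

Importance of a feature is the drop in held-out AUROC when that feature's
column is shuffled (64 repetitions). Significance is calibrated against a
null built by refitting the model on permuted labels: each refit
contributes one null mean per feature, and the observed mean importance is
tested against those refit means with a one-tailed t statistic, then
corrected with Benjamini-Yekutieli FDR. Consensus across the top models
flags features that rank highly everywhere.
"""

import numpy as np

import connsearch as cs
from connsearch import zoo
from connsearch.search import make_split_plan

spec = cs.CohortSpec(n_subjects=160, n_rois=10, n_timepoints=150, n_anat=5,
                     planted_edges=((0, 1, 0.35), (2, 5, 0.35)), seed=11)
subjects, truth = cs.generate_cohort(spec)
y = np.array([s.diagnosis for s in subjects])
sex = np.array([s.sex for s in subjects])
plan = make_split_plan(y, sex, seed=0)
pipe = cs.FeaturePipeline(subjects, "functional",
                          include_covariates=False).fit(plan.train_idx)
X_train, X_test = pipe.transform(plan.train_idx), pipe.transform(plan.test_idx)
y_train, y_test = y[plan.train_idx], y[plan.test_idx]

# fit a few models with different regularization, rank features per model
configs = [zoo.ModelConfig("logistic_ridge", {"C": c, "max_iter": 10000}, i, 0)
           for i, c in enumerate([0.1, 1.0, 10.0])]
models = [zoo.fit(cfg, X_train, y_train) for cfg in configs]
per_model = [cs.permutation_importance(m, X_test, y_test, seed=3)
             for m in models]

# calibrated significance for the middle model
null = cs.build_null(configs[1], X_train, y_train, X_test, y_test,
                     n_label_perms=20, seed=3)
sig = cs.significance(per_model[1], null, fdr_rate=0.01)
n_sig = sum(bool(r.significant) for r in sig)
print(f"{n_sig} of {len(sig)} features significant at BY 1%")

# consensus across the three models, with univariate direction marks
consensus = cs.consensus_rank(per_model, top_k=10, X=X_test, y=y_test)
print("\ntop consensus features (star = z>=3 in all models):")
for c in consensus:
    flag = "*" if c.star else ("+" if c.diamond else " ")
    planted = " <- planted" if c.feature in truth.edge_names else ""
    print(f"  {flag} {c.feature:<12} median z {c.median_z:6.2f} "
          f"direction {c.direction}{planted}")
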