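"""End-to-end orchestration: one YAML/JSON config drives cohort simulation,
feature extraction, model search, biomarker importance, landscape analysis
and external validation, with a manifest sufficient to re-execute the run
bit-identically.

Stages communicate only through serialized artifacts in the output
directory (split_plan.json, search_records.jsonl, result_matrix.csv,
importance/consensus tables, transfer/adaptation reports), so any stage
can be rerun or replaced independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import zoo
from .cohort import CohortShift, CohortSpec, generate_cohort, generate_external_cohort, save_cohort
from .external import build_external_features, domain_adapt, importance_concordance, transfer_evaluate
from .importance import (build_null, consensus_rank, importance_table,
                         permutation_importance, significance)
from .metrics import compute_auroc
from .nn import TrainingOptions
from .search import landscape_kde, make_split_plan, run_search

logger = logging.getLogger("connsearch")

ALL_STAGES = ("cohort", "search", "importance", "landscape", "external", "report")
__version__ = "0.1.0"

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "render_reports", "ALL_STAGES"]


@dataclass
class RunConfig:
    out_dir: str
    cohort: dict = field(default_factory=dict)          # CohortSpec kwargs
    cohort_dir: str | None = None                       # load instead of simulate
    families: list = field(default_factory=lambda: ["logistic_ridge", "svm_linear", "dfnn"])
    feature_modes: list = field(default_factory=lambda: ["functional", "anatomical", "combined"])
    n_configs: int = 50
    master_seed: int = 0
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    embed_scope: str = "fold"
    importance: dict = field(default_factory=dict)      # family, feature_set, n_reps, ...
    landscape: dict = field(default_factory=dict)       # family, dims, quantile
    external_shift: dict = field(default_factory=dict)  # CohortShift kwargs
    training: dict = field(default_factory=dict)        # TrainingOptions kwargs
    save_cohort_files: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> None:
        """Fail fast: every enabled stage's inputs must be resolvable."""
        for st in self.stages:
            if st not in ALL_STAGES:
                raise ValueError(f"unknown stage '{st}'")
        for fam in self.families:
            if fam not in zoo.FAMILIES:
                raise ValueError(f"unknown model family '{fam}'")
        if self.cohort_dir is None:
            CohortSpec(**{**self.cohort, "seed": 0})   # raises on bad spec
        elif not os.path.isdir(self.cohort_dir):
            raise ValueError(f"cohort_dir '{self.cohort_dir}' does not exist")
        needs_search = {"search", "importance", "landscape", "external"}
        if needs_search & set(self.stages) and "cohort" not in self.stages \
                and self.cohort_dir is None:
            raise ValueError("downstream stages need either the cohort stage "
                             "or a cohort_dir")
        imp_fam = self.importance.get("family", "dfnn" if "dfnn" in self.families
                                      else self.families[0])
        if "importance" in self.stages and imp_fam not in self.families:
            raise ValueError(f"importance family '{imp_fam}' is not searched")


@dataclass
class RunManifest:
    config: dict
    version: str
    seeds: dict
    stage_checksums: dict
    stage_seconds: dict

    def to_json(self) -> str:
        return json.dumps({"config": self.config, "version": self.version,
                           "seeds": self.seeds,
                           "stage_checksums": self.stage_checksums,
                           "stage_seconds": self.stage_seconds}, indent=1,
                          sort_keys=True)


def derive_seeds(master_seed: int) -> dict:
    """Expand one master seed into named per-stage seeds (all < 2**31)."""
    names = ("cohort", "split", "search", "importance", "external")
    return {name: int(np.random.SeedSequence([master_seed, i]).generate_state(1)[0]
                      % (2 ** 31))
            for i, name in enumerate(names)}


def _file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in order and write the run manifest.

    Two runs with the same config produce identical manifests up to
    wall-clock times.
    """
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    seeds = derive_seeds(config.master_seed)
    options = TrainingOptions(**config.training) if config.training else None
    checksums: dict = {}
    seconds: dict = {}
    artifacts: dict = {}

    def _track(stage, *paths):
        checksums.setdefault(stage, {})
        for p in paths:
            checksums[stage][os.path.basename(p)] = _file_checksum(p)

    # ---- cohort ------------------------------------------------------------
    t0 = time.time()
    if config.cohort_dir is not None:
        from .cohort import load_cohort
        cohort, truth = load_cohort(config.cohort_dir)
        spec = None
        logger.info("loaded cohort of %d subjects from %s", len(cohort), config.cohort_dir)
    else:
        spec = CohortSpec(**{**config.cohort, "seed": seeds["cohort"]})
        cohort, truth = generate_cohort(spec)
        logger.info("simulated cohort: n=%d, R=%d, seed=%d", spec.n_subjects,
                    spec.n_rois, seeds["cohort"])
        if "cohort" in config.stages and config.save_cohort_files:
            cdir = os.path.join(out, "cohort")
            save_cohort(cohort, truth, cdir, spec=spec)
            _track("cohort", os.path.join(cdir, "subjects.csv"),
                   os.path.join(cdir, "ground_truth.json"))
    y = np.array([s.diagnosis for s in cohort], int)
    sex = np.array([s.sex for s in cohort], int)
    seconds["cohort"] = time.time() - t0

    plan = make_split_plan(y, sex, seed=seeds["split"])
    plan_path = os.path.join(out, "split_plan.json")
    plan.save(plan_path)
    _track("cohort", plan_path)

    # ---- search ------------------------------------------------------------
    result = None
    if {"search", "importance", "landscape", "external"} & set(config.stages):
        t0 = time.time()
        logger.info("search: %d families x %d feature sets x %d configs (seed %d)",
                    len(config.families), len(config.feature_modes),
                    config.n_configs, seeds["search"])
        result = run_search(cohort, config.families, config.feature_modes, plan,
                            n_configs=config.n_configs, seed=seeds["search"],
                            out_dir=out, embed_scope=config.embed_scope,
                            options=options)
        mpath = os.path.join(out, "result_matrix.csv")
        result.matrix_to_csv(mpath)
        _track("search", mpath, os.path.join(out, "search_records.jsonl"))
        seconds["search"] = time.time() - t0
        logger.info("search done: plan checksum %s", plan.checksum[:12])

    # ---- importance ----------------------------------------------------------
    imp_artifacts = {}
    if "importance" in config.stages:
        t0 = time.time()
        icfg = config.importance
        family = icfg.get("family", "dfnn" if "dfnn" in config.families
                          else config.families[0])
        mode = icfg.get("feature_set",
                        "functional" if "functional" in config.feature_modes
                        else config.feature_modes[0])
        n_top = int(icfg.get("top_models", 5))
        n_reps = int(icfg.get("n_reps", 64))
        n_label_perms = int(icfg.get("n_label_perms", 20))
        fdr_rate = float(icfg.get("fdr_rate", 0.01))
        top_k = int(icfg.get("top_k", 15))

        combo = [r for r in result.records
                 if r.family == family and r.feature_set == mode
                 and not r.selected and r.mean_cv_auroc is not None]
        combo.sort(key=lambda r: (-r.mean_cv_auroc, r.draw_index))
        top = combo[:n_top]
        pipe = result.pipelines[mode]
        X_train = pipe.transform(plan.train_idx)
        X_test = pipe.transform(plan.test_idx)
        y_train, y_test = y[plan.train_idx], y[plan.test_idx]

        per_model = []
        models = []
        from .search import fit_on_training_set
        for rec in top:
            m = fit_on_training_set(rec.config, X_train, y_train,
                                    seed=seeds["search"], options=options)
            models.append(m)
            per_model.append(permutation_importance(m, X_test, y_test,
                                                    n_reps=n_reps,
                                                    seed=seeds["importance"]))
        median_idx = len(top) // 2
        null = build_null(top[median_idx].config, X_train, y_train, X_test, y_test,
                          n_label_perms=n_label_perms, n_reps=n_reps,
                          seed=seeds["importance"], options=options)
        sig = significance(per_model[median_idx], null, fdr_rate=fdr_rate)
        consensus = consensus_rank(per_model, top_k=top_k, X=X_test, y=y_test)

        itab = importance_table(sig)
        ipath = os.path.join(out, "importance_table.csv")
        itab.to_csv(ipath, index=False)
        cpath = os.path.join(out, "consensus_top15.csv")
        pd.DataFrame([{"feature": c.feature, "median_z": c.median_z,
                       "star": c.star, "diamond": c.diamond,
                       "direction": c.direction, "direction_p": c.direction_p,
                       **{f"z_model_{i}": z for i, z in enumerate(c.per_model_z)}}
                      for c in consensus]).to_csv(cpath, index=False)
        _track("importance", ipath, cpath)
        seconds["importance"] = time.time() - t0
        imp_artifacts = {"models": models, "per_model": per_model, "family": family,
                         "mode": mode, "top": top, "pipe": pipe}
        logger.info("importance: %d features, %d significant at BY %.0f%%",
                    len(sig), sum(bool(r.significant) for r in sig), fdr_rate * 100)

    # ---- landscape -----------------------------------------------------------
    if "landscape" in config.stages:
        t0 = time.time()
        lcfg = config.landscape
        family = lcfg.get("family", "dfnn" if "dfnn" in config.families
                          else config.families[0])
        dims = lcfg.get("dims")
        if dims is None:
            space = zoo.default_spaces()[family]
            dims = list(space)[:2]
        recs = [r for r in result.records if r.family == family]
        if dims and recs:
            est = landscape_kde(recs, dims, quantile=float(lcfg.get("quantile", 0.2)))
            ppath = os.path.join(out, "landscape_peaks.csv")
            est.peak_table().to_csv(ppath, index=False)
            paths = [ppath]
            if not est.degenerate:
                gpath = os.path.join(out, "landscape_grid.csv")
                flat = {f"{d}": np.stack(np.meshgrid(*[est.grid[dd] for dd in est.dims],
                                                     indexing="ij"))[a].ravel()
                        for a, d in enumerate(est.dims)}
                flat["top_density"] = est.top_density.ravel()
                flat["bottom_density"] = est.bottom_density.ravel()
                pd.DataFrame(flat).to_csv(gpath, index=False)
                paths.append(gpath)
            _track("landscape", *paths)
        seconds["landscape"] = time.time() - t0

    # ---- external ------------------------------------------------------------
    if "external" in config.stages:
        t0 = time.time()
        if spec is None:
            raise ValueError("external stage requires a simulated source cohort spec")
        shift = CohortShift(**{**config.external_shift,
                               "seed": config.external_shift.get("seed",
                                                                 seeds["external"])})
        ext_cohort, _ = generate_external_cohort(spec, shift)
        if imp_artifacts:
            models = imp_artifacts["models"]
            pipe = imp_artifacts["pipe"]
            mode = imp_artifacts["mode"]
        else:
            mode = config.feature_modes[0]
            pipe = result.pipelines[mode]
            models = [m for (fam, md), m in result.best_models.items() if md == mode]
        X_ext, y_ext = build_external_features(pipe, ext_cohort)
        transfer = transfer_evaluate(models, X_ext, y_ext, pipeline=pipe,
                                     expected_checksum=pipe.checksum)
        tpath = os.path.join(out, "transfer_report.csv")
        pd.DataFrame({"model": list(range(len(models))),
                      "auroc": transfer.per_model_auroc}).to_csv(tpath, index=False)

        best_model = models[int(np.argmax(transfer.per_model_auroc))]
        adapt = domain_adapt(best_model, X_ext, y_ext, seed=seeds["external"],
                             options=options)
        apath = os.path.join(out, "adaptation_report.csv")
        pd.DataFrame({"fold": list(range(len(adapt.fold_auroc))),
                      "auroc": adapt.fold_auroc}).to_csv(apath, index=False)

        paths = [tpath, apath]
        if imp_artifacts:
            # pre/post importance concordance on the externally tuned model
            pre = permutation_importance(best_model, X_ext, y_ext,
                                         seed=seeds["external"],
                                         n_reps=int(config.importance.get("n_reps", 64)))
            tuned = dataclasses.replace(best_model,
                                        estimator=best_model.estimator.clone()
                                        if best_model.is_deep else best_model.estimator)
            if best_model.is_deep:
                rng = np.random.default_rng(np.random.SeedSequence([seeds["external"], 9]))
                tune_idx = rng.permutation(y_ext.size)[:max(4, y_ext.size // 10)]
                from .zoo import _as_matrix
                dd, _, _ = _as_matrix(X_ext.rows(tune_idx))
                tuned.estimator.fine_tune(dd, y_ext[tune_idx].astype(float),
                                          seed=seeds["external"])
            post = permutation_importance(tuned, X_ext, y_ext,
                                          seed=seeds["external"],
                                          n_reps=int(config.importance.get("n_reps", 64)))
            conc = importance_concordance(pre, post)
            cpath = os.path.join(out, "concordance.json")
            with open(cpath, "w") as fh:
                json.dump({"pearson": conc.pearson, "spearman": conc.spearman,
                           "n_features": conc.n_features, "rule": conc.rule,
                           "flagged": conc.flagged,
                           "alternative": conc.alternative}, fh, indent=1)
            paths.append(cpath)
        _track("external", *paths)
        seconds["external"] = time.time() - t0

    # ---- report ---------------------------------------------------------------
    if "report" in config.stages:
        t0 = time.time()
        rpaths = render_reports(out)
        _track("report", *rpaths)
        seconds["report"] = time.time() - t0

    manifest = RunManifest(config=config.to_dict(), version=__version__,
                           seeds=seeds, stage_checksums=checksums,
                           stage_seconds=seconds)
    tmp = os.path.join(out, "manifest.json.tmp")
    with open(tmp, "w") as fh:
        fh.write(manifest.to_json())
    os.replace(tmp, os.path.join(out, "manifest.json"))
    return manifest


def render_reports(out_dir, plots: bool = False) -> list:
    """Assemble human-readable summaries from the stage artifacts.

    Missing stage outputs are skipped with a message in the summary.
    """
    lines = ["# Run summary", ""]
    written = []
    mpath = os.path.join(out_dir, "result_matrix.csv")
    if os.path.exists(mpath):
        mat = pd.read_csv(mpath, index_col=0)
        lines += ["## Test AUROC (family x feature set)", "",
                  mat.round(3).to_markdown(), ""]
    else:
        lines.append("result matrix missing: search stage not run\n")
    cpath = os.path.join(out_dir, "consensus_top15.csv")
    if os.path.exists(cpath):
        cons = pd.read_csv(cpath)
        lines += ["## Consensus biomarkers", "",
                  cons[["feature", "median_z", "star", "diamond", "direction"]]
                  .round(3).to_markdown(index=False), ""]
    else:
        lines.append("consensus table missing: importance stage not run\n")
    ppath = os.path.join(out_dir, "landscape_peaks.csv")
    if os.path.exists(ppath):
        peaks = pd.read_csv(ppath)
        lines += ["## Hyperparameter landscape peaks", "",
                  peaks.to_markdown(index=False), ""]
    spath = os.path.join(out_dir, "summary.md")
    with open(spath, "w") as fh:
        fh.write("\n".join(lines))
    written.append(spath)
    if plots and os.path.exists(mpath):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        mat = pd.read_csv(mpath, index_col=0)
        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.imshow(mat.to_numpy(float), cmap="Greens", vmin=0.4, vmax=1.0)
        ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=45)
        ax.set_yticks(range(mat.shape[0]), mat.index)
        fig.colorbar(im, label="test AUROC")
        fig.tight_layout()
        fpath = os.path.join(out_dir, "result_matrix.png")
        fig.savefig(fpath, dpi=120)
        plt.close(fig)
        written.append(fpath)
    return written
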