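"""Twelve-family model zoo behind one train/score contract.

Three linear classical families (linear SVM, lasso- and ridge-penalized
logistic regression), six nonlinear classical families (naive Bayes,
random forest, extremely random trees, adaptive boosting, gradient
boosting, Gaussian-kernel SVM) and three deep families (dense feedforward
net, bidirectional LSTM, BrainNetCNN-style connectivity net). Each family
carries its published random-search space; classical learners delegate to
scikit-learn, deep learners to the in-package autodiff classifiers.

The BrainNetCNN family accepts only square connectivity input (edge
features reshaped back into R x R matrices); giving it anatomical
features is an input-compatibility error.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import (AdaBoostClassifier, ExtraTreesClassifier,
                              GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC, LinearSVC

from .features import FeatureMatrix, unvectorize_upper
from .nn import (BiLSTMClassifier, BrainNetCNNClassifier, DFNNClassifier,
                 TrainingOptions)

__all__ = [
    "Dimension", "HyperparameterSpace", "ModelConfig", "TrainedModel",
    "FamilySpec", "FAMILIES", "default_spaces", "sample_config", "fit",
    "predict_score", "InputCompatibilityError", "SignatureMismatchError",
    "CATEGORY_OF", "DEEP_FAMILIES",
]


class InputCompatibilityError(ValueError):
    pass


class SignatureMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class Dimension:
    lo: float
    hi: float
    scale: str = "uniform"       # "uniform" | "log"
    dtype: str = "float"         # "float" | "int"

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("dimension requires lo < hi")
        if self.scale == "log" and self.lo <= 0:
            raise ValueError("log scale requires positive bounds")

    def sample(self, rng: np.random.Generator):
        if self.scale == "log":
            v = float(np.exp(rng.uniform(math.log(self.lo), math.log(self.hi))))
        else:
            v = float(rng.uniform(self.lo, self.hi))
        if self.dtype == "int":
            return int(np.clip(round(v), self.lo, self.hi))
        return v

    def contains(self, v) -> bool:
        return self.lo <= v <= self.hi


HyperparameterSpace = dict  # name -> Dimension


def default_spaces(adaboost_conventional_rate: bool = False) -> dict[str, HyperparameterSpace]:
    """Published random-search ranges for every family.

    Integer dimensions spanning two or more decades are drawn log-uniformly
    (tree/boosting estimator counts); others uniformly. The adaptive
    boosting learning-rate range [5, 50] is unusually large; pass
    ``adaboost_conventional_rate=True`` for a conventional [0.01, 2] range
    instead.
    """
    est = Dimension(50, 5e3, "log", "int")
    max_nodes = Dimension(5, 50, "uniform", "int")
    max_iter = Dimension(1e4, 1e5, "uniform", "int")
    deep_common = {
        "hidden_layers": Dimension(1, 3, "uniform", "int"),
        "initial_width": Dimension(16, 256, "uniform", "int"),
        "dropout": Dimension(0.1, 0.6),
        "l2": Dimension(1e-4, 2e-2, "log"),
    }
    ada_rate = Dimension(0.01, 2.0, "log") if adaboost_conventional_rate else Dimension(5, 50)
    return {
        "naive_bayes": {},
        "random_forest": {"estimators": est, "max_nodes": max_nodes},
        "extra_trees": {"estimators": est, "max_nodes": max_nodes},
        "adaboost": {"estimators": est, "learning_rate": ada_rate},
        "gradient_boosting": {"estimators": est,
                              "learning_rate": Dimension(0.1, 0.9),
                              "max_depth": Dimension(1, 10, "uniform", "int"),
                              "subsample": Dimension(0.2, 0.8),
                              "cols_per_tree": Dimension(0.2, 1.0)},
        "svm_gaussian": {"C": Dimension(1e-4, 1e5, "log"),
                         "max_iter": max_iter,
                         "gamma": Dimension(1e-2, 1e2, "log")},
        "svm_linear": {"C": Dimension(1e-4, 1e5, "log"), "max_iter": max_iter},
        "logistic_lasso": {"C": Dimension(1e-4, 1e4, "log"), "max_iter": max_iter},
        "logistic_ridge": {"C": Dimension(1e-4, 1e4, "log"), "max_iter": max_iter},
        "dfnn": dict(deep_common),
        "lstm": dict(deep_common),
        "brainnet_cnn": {"hidden_layers": Dimension(0, 2, "uniform", "int"),
                         "initial_width": Dimension(16, 64, "uniform", "int"),
                         "dropout": Dimension(0.1, 0.6),
                         "leaky_slope": Dimension(0.1, 0.5)},
    }


def spaces_to_json(spaces: dict[str, HyperparameterSpace]) -> str:
    return json.dumps({fam: {name: {"lo": d.lo, "hi": d.hi, "scale": d.scale,
                                    "dtype": d.dtype}
                             for name, d in sp.items()}
                       for fam, sp in spaces.items()}, indent=1)


def spaces_from_json(text: str) -> dict[str, HyperparameterSpace]:
    raw = json.loads(text)
    return {fam: {name: Dimension(**dd) for name, dd in sp.items()}
            for fam, sp in raw.items()}


@dataclass(frozen=True)
class FamilySpec:
    name: str
    category: str               # linear | nonlinear | deep
    square_input: bool = False  # accepts only square connectivity input


FAMILIES: dict[str, FamilySpec] = {
    "naive_bayes": FamilySpec("naive_bayes", "nonlinear"),
    "random_forest": FamilySpec("random_forest", "nonlinear"),
    "extra_trees": FamilySpec("extra_trees", "nonlinear"),
    "adaboost": FamilySpec("adaboost", "nonlinear"),
    "gradient_boosting": FamilySpec("gradient_boosting", "nonlinear"),
    "svm_gaussian": FamilySpec("svm_gaussian", "nonlinear"),
    "svm_linear": FamilySpec("svm_linear", "linear"),
    "logistic_lasso": FamilySpec("logistic_lasso", "linear"),
    "logistic_ridge": FamilySpec("logistic_ridge", "linear"),
    "dfnn": FamilySpec("dfnn", "deep"),
    "lstm": FamilySpec("lstm", "deep"),
    "brainnet_cnn": FamilySpec("brainnet_cnn", "deep", square_input=True),
}

CATEGORY_OF = {name: spec.category for name, spec in FAMILIES.items()}
DEEP_FAMILIES = tuple(n for n, s in FAMILIES.items() if s.category == "deep")


@dataclass(frozen=True)
class ModelConfig:
    family: str
    values: dict
    draw_index: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return {"family": self.family, "values": dict(self.values),
                "draw_index": self.draw_index, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(d["family"], dict(d["values"]), d["draw_index"], d["seed"])


def sample_config(family: str, rng: np.random.Generator, draw_index: int = 0,
                  spaces: dict | None = None) -> ModelConfig:
    """Draw one configuration, each dimension independently."""
    space = (spaces or default_spaces())[family]
    values = {name: dim.sample(rng) for name, dim in space.items()}
    seed = int(rng.integers(2 ** 31))
    return ModelConfig(family=family, values=values, draw_index=draw_index, seed=seed)


# ---------------------------------------------------------------------------
# Fitting and scoring
# ---------------------------------------------------------------------------

def _feature_signature(names) -> str:
    return hashlib.sha256("\x1f".join(names).encode()).hexdigest()


@dataclass
class TrainedModel:
    family: str
    config: ModelConfig
    estimator: object
    feature_signature: str
    n_rois: int | None = None          # set for square-input families
    edge_columns: np.ndarray | None = None
    covariate_columns: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def is_deep(self) -> bool:
        return CATEGORY_OF[self.family] == "deep"


def _as_matrix(X) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(X, FeatureMatrix):
        return X.data, X.names, X.kinds
    X = np.asarray(X, float)
    names = [f"f{i}" for i in range(X.shape[1])]
    return X, names, ["edge"] * X.shape[1]


def _brainnet_prepare(data, names, kinds):
    kinds = np.asarray(kinds)
    if np.any(kinds == "anat"):
        raise InputCompatibilityError(
            "brainnet_cnn accepts only square connectivity input; anatomical "
            "features are not supported")
    edge_cols = np.flatnonzero(kinds == "edge")
    if edge_cols.size == 0:
        raise InputCompatibilityError("brainnet_cnn requires edge features")
    R = int(round((1 + math.sqrt(1 + 8 * edge_cols.size)) / 2))
    if R * (R - 1) // 2 != edge_cols.size:
        raise InputCompatibilityError(
            f"{edge_cols.size} edge columns do not form a full upper triangle")
    cov_cols = np.flatnonzero(kinds == "covariate")
    return R, edge_cols, cov_cols


def _brainnet_pack(data, R, edge_cols, cov_cols) -> np.ndarray:
    mats = np.stack([unvectorize_upper(row, R) for row in data[:, edge_cols]])
    cov = data[:, cov_cols] if cov_cols.size else None
    return BrainNetCNNClassifier.pack_input(mats, cov)


def _build_estimator(family: str, v: dict, seed: int, n_features: int,
                     options: TrainingOptions | None, n_rois: int | None = None,
                     n_covariates: int = 0):
    if family == "naive_bayes":
        return GaussianNB()
    if family == "random_forest":
        return RandomForestClassifier(n_estimators=v["estimators"],
                                      max_leaf_nodes=v["max_nodes"],
                                      random_state=seed, n_jobs=1)
    if family == "extra_trees":
        return ExtraTreesClassifier(n_estimators=v["estimators"],
                                    max_leaf_nodes=v["max_nodes"],
                                    random_state=seed, n_jobs=1)
    if family == "adaboost":
        return AdaBoostClassifier(n_estimators=v["estimators"],
                                  learning_rate=v["learning_rate"],
                                  random_state=seed)
    if family == "gradient_boosting":
        return GradientBoostingClassifier(n_estimators=v["estimators"],
                                          learning_rate=v["learning_rate"],
                                          max_depth=v["max_depth"],
                                          subsample=v["subsample"],
                                          max_features=v["cols_per_tree"],
                                          random_state=seed)
    if family == "svm_gaussian":
        return SVC(kernel="rbf", C=v["C"], gamma=v["gamma"],
                   max_iter=v["max_iter"], random_state=seed)
    if family == "svm_linear":
        return LinearSVC(C=v["C"], max_iter=v["max_iter"], dual="auto",
                         random_state=seed)
    if family == "logistic_lasso":
        return LogisticRegression(penalty="l1", solver="liblinear", C=v["C"],
                                  max_iter=v["max_iter"], random_state=seed)
    if family == "logistic_ridge":
        return LogisticRegression(penalty="l2", solver="lbfgs", C=v["C"],
                                  max_iter=v["max_iter"])
    if family == "dfnn":
        return DFNNClassifier(n_features=n_features, hidden_layers=v["hidden_layers"],
                              initial_width=v["initial_width"], dropout=v["dropout"],
                              l2=v["l2"], seed=seed, options=options)
    if family == "lstm":
        return BiLSTMClassifier(n_features=n_features, hidden_layers=v["hidden_layers"],
                                initial_width=v["initial_width"], dropout=v["dropout"],
                                l2=v["l2"], seed=seed, options=options)
    if family == "brainnet_cnn":
        return BrainNetCNNClassifier(n_rois=n_rois, n_covariates=n_covariates,
                                     hidden_layers=v["hidden_layers"],
                                     initial_width=v["initial_width"],
                                     dropout=v["dropout"], leaky_slope=v["leaky_slope"],
                                     l2=0.0, seed=seed, options=options)
    raise KeyError(f"unknown model family '{family}'")


def fit(config: ModelConfig, X, y, validation=None,
        options: TrainingOptions | None = None) -> TrainedModel:
    """Train one configuration; deterministic given ``config.seed``.

    ``validation`` (X_val, y_val) is used by the deep families for early
    stopping and ignored by the classical ones.
    """
    family = config.family
    if family not in FAMILIES:
        raise KeyError(f"unknown model family '{family}'")
    data, names, kinds = _as_matrix(X)
    if not np.all(np.isfinite(data)):
        raise ValueError("feature matrix contains non-finite values")
    y = np.asarray(y)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")

    n_rois = edge_cols = cov_cols = None
    if FAMILIES[family].square_input:
        n_rois, edge_cols, cov_cols = _brainnet_prepare(data, names, kinds)
        train_in = _brainnet_pack(data, n_rois, edge_cols, cov_cols)
    else:
        train_in = data

    est = _build_estimator(family, config.values, config.seed, train_in.shape[1],
                           options, n_rois=n_rois,
                           n_covariates=0 if cov_cols is None else int(cov_cols.size))

    if CATEGORY_OF[family] == "deep":
        val = None
        if validation is not None:
            Xv, yv = validation
            vdata, _, _ = _as_matrix(Xv)
            if FAMILIES[family].square_input:
                vdata = _brainnet_pack(vdata, n_rois, edge_cols, cov_cols)
            val = (vdata, np.asarray(yv, float))
        est.fit(train_in, y.astype(float), validation=val)
    else:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # SVM/liblinear iteration caps
            est.fit(train_in, y)

    return TrainedModel(family=family, config=config, estimator=est,
                        feature_signature=_feature_signature(names),
                        n_rois=n_rois, edge_columns=edge_cols,
                        covariate_columns=cov_cols)


def predict_score(model: TrainedModel, X) -> np.ndarray:
    """Continuous per-subject score, higher = more case-like (class 1)."""
    data, names, kinds = _as_matrix(X)
    if _feature_signature(names) != model.feature_signature:
        raise SignatureMismatchError(
            "feature namespace does not match the one this model was trained on")
    if model.n_rois is not None:
        data = _brainnet_pack(data, model.n_rois, model.edge_columns,
                              model.covariate_columns)
    est = model.estimator
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(data), float).reshape(-1)
    return np.asarray(est.predict_proba(data)[:, 1], float)
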