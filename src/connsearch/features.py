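"""Connectivity feature extraction: covariances, tangent-space embedding,
vectorization, covariate assembly and training-set-frozen standardization.

A subject's ROI timeseries is summarized by a shrunk covariance matrix
(symmetric positive definite, SPD). The cohort of SPD matrices is embedded
in the tangent space at their Riemannian (affine-invariant) geometric mean
G: each matrix C maps to ``logm(G^{-1/2} C G^{-1/2})``, whose strict upper
triangle forms the functional "edge" features. The reference G and the
per-feature scaler are always estimated on a designated training
population and then frozen, so external cohorts are projected through the
*source* geometry — the contract that makes transfer evaluation honest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "estimate_covariance",
    "geometric_mean",
    "GeometricMeanError",
    "TangentReference",
    "tangent_embed",
    "vectorize_upper",
    "unvectorize_upper",
    "FeatureMatrix",
    "assemble_feature_set",
    "Scaler",
    "FeaturePipeline",
]

_SYM_TOL = 1e-8


class GeometricMeanError(RuntimeError):
    """Fixed-point iteration for the geometric mean failed to converge."""

    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


# ---------------------------------------------------------------------------
# SPD primitives (eigendecomposition-based)
# ---------------------------------------------------------------------------

def _check_spd(M: np.ndarray, name: str = "matrix") -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square, got shape {M.shape}")
    if np.max(np.abs(M - M.T)) > 1e-10 * max(1.0, np.max(np.abs(M))):
        raise ValueError(f"{name} is not symmetric")
    return 0.5 * (M + M.T)


def _eig_fun(M: np.ndarray, fun) -> np.ndarray:
    w, V = np.linalg.eigh(0.5 * (M + M.T))
    out = (V * fun(w)) @ V.T
    return 0.5 * (out + out.T)


def logm_spd(M: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD matrix via eigendecomposition."""
    w, V = np.linalg.eigh(0.5 * (np.asarray(M, float) + np.asarray(M, float).T))
    if w.min() <= 0:
        raise ValueError(f"matrix is not positive definite (min eigenvalue {w.min():.3g})")
    out = (V * np.log(w)) @ V.T
    return 0.5 * (out + out.T)


def expm_sym(M: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix via eigendecomposition."""
    return _eig_fun(M, np.exp)


def sqrtm_spd(M: np.ndarray) -> np.ndarray:
    return _eig_fun(M, np.sqrt)


def invsqrtm_spd(M: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(0.5 * (M + M.T))
    if w.min() <= 0:
        raise ValueError("matrix is not positive definite")
    out = (V * (w ** -0.5)) @ V.T
    return 0.5 * (out + out.T)


# ---------------------------------------------------------------------------
# Covariance estimation
# ---------------------------------------------------------------------------

def estimate_covariance(timeseries, shrinkage: float | str = "auto") -> np.ndarray:
    """Shrunk covariance of a T x R timeseries matrix.

    The empirical covariance S is blended toward its own diagonal,
    ``(1 - lam) * S + lam * diag(S)``, which is positive definite for any
    lam > 0. ``shrinkage='auto'`` uses the analytic (Ledoit-Wolf-style)
    intensity for the diagonal target, estimated from the sampling variance
    of the off-diagonal entries; a float in [0, 1] fixes lam directly.
    """
    X = np.asarray(timeseries, dtype=float)
    if X.ndim != 2:
        raise ValueError("timeseries must be 2-D (T timepoints x R ROIs)")
    T, R = X.shape
    if T < 2:
        raise ValueError("need at least 2 timepoints")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = int(np.flatnonzero(sds == 0)[0])
        raise ValueError(f"ROI {bad} has a constant timeseries (zero variance)")

    Xc = X - X.mean(axis=0)
    S = (Xc.T @ Xc) / (T - 1)

    if shrinkage == "auto":
        # analytic intensity for the diagonal target: sum of estimated
        # sampling variances of off-diagonal s_ij over their squared size
        W = Xc[:, :, None] * Xc[:, None, :]          # T x R x R cross-products
        var_s = W.var(axis=0, ddof=1) * T / (T - 1) ** 2
        off = ~np.eye(R, dtype=bool)
        denom = np.sum(S[off] ** 2)
        lam = 1.0 if denom == 0 else float(np.clip(np.sum(var_s[off]) / denom, 0.0, 1.0))
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage must be in [0, 1]")

    C = (1.0 - lam) * S + lam * np.diag(np.diag(S))
    return 0.5 * (C + C.T)


# ---------------------------------------------------------------------------
# Riemannian geometric mean and tangent embedding
# ---------------------------------------------------------------------------

def geometric_mean(matrices, tol: float = 1e-7, max_iter: int = 200,
                   return_info: bool = False):
    """Fréchet mean of SPD matrices under the affine-invariant metric.

    Fixed-point iteration ``G <- G^{1/2} expm(step * mean_i logm(G^{-1/2}
    C_i G^{-1/2})) G^{1/2}`` starting at the arithmetic mean, with
    step-halving whenever the Frobenius residual of the whitened log-mean
    increases. At the solution the whitened logs average to zero.
    """
    mats = [_check_spd(np.asarray(M, float), f"matrices[{i}]") for i, M in enumerate(matrices)]
    if not mats:
        raise ValueError("need at least one SPD matrix")
    if len(mats) == 1:
        return (mats[0], 0) if return_info else mats[0]

    G = np.mean(mats, axis=0)
    step = 1.0
    prev_resid = np.inf
    for it in range(1, max_iter + 1):
        Gh = sqrtm_spd(G)
        Gih = invsqrtm_spd(G)
        M = np.mean([logm_spd(Gih @ C @ Gih) for C in mats], axis=0)
        resid = float(np.linalg.norm(M, "fro"))
        if resid < tol:
            return (G, it) if return_info else G
        if resid > prev_resid:
            step = max(step / 2.0, 1e-4)
        prev_resid = resid
        G = Gh @ expm_sym(step * M) @ Gh
        G = 0.5 * (G + G.T)
    raise GeometricMeanError(
        f"geometric mean did not converge in {max_iter} iterations "
        f"(last residual {prev_resid:.3e}, tol {tol:.1e})",
        residual=prev_resid, iterations=max_iter)


def _sha256_array(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a, dtype=float).tobytes())
    return h.hexdigest()


@dataclass(frozen=True)
class TangentReference:
    """Frozen tangent-space reference: geometric mean G and whitener G^{-1/2}."""

    mean: np.ndarray
    whitener: np.ndarray
    population: str = "train"

    @classmethod
    def fit(cls, matrices, population: str = "train", tol: float = 1e-7,
            max_iter: int = 200) -> "TangentReference":
        G = geometric_mean(matrices, tol=tol, max_iter=max_iter)
        return cls(mean=G, whitener=invsqrtm_spd(G), population=population)

    @property
    def n_rois(self) -> int:
        return self.mean.shape[0]

    @property
    def checksum(self) -> str:
        return _sha256_array(self.mean, self.whitener)

    def to_json(self) -> str:
        return json.dumps({"population": self.population,
                           "mean": self.mean.tolist(),
                           "whitener": self.whitener.tolist(),
                           "version": 1})

    @classmethod
    def from_json(cls, text: str) -> "TangentReference":
        d = json.loads(text)
        return cls(mean=np.array(d["mean"]), whitener=np.array(d["whitener"]),
                   population=d["population"])


def tangent_embed(C: np.ndarray, ref: TangentReference) -> np.ndarray:
    """Project an SPD matrix into the tangent space at the reference mean.

    Returns ``logm(W C W)`` with ``W = G^{-1/2}``; symmetric by construction.
    """
    C = _check_spd(C, "C")
    if C.shape[0] != ref.n_rois:
        raise ValueError(f"dimension mismatch: C is {C.shape[0]}x{C.shape[0]}, "
                         f"reference is {ref.n_rois}x{ref.n_rois}")
    W = ref.whitener
    return logm_spd(W @ C @ W.T)


def tangent_unembed(Tv: np.ndarray, ref: TangentReference) -> np.ndarray:
    """Inverse of :func:`tangent_embed` (exp then un-whiten)."""
    Gh = sqrtm_spd(ref.mean)
    return Gh @ expm_sym(Tv) @ Gh


# ---------------------------------------------------------------------------
# Vectorization and feature assembly
# ---------------------------------------------------------------------------

def edge_names(n_rois: int) -> list[str]:
    iu = np.triu_indices(n_rois, k=1)
    return [f"edge_{i}_{j}" for i, j in zip(*iu)]


def vectorize_upper(M: np.ndarray, tol: float = _SYM_TOL) -> np.ndarray:
    """Strict upper triangle of a symmetric matrix, row-major order.

    Order is (0,1), (0,2), ..., (0,R-1), (1,2), ... matching ``edge_i_j``
    feature names.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("input must be square")
    if np.max(np.abs(M - M.T)) > tol * max(1.0, np.max(np.abs(M))):
        raise ValueError("input is not symmetric within tolerance")
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def unvectorize_upper(v: np.ndarray, n_rois: int) -> np.ndarray:
    """Rebuild the symmetric matrix (zero diagonal) from edge features."""
    v = np.asarray(v, dtype=float)
    expected = n_rois * (n_rois - 1) // 2
    if v.size != expected:
        raise ValueError(f"expected {expected} edges for R={n_rois}, got {v.size}")
    M = np.zeros((n_rois, n_rois))
    iu = np.triu_indices(n_rois, k=1)
    M[iu] = v
    return M + M.T


@dataclass
class FeatureMatrix:
    """Subjects x features with names and kind tags (edge | anat | covariate)."""

    data: np.ndarray
    names: list[str]
    kinds: list[str]
    subject_ids: list[str] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D")
        if len(self.names) != self.data.shape[1] or len(self.kinds) != self.data.shape[1]:
            raise ValueError("names/kinds length must match number of columns")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def columns_of_kind(self, kind: str) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kinds) if k == kind], dtype=int)

    def rows(self, idx) -> "FeatureMatrix":
        ids = None if self.subject_ids is None else [self.subject_ids[i] for i in np.atleast_1d(idx)]
        return FeatureMatrix(self.data[idx], list(self.names), list(self.kinds), ids)

    def to_csv(self, path) -> None:
        import pandas as pd
        df = pd.DataFrame(self.data, columns=self.names)
        if self.subject_ids is not None:
            df.insert(0, "subject_id", self.subject_ids)
        df.to_csv(path, index=False)
        with open(str(path) + ".kinds.json", "w") as fh:
            json.dump(dict(zip(self.names, self.kinds)), fh)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        import pandas as pd
        df = pd.read_csv(path)
        ids = None
        if "subject_id" in df.columns:
            ids = df.pop("subject_id").astype(str).tolist()
        with open(str(path) + ".kinds.json") as fh:
            kinds_map = json.load(fh)
        names = list(df.columns)
        return cls(df.to_numpy(float), names, [kinds_map[n] for n in names], ids)


FEATURE_MODES = ("functional", "anatomical", "combined")


def assemble_feature_set(mode: str,
                         edges: FeatureMatrix | None = None,
                         anat: FeatureMatrix | None = None,
                         sex: np.ndarray | None = None,
                         site: np.ndarray | None = None,
                         site_categories: list | None = None) -> FeatureMatrix:
    """Concatenate [functional | anatomical | sex | site one-hot] per mode.

    Site one-hot columns use the category list fixed on the source cohort;
    an unseen external site maps to an all-zeros row with a warning.
    """
    if mode not in FEATURE_MODES:
        raise ValueError(f"mode must be one of {FEATURE_MODES}")
    blocks, names, kinds = [], [], []
    n_ref = None

    def _add(block: FeatureMatrix):
        nonlocal n_ref
        if n_ref is None:
            n_ref = block.n_subjects
        elif block.n_subjects != n_ref:
            raise ValueError("subject misalignment between feature blocks")
        blocks.append(block.data)
        names.extend(block.names)
        kinds.extend(block.kinds)

    if mode in ("functional", "combined"):
        if edges is None:
            raise ValueError(f"mode '{mode}' requires edge features")
        _add(edges)
    if mode in ("anatomical", "combined"):
        if anat is None:
            raise ValueError(f"mode '{mode}' requires anatomical features")
        _add(anat)

    if sex is not None:
        sex = np.asarray(sex, dtype=float).reshape(-1, 1)
        if n_ref is not None and sex.shape[0] != n_ref:
            raise ValueError("subject misalignment for sex covariate")
        blocks.append(sex)
        names.append("sex")
        kinds.append("covariate")
        n_ref = sex.shape[0] if n_ref is None else n_ref
    if site is not None:
        site = np.asarray(site)
        if n_ref is not None and site.shape[0] != n_ref:
            raise ValueError("subject misalignment for site covariate")
        cats = list(site_categories) if site_categories is not None else sorted(set(site.tolist()))
        onehot = np.zeros((site.shape[0], len(cats)))
        unseen = set()
        lookup = {c: i for i, c in enumerate(cats)}
        for r, s in enumerate(site.tolist()):
            if s in lookup:
                onehot[r, lookup[s]] = 1.0
            else:
                unseen.add(s)
        if unseen:
            warnings.warn(f"unseen site categories {sorted(map(str, unseen))} mapped to "
                          "all-zero one-hot rows", UserWarning, stacklevel=2)
        blocks.append(onehot)
        names.extend([f"site_{c}" for c in cats])
        kinds.extend(["covariate"] * len(cats))

    if not blocks:
        raise ValueError("nothing to assemble")
    return FeatureMatrix(np.hstack(blocks), names, kinds)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass
class Scaler:
    """Per-feature mean/sd frozen on a fit population.

    Constant features are centered but not divided (their scale is left at
    1 and they are flagged), so they come out as zeros on the fit rows.
    """

    mean: np.ndarray
    scale: np.ndarray
    constant_mask: np.ndarray
    population: str = "train"

    @classmethod
    def fit(cls, X: FeatureMatrix | np.ndarray, fit_rows=None,
            population: str = "train") -> "Scaler":
        data = X.data if isinstance(X, FeatureMatrix) else np.asarray(X, float)
        rows = np.arange(data.shape[0]) if fit_rows is None else np.asarray(fit_rows)
        if rows.size == 0:
            raise ValueError("fit_rows must be nonempty")
        sub = data[rows]
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0)
        constant = sd < 1e-12
        scale = np.where(constant, 1.0, sd)
        return cls(mean=mean, scale=scale, constant_mask=constant, population=population)

    def transform(self, X: FeatureMatrix | np.ndarray):
        if isinstance(X, FeatureMatrix):
            return FeatureMatrix((X.data - self.mean) / self.scale,
                                 list(X.names), list(X.kinds), X.subject_ids)
        return (np.asarray(X, float) - self.mean) / self.scale

    @property
    def checksum(self) -> str:
        return _sha256_array(self.mean, self.scale)

    def to_json(self) -> str:
        return json.dumps({"mean": self.mean.tolist(), "scale": self.scale.tolist(),
                           "constant_mask": self.constant_mask.astype(int).tolist(),
                           "population": self.population, "version": 1})

    @classmethod
    def from_json(cls, text: str) -> "Scaler":
        d = json.loads(text)
        return cls(np.array(d["mean"]), np.array(d["scale"]),
                   np.array(d["constant_mask"], dtype=bool), d["population"])


# ---------------------------------------------------------------------------
# End-to-end pipeline: cohort -> standardized feature matrix
# ---------------------------------------------------------------------------

class FeaturePipeline:
    """Covariance -> tangent embedding -> assembly -> scaling for one cohort.

    Per-subject covariances are estimated once. `fit(rows)` estimates the
    tangent reference and scaler on those rows only; `transform` then maps
    any subset — or a whole external cohort via `transform_cohort` — through
    the frozen artifacts.
    """

    def __init__(self, cohort, mode: str = "combined", shrinkage: float | str = "auto",
                 include_covariates: bool = True, covariances: list | None = None,
                 site_categories: list | None = None):
        if mode not in FEATURE_MODES:
            raise ValueError(f"mode must be one of {FEATURE_MODES}")
        self.mode = mode
        self.shrinkage = shrinkage
        self.include_covariates = include_covariates
        self._subjects = list(cohort)
        self.site_categories = (sorted({s.site for s in self._subjects})
                                if site_categories is None else list(site_categories))
        if mode == "anatomical":
            self._covs = None
        elif covariances is not None:
            self._covs = list(covariances)
        else:
            self._covs = [estimate_covariance(s.timeseries, shrinkage) for s in self._subjects]
        self.reference: TangentReference | None = None
        self.scaler: Scaler | None = None

    # -- fitting -----------------------------------------------------------
    def fit(self, rows) -> "FeaturePipeline":
        rows = np.asarray(rows, dtype=int)
        if self._covs is not None:
            self.reference = TangentReference.fit([self._covs[i] for i in rows])
        raw = self._assemble(self._subjects, self._covs)
        self.scaler = Scaler.fit(raw, fit_rows=rows)
        self._fitted_full = raw
        return self

    def _assemble(self, subjects, covs) -> FeatureMatrix:
        edges = anat = None
        if self.mode in ("functional", "combined"):
            names = edge_names(covs[0].shape[0])
            mat = np.stack([vectorize_upper(tangent_embed(C, self.reference)) for C in covs])
            edges = FeatureMatrix(mat, names, ["edge"] * len(names))
        if self.mode in ("anatomical", "combined"):
            amat = np.stack([s.anat for s in subjects])
            anames = [f"anat_{i}" for i in range(amat.shape[1])]
            anat = FeatureMatrix(amat, anames, ["anat"] * len(anames))
        sex = site = None
        if self.include_covariates:
            sex = np.array([s.sex for s in subjects], dtype=float)
            site = np.array([s.site for s in subjects])
        return assemble_feature_set(self.mode, edges=edges, anat=anat, sex=sex,
                                    site=site, site_categories=self.site_categories)

    # -- transforming ------------------------------------------------------
    def _require_fit(self):
        if self.scaler is None:
            raise RuntimeError("pipeline is not fitted; call fit(rows) first")

    def transform(self, rows) -> FeatureMatrix:
        """Standardized features for a subset of the fit cohort."""
        self._require_fit()
        rows = np.asarray(rows, dtype=int)
        return self.scaler.transform(self._fitted_full.rows(rows))

    def transform_cohort(self, subjects) -> FeatureMatrix:
        """Project an external cohort through the frozen reference and scaler."""
        self._require_fit()
        subjects = list(subjects)
        covs = None
        if self.mode in ("functional", "combined"):
            covs = [estimate_covariance(s.timeseries, self.shrinkage) for s in subjects]
        raw = self._assemble(subjects, covs)
        if raw.names != self._fitted_full.names:
            raise ValueError("external cohort produced a different feature namespace")
        return self.scaler.transform(raw)

    @property
    def feature_names(self) -> list[str]:
        self._require_fit()
        return list(self._fitted_full.names)

    @property
    def checksum(self) -> str:
        """Joint checksum of the frozen reference and scaler (leakage guard)."""
        self._require_fit()
        parts = self.scaler.checksum
        if self.reference is not None:
            parts += self.reference.checksum
        return hashlib.sha256(parts.encode()).hexdigest()
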