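"""Synthetic cohorts with planted connectivity and anatomical group effects.

Emulates the structure of multi-site case/control neuroimaging cohorts:
a near-balanced binary diagnosis (ASD=1 / TD=0), a binary sex covariate,
categorical acquisition sites with batch effects, per-subject ROI
timeseries drawn from group-specific population correlation matrices, and
anatomical feature vectors with optional group mean shifts. Group
differences in connectivity are planted on a sparse, known set of edges so
biomarker-recovery claims can be checked against ground truth.

Site effects use two distinct mechanisms mimicking scanner/batch
variation: an additive per-site shift on anatomical features and a
multiplicative per-site variance factor on the timeseries (which leaves
correlations — the signal carrier — untouched).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CohortSpec",
    "CohortShift",
    "SubjectRecord",
    "GroundTruth",
    "generate_cohort",
    "generate_external_cohort",
    "save_cohort",
    "load_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``planted_edges`` is a list of (roi_i, roi_j, delta_corr) with
    ``delta_corr`` the ASD-minus-TD difference in population correlation;
    ``planted_anat`` lists (index, delta) standardized mean shifts on the
    anatomical vector. ``base_corr`` is the within-network correlation of
    the block design shared by both groups.
    """

    n_subjects: int = 200
    n_rois: int = 16
    n_timepoints: int = 200
    n_anat: int = 20
    prevalence: float = 0.5
    sex_ratio: float = 0.5          # fraction male (sex=1)
    n_sites: int = 3
    site_effect_sd: float = 0.3
    planted_edges: tuple = ()
    planted_anat: tuple = ()
    base_corr: float = 0.3
    n_networks: int = 4
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects", "n_rois", "n_timepoints", "n_anat", "n_sites", "n_networks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.site_effect_sd < 0:
            raise ValueError("site_effect_sd must be >= 0")
        object.__setattr__(self, "planted_edges",
                           tuple((int(i), int(j), float(d)) for i, j, d in self.planted_edges))
        object.__setattr__(self, "planted_anat",
                           tuple((int(i), float(d)) for i, d in self.planted_anat))
        for i, j, d in self.planted_edges:
            if not (0 <= i < j < self.n_rois):
                raise ValueError(f"planted edge ({i},{j}) requires 0 <= roi_i < roi_j < n_rois")
        for i, _ in self.planted_anat:
            if not 0 <= i < self.n_anat:
                raise ValueError(f"planted anatomical index {i} out of range")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_edges"] = [list(e) for e in self.planted_edges]
        d["planted_anat"] = [list(a) for a in self.planted_anat]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["planted_edges"] = tuple(tuple(e) for e in d.get("planted_edges", ()))
        d["planted_anat"] = tuple(tuple(a) for a in d.get("planted_anat", ()))
        return cls(**d)


@dataclass(frozen=True)
class CohortShift:
    """Perturbation describing an external cohort relative to a source spec.

    Fields left as None keep the source value, so a zero perturbation with
    the same seed reproduces the source cohort exactly. The planted signal
    (edges and anatomical shifts) is never altered.
    """

    n_subjects: int | None = None
    prevalence: float | None = None
    sex_ratio: float | None = None
    n_sites: int | None = None
    site_effect_sd: float | None = None
    seed: int | None = None

    def apply(self, spec: CohortSpec) -> CohortSpec:
        updates = {k: v for k, v in dataclasses.asdict(self).items() if v is not None}
        return dataclasses.replace(spec, **updates)


@dataclass
class SubjectRecord:
    subject_id: str
    diagnosis: int          # ASD=1, TD=0
    sex: int                # male=1, female=0
    site: str
    timeseries: np.ndarray  # T x R
    anat: np.ndarray        # n_anat


@dataclass
class GroundTruth:
    """Planted signal: which features genuinely differ between groups."""

    planted_edges: list          # (roi_i, roi_j, delta_corr)
    planted_anat: list           # (index, delta)
    edge_names: list             # "edge_i_j" for planted edges
    anat_names: list

    def to_dict(self) -> dict:
        return {"planted_edges": [list(e) for e in self.planted_edges],
                "planted_anat": [list(a) for a in self.planted_anat],
                "edge_names": self.edge_names, "anat_names": self.anat_names}

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls([tuple(e) for e in d["planted_edges"]],
                   [tuple(a) for a in d["planted_anat"]],
                   list(d["edge_names"]), list(d["anat_names"]))


# ---------------------------------------------------------------------------
# Correlation targets
# ---------------------------------------------------------------------------

def _block_correlation(spec: CohortSpec) -> np.ndarray:
    """Within-network base_corr, zero across networks, unit diagonal."""
    R = spec.n_rois
    C = np.eye(R)
    blocks = np.array_split(np.arange(R), min(spec.n_networks, R))
    for b in blocks:
        for i in b:
            for j in b:
                if i != j:
                    C[i, j] = spec.base_corr
    return C


def _nearest_correlation(C: np.ndarray, n_pass: int = 5) -> np.ndarray:
    """Eigenvalue-clipping projection to a positive-definite correlation matrix."""
    X = 0.5 * (C + C.T)
    for _ in range(n_pass):
        w, V = np.linalg.eigh(X)
        if w.min() > 1e-8 and np.allclose(np.diag(X), 1.0, atol=1e-12):
            break
        w = np.clip(w, 1e-6, None)
        X = (V * w) @ V.T
        d = np.sqrt(np.diag(X))
        X = X / np.outer(d, d)
        np.fill_diagonal(X, 1.0)
    return 0.5 * (X + X.T)


def group_correlation_targets(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Population correlation matrices (TD, ASD) implied by the spec.

    The ASD matrix shifts each planted edge by delta_corr; both matrices
    are projected to the nearest correlation matrix if the shift breaks
    positive definiteness. An edge whose implied correlation leaves (-1, 1)
    is rejected with a diagnostic naming it.
    """
    base = _block_correlation(spec)
    asd = base.copy()
    for i, j, d in spec.planted_edges:
        target = base[i, j] + d
        if not -1.0 < target < 1.0:
            raise ValueError(
                f"planted edge ({i},{j}) with delta {d:+.3f} implies correlation "
                f"{target:.3f} outside (-1, 1); reduce base_corr or the delta")
        asd[i, j] = asd[j, i] = target

    def _ensure_pd(M, label):
        try:
            np.linalg.cholesky(M)
            return M
        except np.linalg.LinAlgError:
            fixed = _nearest_correlation(M)
            np.linalg.cholesky(fixed)  # raises with context if still bad
            return fixed

    return _ensure_pd(base, "TD"), _ensure_pd(asd, "ASD")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _exact_count_vector(n: int, frac: float, rng: np.random.Generator) -> np.ndarray:
    """Binary vector with exactly round(frac * n) ones, order randomized."""
    k = int(round(frac * n))
    v = np.zeros(n, dtype=int)
    v[:k] = 1
    return rng.permutation(v)


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], GroundTruth]:
    """Draw a cohort; bit-reproducible from ``spec.seed``.

    Labels are exactly balanced to ``round(prevalence * n)`` ASD; sex to
    ``round(sex_ratio * n)`` male. Each subject's timeseries is zero-mean
    multivariate normal under its group's population correlation matrix,
    scaled by its site's variance factor. One global seed fans out into
    per-subject substreams, so enlarging a cohort does not reshuffle
    existing subjects.
    """
    corr_td, corr_asd = group_correlation_targets(spec)
    chol = {0: np.linalg.cholesky(corr_td), 1: np.linalg.cholesky(corr_asd)}

    root = np.random.SeedSequence(spec.seed)
    ss_assign, ss_site, ss_subjects = root.spawn(3)
    rng_assign = np.random.default_rng(ss_assign)
    rng_site = np.random.default_rng(ss_site)

    n = spec.n_subjects
    diagnosis = _exact_count_vector(n, spec.prevalence, rng_assign)
    sex = _exact_count_vector(n, spec.sex_ratio, rng_assign)
    site_idx = rng_assign.permutation(np.arange(n) % spec.n_sites)

    # site batch effects: additive anat shift, multiplicative ts variance
    site_anat_shift = rng_site.normal(0.0, spec.site_effect_sd,
                                      size=(spec.n_sites, spec.n_anat))
    site_var_factor = np.exp(rng_site.normal(0.0, spec.site_effect_sd,
                                             size=spec.n_sites))

    anat_delta = np.zeros(spec.n_anat)
    for i, d in spec.planted_anat:
        anat_delta[i] = d

    subjects = []
    for k, ss in enumerate(ss_subjects.spawn(n)):
        rng = np.random.default_rng(ss)
        g = int(diagnosis[k])
        s = int(site_idx[k])
        Z = rng.standard_normal((spec.n_timepoints, spec.n_rois))
        ts = (Z @ chol[g].T) * np.sqrt(site_var_factor[s])
        anat = rng.standard_normal(spec.n_anat) + site_anat_shift[s] + g * anat_delta
        subjects.append(SubjectRecord(
            subject_id=f"sub-{k:04d}", diagnosis=g, sex=int(sex[k]),
            site=f"site_{s}", timeseries=ts, anat=anat))

    truth = GroundTruth(
        planted_edges=list(spec.planted_edges),
        planted_anat=list(spec.planted_anat),
        edge_names=[f"edge_{i}_{j}" for i, j, _ in spec.planted_edges],
        anat_names=[f"anat_{i}" for i, _ in spec.planted_anat])
    return subjects, truth


def generate_external_cohort(spec: CohortSpec,
                             shift: CohortShift = CohortShift()
                             ) -> tuple[list[SubjectRecord], GroundTruth]:
    """External cohort sharing the source's planted signal.

    Demographics and batch structure move per ``shift`` (e.g. a shifted sex
    ratio and fresh site effects via a new seed); the planted edges and
    anatomical shifts are those of the source spec.
    """
    return generate_cohort(shift.apply(spec))


# ---------------------------------------------------------------------------
# Serialization: directory of CSV/TSV/JSON
# ---------------------------------------------------------------------------

def save_cohort(subjects, truth: GroundTruth, out_dir, spec: CohortSpec | None = None) -> None:
    import pandas as pd
    os.makedirs(out_dir, exist_ok=True)
    meta = pd.DataFrame({"subject_id": [s.subject_id for s in subjects],
                         "diagnosis": [s.diagnosis for s in subjects],
                         "sex": [s.sex for s in subjects],
                         "site": [s.site for s in subjects]})
    meta.to_csv(os.path.join(out_dir, "subjects.csv"), index=False)
    anat = pd.DataFrame(np.stack([s.anat for s in subjects]),
                        columns=[f"anat_{i}" for i in range(subjects[0].anat.size)])
    anat.insert(0, "subject_id", [s.subject_id for s in subjects])
    anat.to_csv(os.path.join(out_dir, "anat.csv"), index=False)
    ts_dir = os.path.join(out_dir, "timeseries")
    os.makedirs(ts_dir, exist_ok=True)
    for s in subjects:
        np.savetxt(os.path.join(ts_dir, f"{s.subject_id}.tsv"), s.timeseries,
                   delimiter="\t")
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
    if spec is not None:
        with open(os.path.join(out_dir, "cohort_spec.json"), "w") as fh:
            json.dump(spec.to_dict(), fh, indent=1)


def load_cohort(in_dir) -> tuple[list[SubjectRecord], GroundTruth]:
    import pandas as pd
    meta = pd.read_csv(os.path.join(in_dir, "subjects.csv"))
    anat = pd.read_csv(os.path.join(in_dir, "anat.csv")).set_index("subject_id")
    subjects = []
    for _, row in meta.iterrows():
        sid = str(row["subject_id"])
        ts = np.loadtxt(os.path.join(in_dir, "timeseries", f"{sid}.tsv"), delimiter="\t")
        subjects.append(SubjectRecord(
            subject_id=sid, diagnosis=int(row["diagnosis"]), sex=int(row["sex"]),
            site=str(row["site"]), timeseries=ts,
            anat=anat.loc[sid].to_numpy(float)))
    with open(os.path.join(in_dir, "ground_truth.json")) as fh:
        truth = GroundTruth.from_dict(json.load(fh))
    return subjects, truth
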