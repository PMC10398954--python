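"""Discriminative spatial network filters (SPN), feature fusion, LOOCV SVM.

The SPN step is the network analogue of common spatial patterns: for each
band, the class-mean PLV adjacency matrices S_P (patients) and S_C
(controls) define the generalized eigenproblem

    S_P v = lambda (S_P + S_C) v,

whose eigenvalues lie in [0, 1] and measure how strongly the spatial
direction v loads on patient versus control network structure.  The k
eigenvectors from each end of the spectrum serve as spatial filters; a
subject with adjacency W contributes the scalar feature v' W v per filter.
Because a PLV adjacency has zero diagonal (hence zero trace), the class
means are given a unit self-locking diagonal and projected onto the PSD
cone, then ridge-stabilized, before the pencil is solved.

Classification fuses, per band, the grand-average absolute band power, the
two graph metrics (C, L) and the SPN projections, z-scored with training-set
statistics only, into a linear SVM (C = 1) evaluated by leave-one-out
cross-validation.  Everything data-dependent — SPN filters, z-scoring, the
SVM — is refit inside each training fold, so the reported metrics carry no
leakage from the held-out subject (a ``refit_per_fold=False`` escape hatch
fits the SPN once on all subjects for comparison).

Performance is summarized as

    accuracy    = (n_PAs + n_HCs) / (N_PAs + N_HCs) * 100%
    sensitivity = n_PAs / N_PAs * 100%
    specificity = n_HCs / N_HCs * 100%

with n the correctly classified and N the total subjects per group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import Band, ValidationError

__all__ = [
    "SPNModel",
    "CohortFeatures",
    "ClassificationReport",
    "spn_fit",
    "spn_project",
    "fuse_features",
    "loocv_svm",
    "report_metrics",
]


@dataclass
class SPNModel:
    """Spatial filters for one band: 2k unit-norm vectors over channels."""

    band: Band
    filters: np.ndarray  # 2k x channels, k from each spectral end
    eigenvalues: np.ndarray  # matching the filter rows, descending
    k: int


def _psd_project(s: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((s + s.T) / 2)
    return (vecs * np.clip(vals, 0.0, None)) @ vecs.T


def _class_mean(ws: np.ndarray) -> np.ndarray:
    s = np.asarray(ws, dtype=float).mean(axis=0)
    s = s + np.eye(s.shape[0])  # unit self-locking diagonal
    return _psd_project(s)


def spn_fit(
    patient_ws: np.ndarray, control_ws: np.ndarray, band: Band, k: int = 1
) -> SPNModel:
    """Fit SPN filters from stacks (subjects x channels x channels) of adjacencies."""
    patient_ws = np.asarray(patient_ws, dtype=float)
    control_ws = np.asarray(control_ws, dtype=float)
    if patient_ws.shape[0] < 2 or control_ws.shape[0] < 2:
        raise ValidationError("need at least 2 subjects per class")
    if patient_ws.shape[1:] != control_ws.shape[1:]:
        raise ValidationError("montage mismatch between classes")
    m = patient_ws.shape[1]
    if k < 1 or 2 * k > m:
        raise ValidationError(f"k={k} filters per end invalid for {m} channels")
    s_p = _class_mean(patient_ws)
    s_c = _class_mean(control_ws)
    composite = s_p + s_c
    ridge = 1e-6 * np.trace(composite) / m
    s_p += ridge * np.eye(m)
    composite += 2 * ridge * np.eye(m)
    try:
        vals, vecs = linalg.eigh(s_p, composite)
    except linalg.LinAlgError as e:  # pragma: no cover - ridge makes this rare
        raise ValidationError(f"SPN eigenproblem is singular: {e}") from e
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = np.r_[0:k, m - k : m]
    filters = vecs[:, keep].T
    filters /= np.linalg.norm(filters, axis=1, keepdims=True)
    return SPNModel(band=band, filters=filters, eigenvalues=np.clip(vals[keep], 0, 1), k=k)


def spn_project(model: SPNModel, ws: np.ndarray) -> np.ndarray:
    """Subject features v' W v, one column per filter."""
    ws = np.asarray(ws, dtype=float)
    return np.einsum("fi,sij,fj->sf", model.filters, ws, model.filters)


@dataclass
class CohortFeatures:
    """Per-subject ingredients for classification, keyed by band name.

    ``adjacency[b]`` is subjects x channels x channels; ``apsd[b]``, ``c[b]``
    and ``l[b]`` are per-subject scalars.  Labels: 1 = patient, 0 = control.
    """

    subject_ids: list[str]
    labels: np.ndarray
    bands: list[Band]
    adjacency: dict[str, np.ndarray]
    apsd: dict[str, np.ndarray]
    c: dict[str, np.ndarray]
    l: dict[str, np.ndarray]
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.subject_ids)
        for b in self.bands:
            for d in (self.adjacency, self.apsd, self.c, self.l):
                if len(d[b.name]) != n:
                    raise ValidationError(f"band {b.name}: feature length != {n} subjects")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def fuse_features(
    cohort: CohortFeatures, spn_models: dict[str, SPNModel]
) -> tuple[np.ndarray, list[str]]:
    """Concatenate [aPSD, C, L, SPN projections] per band, in band order."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    for b in cohort.bands:
        cols += [cohort.apsd[b.name], cohort.c[b.name], cohort.l[b.name]]
        names += [f"{b.name}:apsd", f"{b.name}:C", f"{b.name}:L"]
        proj = spn_project(spn_models[b.name], cohort.adjacency[b.name])
        cols += [proj[:, j] for j in range(proj.shape[1])]
        names += [f"{b.name}:spn{j}" for j in range(proj.shape[1])]
    return np.column_stack(cols), names


@dataclass
class ClassificationReport:
    """LOOCV outcome: per-fold predictions, group counts and the metrics in %."""

    subject_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    n_pas: int
    n_hcs: int
    n_pas_total: int
    n_hcs_total: int
    accuracy: float
    sensitivity: float
    specificity: float

    def to_dict(self) -> dict:
        return {
            "per_fold": [
                {"subject_id": s, "true": int(t), "pred": int(p)}
                for s, t, p in zip(self.subject_ids, self.y_true, self.y_pred)
            ],
            "n_PAs": self.n_pas,
            "n_HCs": self.n_hcs,
            "N_PAs": self.n_pas_total,
            "N_HCs": self.n_hcs_total,
            "accuracy_pct": self.accuracy,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
        }


def report_metrics(
    n_pas: int, n_hcs: int, n_pas_total: int, n_hcs_total: int
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent, rounded to 2 decimals."""
    if n_pas_total <= 0 or n_hcs_total <= 0:
        raise ValidationError("group totals must be positive")
    if not (0 <= n_pas <= n_pas_total and 0 <= n_hcs <= n_hcs_total):
        raise ValidationError("correct counts must lie in [0, N] per group")
    accuracy = (n_pas + n_hcs) / (n_pas_total + n_hcs_total) * 100.0
    sensitivity = n_pas / n_pas_total * 100.0
    specificity = n_hcs / n_hcs_total * 100.0
    return round(accuracy, 2), round(sensitivity, 2), round(specificity, 2)


def _fit_fold(
    cohort: CohortFeatures, train: np.ndarray, k: int, kernel: str, c: float
) -> tuple[dict[str, SPNModel], StandardScaler, SVC, np.ndarray]:
    y = cohort.labels[train]
    models = {
        b.name: spn_fit(
            cohort.adjacency[b.name][train][y == 1],
            cohort.adjacency[b.name][train][y == 0],
            b,
            k=k,
        )
        for b in cohort.bands
    }
    x_all, names = fuse_features(cohort, models)
    x_train = x_all[train]
    keep = x_train.std(axis=0) > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
    scaler = StandardScaler().fit(x_train[:, keep])
    clf = SVC(kernel=kernel, C=c)
    clf.fit(scaler.transform(x_train[:, keep]), y)
    return models, scaler, clf, keep


def loocv_svm(
    cohort: CohortFeatures,
    k: int = 1,
    kernel: str = "linear",
    svm_c: float = 1.0,
    refit_per_fold: bool = True,
) -> ClassificationReport:
    """Leave-one-out SVM over fused aPSD + graph-metric + SPN features.

    With ``refit_per_fold`` (default) the SPN filters, the z-scaling and the
    SVM are all fit on the 35-subject training side of every fold.
    """
    n = cohort.n_subjects
    y = cohort.labels
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValidationError("need at least 2 subjects per class")
    y_pred = np.empty(n, dtype=int)
    shared = None
    if not refit_per_fold:
        shared = _fit_fold(cohort, np.arange(n), k, kernel, svm_c)
    for i in range(n):
        train = np.array([j for j in range(n) if j != i])
        if len(np.unique(y[train])) < 2:
            raise ValidationError(f"fold {i}: training set lost a class")
        if refit_per_fold:
            models, scaler, clf, keep = _fit_fold(cohort, train, k, kernel, svm_c)
        else:
            models, scaler, clf, keep = shared
        x_all, _ = fuse_features(cohort, models)
        y_pred[i] = clf.predict(scaler.transform(x_all[[i]][:, keep]))[0]
    n_pas = int(((y == 1) & (y_pred == 1)).sum())
    n_hcs = int(((y == 0) & (y_pred == 0)).sum())
    acc, sens, spec = report_metrics(n_pas, n_hcs, int((y == 1).sum()), int((y == 0).sum()))
    return ClassificationReport(
        subject_ids=cohort.subject_ids,
        y_true=y,
        y_pred=y_pred,
        n_pas=n_pas,
        n_hcs=n_hcs,
        n_pas_total=int((y == 1).sum()),
        n_hcs_total=int((y == 0).sum()),
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
    )
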