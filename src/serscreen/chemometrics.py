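"""PLS–SVM diagnostic modelling of processed SERS cohorts.

The classification chain mirrors the standard chemometric protocol for
spectral diagnosis:

1. partial least squares (PLS2, NIPALS) compresses the sample × wavenumber
   matrix onto a few latent components supervised by one-hot class
   indicators;
2. the component count is chosen from a cross-validated mean squared error
   of prediction (MSEP) curve with an adjusted Wold's R stopping rule — a
   component is kept only while it improves MSEP by at least a threshold
   fraction (default 5%);
3. an RBF-kernel SVM, K(u,v) = exp(−‖u−v‖²/(2σ²)), is trained on the latent
   scores, with (C, σ) tuned by grid search under stratified 10-fold
   cross-validation;
4. out-of-fold predictions are aggregated into confusion matrices,
   per-class sensitivity/specificity, overall accuracy and one-vs-rest
   ROC/AUC.

Inside :func:`run_pls_svm` the PLS projection is re-fit on each training
fold before the SVM sees the scores.  Projecting with a supervised
reduction fit on all samples would leak the held-out labels into the
features (with many more wavenumbers than samples the leak is total), so
the per-fold refit is the default; grid search and reporting share one fold
structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .exceptions import ChemometricsError
from .preprocess import SampleSpectrum

__all__ = [
    "LabeledSpectraMatrix",
    "PLSFit",
    "ComponentSelection",
    "SVMHyperParams",
    "CVResult",
    "ClassificationReport",
    "ChemometricsConfig",
    "PipelineResult",
    "default_c_grid",
    "default_sigma_grid",
    "fit_pls",
    "compute_msep_curve",
    "select_components",
    "grid_search_svm",
    "classify_and_report",
    "run_pls_svm",
]


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabeledSpectraMatrix:
    """Samples × wavenumbers intensity matrix with group labels."""

    X: np.ndarray
    y: tuple[str, ...]
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        if X.ndim != 2:
            raise ChemometricsError("X must be a 2-D samples × features matrix")
        if not np.all(np.isfinite(X)):
            raise ChemometricsError("X contains non-finite values")
        if len(self.y) != X.shape[0]:
            raise ChemometricsError(
                f"{len(self.y)} labels for {X.shape[0]} rows"
            )
        if not self.sample_ids:
            object.__setattr__(
                self, "sample_ids", tuple(f"s{i}" for i in range(X.shape[0]))
            )

    @classmethod
    def from_samples(cls, samples: Sequence[SampleSpectrum]) -> "LabeledSpectraMatrix":
        return cls(
            X=np.vstack([s.spectrum.intensities for s in samples]),
            y=tuple(s.group for s in samples),
            sample_ids=tuple(s.sample_id for s in samples),
        )

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.y)))

    def subset(self, labels: Sequence[str]) -> "LabeledSpectraMatrix":
        keep = np.array([yi in labels for yi in self.y])
        return LabeledSpectraMatrix(
            X=self.X[keep],
            y=tuple(yi for yi, k in zip(self.y, keep) if k),
            sample_ids=tuple(s for s, k in zip(self.sample_ids, keep) if k),
        )


def _one_hot(y: Sequence[str], classes: Sequence[str]) -> np.ndarray:
    Y = np.zeros((len(y), len(classes)))
    index = {c: j for j, c in enumerate(classes)}
    for i, yi in enumerate(y):
        Y[i, index[yi]] = 1.0
    return Y


# ---------------------------------------------------------------------------
# NIPALS PLS2
# ---------------------------------------------------------------------------

def _nipals(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    tol: float = 1e-12,
    max_iter: int = 5000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """NIPALS latent-component extraction on centered X (n×p) and Y (n×m).

    Returns (T scores, W weights, P x-loadings, Q y-loadings, cumulative
    explained response-variance fractions, number of components actually
    extracted).  Both blocks are deflated by each component's score
    (regression deflation), so scores are mutually orthogonal.
    """
    Xw = X.copy()
    Yw = Y.copy()
    n, p = Xw.shape
    m = Yw.shape[1]
    ss_y_total = float(np.sum(Y**2))
    eps = np.finfo(float).eps

    T = np.zeros((n, n_components))
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((m, n_components))
    cumulative = np.zeros(n_components)

    extracted = 0
    for a in range(n_components):
        if float(np.sum(Xw**2)) < eps * max(1.0, float(np.sum(X**2))):
            warnings.warn(
                f"X block exhausted after {extracted} components; stopping early",
                stacklevel=2,
            )
            break
        u = Yw[:, int(np.argmax(Yw.var(axis=0)))].copy()
        if float(u @ u) < eps:
            u = Yw.sum(axis=1)
        w_old = None
        for _ in range(max_iter):
            w = Xw.T @ u
            norm_w = float(np.linalg.norm(w))
            if norm_w < eps:
                break
            w /= norm_w
            t = Xw @ w
            tt = float(t @ t)
            if tt < eps:
                break
            c = Yw.T @ t / tt
            cc = float(c @ c)
            if cc < eps:
                break
            u = Yw @ c / cc
            if w_old is not None and float(np.linalg.norm(w - w_old)) < tol:
                break
            w_old = w
        t = Xw @ w
        tt = float(t @ t)
        if tt < eps:
            warnings.warn(
                f"degenerate score at component {a + 1}; stopping early",
                stacklevel=2,
            )
            break
        pvec = Xw.T @ t / tt
        qvec = Yw.T @ t / tt
        Xw -= np.outer(t, pvec)
        Yw -= np.outer(t, qvec)
        T[:, a], W[:, a], P[:, a], Q[:, a] = t, w, pvec, qvec
        cumulative[a] = 1.0 - float(np.sum(Yw**2)) / ss_y_total if ss_y_total > 0 else 0.0
        extracted = a + 1

    k = extracted
    return T[:, :k], W[:, :k], P[:, :k], Q[:, :k], cumulative[:k], k


@dataclass(frozen=True)
class PLSFit:
    """A fitted PLS2 decomposition with mean-centering offsets."""

    classes: tuple[str, ...]
    n_components: int
    scores: np.ndarray        # samples × components
    weights: np.ndarray       # wavenumbers × components
    loadings: np.ndarray      # wavenumbers × components (x-loadings)
    y_loadings: np.ndarray    # classes × components
    cumulative_proportion: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray

    def rotations(self, n_components: int | None = None) -> np.ndarray:
        """W(PᵀW)⁻¹ restricted to the first ``n_components`` components,
        mapping centered X directly to scores."""
        k = self.n_components if n_components is None else n_components
        if not (1 <= k <= self.n_components):
            raise ChemometricsError(
                f"n_components must be in 1..{self.n_components}, got {k}"
            )
        W, P = self.weights[:, :k], self.loadings[:, :k]
        return W @ np.linalg.inv(P.T @ W)

    def transform(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        """Latent scores of (possibly new) rows of X."""
        Xc = np.asarray(X, dtype=float) - self.x_mean
        return Xc @ self.rotations(n_components)

    def predict_response(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        """Predicted one-hot response values (regression scale, not classes)."""
        k = self.n_components if n_components is None else n_components
        scores = self.transform(X, k)
        return scores @ self.y_loadings[:, :k].T + self.y_mean


def fit_pls(data: LabeledSpectraMatrix, n_components_max: int) -> PLSFit:
    """Fit a NIPALS PLS2 model of the spectra against one-hot class labels.

    X and the indicator response are mean-centered; no unit-variance scaling
    is applied (all spectra share the common normalized intensity scale).
    """
    classes = data.classes
    if len(classes) < 2:
        raise ChemometricsError("PLS-DA requires at least 2 distinct classes")
    n, p = data.X.shape
    limit = min(n - 1, p)
    if not (1 <= n_components_max <= limit):
        raise ChemometricsError(
            f"n_components_max must be in 1..{limit} for a {n}×{p} matrix, "
            f"got {n_components_max}"
        )
    Y = _one_hot(data.y, classes)
    x_mean = data.X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    T, W, P, Q, cum, k = _nipals(data.X - x_mean, Y - y_mean, n_components_max)
    return PLSFit(
        classes=classes,
        n_components=k,
        scores=T,
        weights=W,
        loadings=P,
        y_loadings=Q,
        cumulative_proportion=cum,
        x_mean=x_mean,
        y_mean=y_mean,
    )


# ---------------------------------------------------------------------------
# Component selection: cross-validated MSEP + adjusted Wold's R
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentSelection:
    """Cross-validated MSEP curve and (optionally) the chosen model size.

    ``msep_curve[0]`` is the zero-component baseline (predicting the training
    class proportions); ``msep_curve[N]`` is the error with N components.
    ``wold_ratio[N-1]`` is the relative improvement achieved by component N.
    """

    msep_curve: np.ndarray
    wold_ratio: np.ndarray
    improvement_threshold: float = 0.05
    n_selected: int | None = None


def _stratified_folds(
    y: Sequence[str], folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    y_arr = np.asarray(y)
    _, counts = np.unique(y_arr, return_counts=True)
    smallest = int(counts.min())
    if smallest < folds:
        warnings.warn(
            f"smallest class has {smallest} members; reducing folds from "
            f"{folds} to {smallest}",
            stacklevel=3,
        )
        folds = smallest
    if folds < 2:
        raise ChemometricsError(
            "cross-validation needs every class to have at least 2 members"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y_arr)), y_arr))


def compute_msep_curve(
    data: LabeledSpectraMatrix,
    n_components_max: int,
    folds: int = 10,
    seed: int = 0,
) -> ComponentSelection:
    """Cross-validated MSEP of one-hot response predictions per model size."""
    classes = data.classes
    if len(classes) < 2:
        raise ChemometricsError("MSEP curve requires at least 2 classes")
    Y = _one_hot(data.y, classes)
    splits = _stratified_folds(data.y, folds, seed)
    n, m = Y.shape
    sq_err = np.zeros(n_components_max + 1)

    for train, test in splits:
        Xtr, Ytr = data.X[train], Y[train]
        x_mean, y_mean = Xtr.mean(axis=0), Ytr.mean(axis=0)
        k_max = min(n_components_max, len(train) - 1, Xtr.shape[1])
        T, W, P, Q, _, k = _nipals(Xtr - x_mean, Ytr - y_mean, k_max)
        Xc_test = data.X[test] - x_mean
        sq_err[0] += float(np.sum((Y[test] - y_mean) ** 2))
        for N in range(1, n_components_max + 1):
            kk = min(N, k)
            R = W[:, :kk] @ np.linalg.inv(P[:, :kk].T @ W[:, :kk])
            pred = (Xc_test @ R) @ Q[:, :kk].T + y_mean
            sq_err[N] += float(np.sum((Y[test] - pred) ** 2))

    msep = sq_err / (n * m)
    prev = msep[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        wold = np.where(prev > 0, (prev - msep[1:]) / prev, 0.0)
    return ComponentSelection(msep_curve=msep, wold_ratio=wold)


def select_components(
    selection: ComponentSelection | Sequence[float],
    threshold: float = 0.05,
    form: str = "improvement",
) -> int:
    """Adjusted Wold's R rule on an MSEP curve (baseline first).

    Walk N = 1, 2, …: keep component N while its relative MSEP improvement
    ``(MSEP[N−1] − MSEP[N]) / MSEP[N−1]`` is at least ``threshold``
    (equivalently, ``form="ratio"``: while ``MSEP[N]/MSEP[N−1] ≤ 1 −
    threshold``); return the last kept N, with a floor of one component.
    """
    if form not in ("improvement", "ratio"):
        raise ChemometricsError(f"unknown selection form {form!r}")
    curve = np.asarray(
        selection.msep_curve if isinstance(selection, ComponentSelection) else selection,
        dtype=float,
    )
    if curve.size < 2:
        raise ChemometricsError("MSEP curve needs the baseline plus >= 1 component")
    if not (0 < threshold < 1):
        raise ChemometricsError(f"threshold must lie in (0, 1), got {threshold}")
    accepted = 0
    for N in range(1, curve.size):
        prev = curve[N - 1]
        if prev <= 0:
            break
        if form == "improvement":
            ok = (prev - curve[N]) / prev >= threshold
        else:
            ok = curve[N] / prev <= 1.0 - threshold
        if not ok:
            break
        accepted = N
    return max(accepted, 1)


# ---------------------------------------------------------------------------
# RBF-SVM grid search and evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SVMHyperParams:
    """RBF-SVM hyperparameters; K(u,v) = exp(−‖u−v‖²/(2σ²))."""

    C: float = 1.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.sigma <= 0:
            raise ChemometricsError(
                f"C and sigma must be > 0, got C={self.C}, sigma={self.sigma}"
            )

    @property
    def gamma(self) -> float:
        return 1.0 / (2.0 * self.sigma**2)


def default_c_grid() -> tuple[float, ...]:
    return tuple(2.0**k for k in range(-5, 16, 2))


def default_sigma_grid() -> tuple[float, ...]:
    return tuple(2.0**k for k in range(-4, 5))


@dataclass(frozen=True)
class CVResult:
    """Grid-search outcome under one stratified fold structure."""

    fold_assignments: np.ndarray
    grid: pd.DataFrame            # columns C, sigma, accuracy
    best_params: SVMHyperParams
    best_accuracy: float
    predictions: tuple[str, ...]  # out-of-fold predictions at best_params
    seed: int


def _make_svc(params: SVMHyperParams) -> SVC:
    # SVC's multiclass rule is one-vs-one majority voting; ovr-shaped decision
    # values (derived from the pairwise votes/margins) serve the ROC.
    return SVC(C=params.C, gamma=params.gamma, kernel="rbf",
               decision_function_shape="ovr")


def _check_train_folds(y: np.ndarray, splits) -> None:
    for train, _ in splits:
        if len(set(y[train])) < 2:
            raise ChemometricsError(
                "a training fold contains a single class; repair stratification "
                "or reduce the fold count"
            )


def _oof_predict(
    per_fold: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
    params: SVMHyperParams,
    n: int,
    classes: Sequence[str],
    collect_decisions: bool = False,
):
    """Out-of-fold SVC predictions over precomputed per-fold feature blocks.

    ``per_fold`` rows are (train_idx, test_idx, train_features, test_features,
    train_labels).  Returns (predictions, decision matrix | None).
    """
    preds = np.empty(n, dtype=object)
    decisions = np.full((n, len(classes)), np.nan) if collect_decisions else None
    class_index = {c: j for j, c in enumerate(classes)}
    for train, test, f_train, f_test, y_train in per_fold:
        clf = _make_svc(params).fit(f_train, y_train)
        preds[test] = clf.predict(f_test)
        if collect_decisions:
            dec = clf.decision_function(f_test)
            if dec.ndim == 1:  # binary: score for clf.classes_[1]
                decisions[test, class_index[clf.classes_[1]]] = dec
                decisions[test, class_index[clf.classes_[0]]] = -dec
            else:
                for j, c in enumerate(clf.classes_):
                    decisions[test, class_index[c]] = dec[:, j]
    return preds, decisions


def _grid_search(
    per_fold, y: np.ndarray, classes, c_grid, sigma_grid, n: int, seed: int,
    fold_assignments: np.ndarray,
) -> CVResult:
    if not c_grid or not sigma_grid:
        raise ChemometricsError("C and sigma candidate grids must be nonempty")
    rows = []
    best: tuple[float, float, float] | None = None  # (accuracy, C, sigma)
    for C in sorted(c_grid):
        for sigma in sorted(sigma_grid):
            params = SVMHyperParams(C=C, sigma=sigma)
            preds, _ = _oof_predict(per_fold, params, n, classes)
            acc = float(np.mean(preds == y))
            rows.append({"C": C, "sigma": sigma, "accuracy": acc})
            if best is None or acc > best[0] + 1e-12:
                best = (acc, C, sigma)
    best_params = SVMHyperParams(C=best[1], sigma=best[2])
    preds, _ = _oof_predict(per_fold, best_params, n, classes)
    return CVResult(
        fold_assignments=fold_assignments,
        grid=pd.DataFrame(rows),
        best_params=best_params,
        best_accuracy=float(best[0]),
        predictions=tuple(preds),
        seed=seed,
    )


def grid_search_svm(
    scores: np.ndarray,
    y: Sequence[str],
    c_grid: Sequence[float] | None = None,
    sigma_grid: Sequence[float] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified-CV accuracy surface over an (C, σ) grid on fixed features.

    Ties in accuracy resolve to the smallest C, then the smallest σ.  The
    feature matrix is taken as given; features derived from a supervised fit
    on all samples would make these accuracies optimistic (see
    :func:`run_pls_svm` for the fold-aware protocol).
    """
    scores = np.asarray(scores, dtype=float)
    y_arr = np.asarray(y)
    splits = _stratified_folds(y, folds, seed)
    _check_train_folds(y_arr, splits)
    fold_assignments = np.empty(len(y_arr), dtype=int)
    per_fold = []
    for f, (train, test) in enumerate(splits):
        fold_assignments[test] = f
        per_fold.append((train, test, scores[train], scores[test], y_arr[train]))
    classes = sorted(set(y))
    return _grid_search(
        per_fold, y_arr, classes,
        tuple(c_grid or default_c_grid()),
        tuple(sigma_grid or default_sigma_grid()),
        len(y_arr), seed, fold_assignments,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationReport:
    """Confusion matrix and derived diagnostic metrics.

    ``confusion`` rows are true classes, columns predicted, both in
    ``labels`` order.  Sensitivity and specificity are one-vs-rest per class;
    ``accuracy`` is trace/total (fraction in [0, 1]).
    """

    labels: tuple[str, ...]
    confusion: np.ndarray
    sensitivity: Mapping[str, float]
    specificity: Mapping[str, float]
    accuracy: float
    positive_class: str | None = None
    roc_points: tuple[tuple[float, float], ...] = ()
    auc: float | None = None

    @property
    def accuracy_percent(self) -> float:
        return 100.0 * self.accuracy

    def sensitivity_percent(self, label: str) -> float:
        return 100.0 * self.sensitivity[label]

    def specificity_percent(self, label: str) -> float:
        return 100.0 * self.specificity[label]

    @classmethod
    def from_confusion(
        cls,
        confusion: np.ndarray | Sequence[Sequence[int]],
        labels: Sequence[str],
        positive_class: str | None = None,
    ) -> "ClassificationReport":
        M = np.asarray(confusion, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1] or M.shape[0] != len(labels):
            raise ChemometricsError("confusion matrix must be square and match labels")
        if (M < 0).any():
            raise ChemometricsError("confusion matrix entries must be non-negative")
        total = float(M.sum())
        if total <= 0:
            raise ChemometricsError("confusion matrix is empty")
        sens: dict[str, float] = {}
        spec: dict[str, float] = {}
        for j, lab in enumerate(labels):
            tp = M[j, j]
            fn = M[j, :].sum() - tp
            fp = M[:, j].sum() - tp
            tn = total - tp - fn - fp
            sens[lab] = float(tp / (tp + fn)) if tp + fn > 0 else float("nan")
            spec[lab] = float(tn / (tn + fp)) if tn + fp > 0 else float("nan")
        return cls(
            labels=tuple(labels),
            confusion=M,
            sensitivity=sens,
            specificity=spec,
            accuracy=float(np.trace(M) / total),
            positive_class=positive_class,
        )


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    M = np.zeros((len(labels), len(labels)))
    index = {c: j for j, c in enumerate(labels)}
    for t, p in zip(y_true, y_pred):
        M[index[t], index[p]] += 1
    return M


def _roc(y_true: np.ndarray, scores: np.ndarray, positive: str):
    fpr, tpr, _ = _roc_curve(y_true == positive, scores)
    return tuple(zip(fpr.tolist(), tpr.tolist())), float(_trapezoid_auc(fpr, tpr))


def _report_from_folds(
    per_fold, y: np.ndarray, classes, params: SVMHyperParams, positive_class: str,
) -> ClassificationReport:
    preds, decisions = _oof_predict(per_fold, params, len(y), classes,
                                    collect_decisions=True)
    M = _confusion(y, preds, classes)
    base = ClassificationReport.from_confusion(M, classes, positive_class)
    j = classes.index(positive_class)
    roc_points, auc_value = _roc(y, decisions[:, j], positive_class)
    return replace(base, roc_points=roc_points, auc=auc_value)


def classify_and_report(
    scores: np.ndarray,
    y: Sequence[str],
    params: SVMHyperParams,
    folds: int = 10,
    seed: int = 0,
    positive_class: str | None = None,
) -> ClassificationReport:
    """Out-of-fold RBF-SVM evaluation on a fixed feature matrix.

    Aggregates held-out predictions into a confusion matrix with per-class
    one-vs-rest sensitivity/specificity and overall accuracy, and builds the
    ROC (trapezoid AUC) from the held-out decision values of
    ``positive_class`` versus the rest.
    """
    scores = np.asarray(scores, dtype=float)
    y_arr = np.asarray(y)
    classes = sorted(set(y))
    positive = positive_class or classes[-1]
    if positive not in classes:
        raise ChemometricsError(
            f"positive_class {positive!r} not among labels {classes}"
        )
    splits = _stratified_folds(y, folds, seed)
    _check_train_folds(y_arr, splits)
    per_fold = [
        (train, test, scores[train], scores[test], y_arr[train])
        for train, test in splits
    ]
    return _report_from_folds(per_fold, y_arr, classes, params, positive)


# ---------------------------------------------------------------------------
# End-to-end composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChemometricsConfig:
    """Parameters of the full PLS–SVM chain."""

    n_components_max: int = 10
    selection_threshold: float = 0.05
    selection_form: str = "improvement"
    folds: int = 10
    seed: int = 0
    c_grid: tuple[float, ...] = field(default_factory=default_c_grid)
    sigma_grid: tuple[float, ...] = field(default_factory=default_sigma_grid)
    positive_class: str = "OVX"
    binary_tasks: bool = True
    refit_pls_per_fold: bool = True


@dataclass(frozen=True)
class TaskResult:
    """One classification task (binary pair or all classes)."""

    task: str
    n_components: int
    selection: ComponentSelection
    cv: CVResult
    report: ClassificationReport


@dataclass(frozen=True)
class PipelineResult:
    """Everything :func:`run_pls_svm` computes."""

    pls: PLSFit
    tasks: Mapping[str, TaskResult]
    config: ChemometricsConfig

    @property
    def three_class(self) -> TaskResult:
        return self.tasks["all"]


def _positive_for(labels: Sequence[str], preferred: str) -> str:
    if preferred in labels:
        return preferred
    non_ref = [c for c in labels if c != "Sham"]
    return non_ref[-1] if non_ref else sorted(labels)[-1]


def _run_task(
    data: LabeledSpectraMatrix, config: ChemometricsConfig, task_name: str
) -> TaskResult:
    n, p = data.X.shape
    k_max = min(config.n_components_max, n - 2, p)
    selection = compute_msep_curve(data, k_max, folds=config.folds, seed=config.seed)
    n_sel = select_components(selection, config.selection_threshold,
                              form=config.selection_form)
    selection = replace(selection, n_selected=n_sel,
                        improvement_threshold=config.selection_threshold)

    y_arr = np.asarray(data.y)
    classes = sorted(set(data.y))
    splits = _stratified_folds(data.y, config.folds, config.seed)
    _check_train_folds(y_arr, splits)

    fold_assignments = np.empty(n, dtype=int)
    per_fold = []
    if config.refit_pls_per_fold:
        for f, (train, test) in enumerate(splits):
            fold_assignments[test] = f
            sub = LabeledSpectraMatrix(
                X=data.X[train], y=tuple(y_arr[train]),
                sample_ids=tuple(np.asarray(data.sample_ids)[train]),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_pls(sub, n_sel)
            kk = min(n_sel, fit.n_components)
            per_fold.append((
                train, test,
                fit.transform(data.X[train], kk),
                fit.transform(data.X[test], kk),
                y_arr[train],
            ))
    else:
        full = fit_pls(data, n_sel)
        scores = full.scores[:, : full.n_components]
        for f, (train, test) in enumerate(splits):
            fold_assignments[test] = f
            per_fold.append((train, test, scores[train], scores[test], y_arr[train]))

    cv = _grid_search(
        per_fold, y_arr, classes, tuple(config.c_grid), tuple(config.sigma_grid),
        n, config.seed, fold_assignments,
    )
    positive = _positive_for(classes, config.positive_class)
    report = _report_from_folds(per_fold, y_arr, classes, cv.best_params, positive)
    return TaskResult(task=task_name, n_components=n_sel, selection=selection,
                      cv=cv, report=report)


def run_pls_svm(data: LabeledSpectraMatrix, config: ChemometricsConfig | None = None) -> PipelineResult:
    """Full PLS–SVM analysis: component selection, grid search, evaluation.

    Runs the all-classes task plus (by default) every pairwise binary task,
    each with its own MSEP-based component selection.  The returned
    :class:`PLSFit` on the full data provides the loadings and cumulative
    response-variance proportions for reporting; classification accuracy is
    always computed with fold-internal PLS projections unless
    ``refit_pls_per_fold`` is disabled.
    """
    config = config or ChemometricsConfig()
    classes = data.classes
    if len(classes) < 2:
        raise ChemometricsError("need at least 2 classes")

    n, p = data.X.shape
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full_fit = fit_pls(data, min(config.n_components_max, n - 1, p))

    tasks: dict[str, TaskResult] = {"all": _run_task(data, config, "all")}
    if config.binary_tasks and len(classes) > 2:
        for i, a in enumerate(classes):
            for b in classes[i + 1:]:
                name = f"{a}_vs_{b}"
                tasks[name] = _run_task(data.subset((a, b)), config, name)
    return PipelineResult(pls=full_fit, tasks=tasks, config=config)
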