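"""OPLS-DA: PLS with an integrated orthogonal signal correction filter.

For a two-class problem (y coded 0/1), the systematic variation in the
peak table that is correlated with class is modeled in ONE predictive
component (scores t1, weights w1, covariance loadings p1), while
systematic variation orthogonal to y is peeled off into separate
orthogonal components before the predictive component is computed. The
orthogonal filter is what keeps between-subject (confounding) variation
out of the class axis: adding purely orthogonal variation to a sample
does not move its predicted y.

Model quality is summarized by R2X / R2Y (explained fractions of X- and
y-variance) and Q2 (fraction of y-variance predicted under k-fold full
cross-validation, 7 folds by default). Variable significance is assessed
by randomly permuting y many times, refitting the model each time, and
comparing each variable's |w1| with its own permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations as _all_permutations
from math import factorial

import numpy as np

from .datatypes import PeakTable

__all__ = [
    "OplsDaModel",
    "PredictionReport",
    "PermutationResult",
    "fit_oplsda",
    "cross_validate",
    "predict_samples",
    "permutation_test",
    "update_and_predict_longitudinal",
]

logger = logging.getLogger("hmcr")

CLASS_THRESHOLD = 0.5  # midpoint of the 0/1 class coding
DEFAULT_FOLDS = 7
DEFAULT_N_PERM = 10_000


class InputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# core decomposition (operates on already scaled data)


def _opls_core(Z: np.ndarray, yc: np.ndarray, n_ortho: int):
    """One predictive + n_ortho orthogonal components on scaled data."""
    X = Z.copy()
    W_o, P_o, T_o = [], [], []
    for _ in range(n_ortho):
        w = X.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w = w / nw
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p = X.T @ t / tt
        w_o = p - float(w @ p) * w
        nwo = np.linalg.norm(w_o)
        if nwo < 1e-10:
            break  # no orthogonal variation left
        w_o = w_o / nwo
        t_o = X @ w_o
        tt_o = float(t_o @ t_o)
        if tt_o < 1e-12:
            break
        p_o = X.T @ t_o / tt_o
        X = X - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
    w = X.T @ yc
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise InputError("y carries no variation correlated with X")
    w = w / nw
    t = X @ w
    tt = float(t @ t)
    p = X.T @ t / tt
    q = float(yc @ t / tt)
    return w, p, q, t, W_o, P_o, T_o, X - np.outer(t, p)


@dataclass
class OplsDaModel:
    """Fitted OPLS-DA model (one predictive + n_ortho orthogonal components)."""

    x_means: np.ndarray
    x_scales: np.ndarray
    w1: np.ndarray  # unit-norm predictive weights
    p1: np.ndarray  # predictive loadings
    covariance_loadings: np.ndarray  # w*1[p]: loading-scale covariance with t1
    ortho_weights: list[np.ndarray]
    ortho_loadings: list[np.ndarray]
    t1: np.ndarray
    t_ortho: np.ndarray  # n x n_ortho
    q_coef: float
    y_mean: float
    r2x: float
    r2y: float
    q2: float | None
    n_ortho: int
    profile_ids: list[str]
    class_threshold: float = CLASS_THRESHOLD
    x_train: np.ndarray | None = None  # raw training areas (for model updating)
    y_train: np.ndarray | None = None
    sample_ids: list[str] = field(default_factory=list)

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_means) / self.x_scales

    def predict_y(self, X: np.ndarray) -> np.ndarray:
        """Predicted y for raw (unscaled) rows with matching variables."""
        Z = self._scale(np.atleast_2d(np.asarray(X, dtype=float)))
        for w_o, p_o in zip(self.ortho_weights, self.ortho_loadings):
            t_o = Z @ w_o
            Z = Z - np.outer(t_o, p_o)
        t = Z @ self.w1
        return t * self.q_coef + self.y_mean

    def to_dict(self) -> dict:
        return {
            "x_means": self.x_means.tolist(),
            "x_scales": self.x_scales.tolist(),
            "w1": self.w1.tolist(),
            "p1": self.p1.tolist(),
            "covariance_loadings": self.covariance_loadings.tolist(),
            "ortho_weights": [w.tolist() for w in self.ortho_weights],
            "ortho_loadings": [p.tolist() for p in self.ortho_loadings],
            "q_coef": self.q_coef,
            "y_mean": self.y_mean,
            "r2x": self.r2x,
            "r2y": self.r2y,
            "q2": self.q2,
            "n_ortho": self.n_ortho,
            "profile_ids": self.profile_ids,
            "class_threshold": self.class_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OplsDaModel":
        return cls(
            x_means=np.asarray(d["x_means"]),
            x_scales=np.asarray(d["x_scales"]),
            w1=np.asarray(d["w1"]),
            p1=np.asarray(d["p1"]),
            covariance_loadings=np.asarray(d["covariance_loadings"]),
            ortho_weights=[np.asarray(w) for w in d["ortho_weights"]],
            ortho_loadings=[np.asarray(p) for p in d["ortho_loadings"]],
            t1=np.empty(0),
            t_ortho=np.empty((0, 0)),
            q_coef=float(d["q_coef"]),
            y_mean=float(d["y_mean"]),
            r2x=float(d["r2x"]),
            r2y=float(d["r2y"]),
            q2=d.get("q2"),
            n_ortho=int(d["n_ortho"]),
            profile_ids=list(d["profile_ids"]),
            class_threshold=float(d.get("class_threshold", CLASS_THRESHOLD)),
        )


@dataclass
class PredictionReport:
    """Per-sample predictions with optional CV / test-set accuracies (%)."""

    sample_ids: list[str]
    predicted_y: np.ndarray
    predicted_class: np.ndarray
    accuracy_cv: float | None = None
    accuracy_test: float | None = None

    def to_dict(self) -> dict:
        return {
            "sample_ids": self.sample_ids,
            "predicted_y": [float(v) for v in self.predicted_y],
            "predicted_class": [int(v) for v in self.predicted_class],
            "accuracy_cv": self.accuracy_cv,
            "accuracy_test": self.accuracy_test,
        }


@dataclass
class PermutationResult:
    """Per-variable |w1| against its own permutation null distribution."""

    n_perm: int
    alpha: float
    original_w: np.ndarray  # |w1| per variable
    null_quantile: np.ndarray  # (1 - alpha) quantile of each null
    significant: np.ndarray  # boolean mask
    profile_ids: list[str]

    def significant_ids(self) -> list[str]:
        return [pid for pid, s in zip(self.profile_ids, self.significant) if s]


def _validate_xy(pt: PeakTable, y) -> tuple[np.ndarray, np.ndarray]:
    X = pt.areas
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != X.shape[0]:
        raise InputError("y length must equal the number of samples")
    if len(np.unique(y)) < 2:
        raise InputError("both classes must be present in y")
    return X, y


def _drop_constant(X: np.ndarray, ids: list[str]):
    scales = X.std(axis=0, ddof=1)
    keep = scales > 0
    if not keep.all():
        dropped = [ids[j] for j in np.nonzero(~keep)[0]]
        logger.warning("dropping constant variables: %s", dropped)
    return keep


def fit_oplsda(
    pt: PeakTable,
    y,
    n_ortho: int | str = "auto",
    folds: int = DEFAULT_FOLDS,
    max_ortho: int = 5,
) -> OplsDaModel:
    """Fit an OPLS-DA model to a peak table and a binary class vector.

    Variables are mean-centered and scaled to unit variance internally;
    constant variables are dropped with a warning. ``n_ortho="auto"``
    chooses the orthogonal component count maximizing cross-validated Q2
    (ties to the smaller count).
    """
    X, y = _validate_xy(pt, y)
    keep = _drop_constant(X, pt.profile_ids)
    Xk = X[:, keep]
    ids = [pid for pid, k in zip(pt.profile_ids, keep) if k]
    kept_pt = PeakTable(
        areas=Xk, sample_ids=list(pt.sample_ids), profile_ids=ids,
        normalized=pt.normalized,
    )

    if n_ortho == "auto":
        bound = min(max_ortho, Xk.shape[0] - 2, Xk.shape[1] - 1)
        best, best_q2 = 0, -np.inf
        for cand in range(0, max(bound, 0) + 1):
            _, q2 = cross_validate(kept_pt, y, n_ortho=cand, folds=folds)
            if q2 > best_q2 + 1e-12:
                best, best_q2 = cand, q2
        n_ortho = best
        logger.info("auto n_ortho = %d (Q2 = %.4f)", best, best_q2)

    means = Xk.mean(axis=0)
    scales = Xk.std(axis=0, ddof=1)
    Z = (Xk - means) / scales
    y_mean = float(y.mean())
    yc = y - y_mean

    w, p, q, t, W_o, P_o, T_o, X_res = _opls_core(Z, yc, int(n_ortho))
    ssx = float((Z**2).sum())
    r2x = 1.0 - float((X_res**2).sum()) / ssx if ssx > 0 else 0.0
    yhat = t * q
    ssy = float((yc**2).sum())
    r2y = 1.0 - float(((yc - yhat) ** 2).sum()) / ssy if ssy > 0 else 0.0

    _, q2 = cross_validate(kept_pt, y, n_ortho=int(n_ortho), folds=folds)

    return OplsDaModel(
        x_means=means,
        x_scales=scales,
        w1=w,
        p1=p,
        covariance_loadings=p,  # w*1[p]: covariance of variables with t1
        ortho_weights=W_o,
        ortho_loadings=P_o,
        t1=t,
        t_ortho=np.column_stack(T_o) if T_o else np.empty((len(y), 0)),
        q_coef=q,
        y_mean=y_mean,
        r2x=r2x,
        r2y=r2y,
        q2=q2,
        n_ortho=len(W_o),
        profile_ids=ids,
        x_train=Xk.copy(),
        y_train=y.copy(),
        sample_ids=list(pt.sample_ids),
    )


def _stratified_folds(y: np.ndarray, sample_ids: list[str], folds: int) -> np.ndarray:
    """Deterministic class-stratified round-robin fold assignment.

    Samples are sorted by ID within each class and dealt out cyclically,
    so "7-fold full cross-validation" is reproducible for a given table.
    """
    assignment = np.zeros(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        order = sorted(idx, key=lambda i: str(sample_ids[i]))
        for pos, i in enumerate(order):
            assignment[i] = pos % folds
    return assignment


def cross_validate(
    pt: PeakTable, y, n_ortho: int, folds: int = DEFAULT_FOLDS
) -> tuple[PredictionReport, float]:
    """K-fold full cross-validation: refit (including scaling) per fold.

    Returns the out-of-fold prediction report (with ``accuracy_cv`` as a
    percentage) and Q2 = 1 - PRESS/SS. ``folds = n_samples`` gives
    leave-one-out.
    """
    X, y = _validate_xy(pt, y)
    n = len(y)
    if not 2 <= folds <= n:
        raise InputError(f"folds must lie in [2, {n}]")
    counts = [int((y == c).sum()) for c in np.unique(y)]
    if min(counts) < 2:
        raise InputError("each class needs at least 2 samples for stratified CV")

    keep = _drop_constant(X, pt.profile_ids)
    Xk = X[:, keep]
    assignment = _stratified_folds(y, pt.sample_ids, folds)
    yhat = np.zeros(n)
    for f in np.unique(assignment):
        test = assignment == f
        train = ~test
        Xt = Xk[train]
        means = Xt.mean(axis=0)
        scales = Xt.std(axis=0, ddof=1)
        scales[scales == 0] = 1.0
        Zt = (Xt - means) / scales
        yt = y[train]
        ymean = float(yt.mean())
        w, p, q, t, W_o, P_o, _, _ = _opls_core(Zt, yt - ymean, n_ortho)
        Zv = (Xk[test] - means) / scales
        for w_o, p_o in zip(W_o, P_o):
            Zv = Zv - np.outer(Zv @ w_o, p_o)
        yhat[test] = (Zv @ w) * q + ymean

    press = float(((y - yhat) ** 2).sum())
    ss = float(((y - y.mean()) ** 2).sum())
    q2 = 1.0 - press / ss if ss > 0 else 0.0
    pred_class = (yhat >= CLASS_THRESHOLD).astype(int)
    acc = 100.0 * float((pred_class == y.astype(int)).mean())
    report = PredictionReport(
        sample_ids=list(pt.sample_ids),
        predicted_y=yhat,
        predicted_class=pred_class,
        accuracy_cv=acc,
    )
    return report, q2


def predict_samples(
    model: OplsDaModel, pt_new: PeakTable, y_true=None
) -> PredictionReport:
    """Predict class membership of new samples with a fitted model.

    Columns must match the model's variables (same reference table);
    missing and extra profile IDs are listed in the error. Orthogonal
    variation is filtered with the model's own components before the
    predictive score is formed.
    """
    missing = [p for p in model.profile_ids if p not in pt_new.profile_ids]
    extra = [p for p in pt_new.profile_ids if p not in model.profile_ids]
    if missing or extra:
        raise InputError(
            f"peak table does not match model variables; missing={missing}, extra={extra}"
        )
    order = [pt_new.profile_ids.index(p) for p in model.profile_ids]
    yhat = model.predict_y(pt_new.areas[:, order])
    pred_class = (yhat >= model.class_threshold).astype(int)
    acc = None
    if y_true is not None:
        y_true = np.asarray(y_true, dtype=int).ravel()
        acc = 100.0 * float((pred_class == y_true).mean())
    return PredictionReport(
        sample_ids=list(pt_new.sample_ids),
        predicted_y=yhat,
        predicted_class=pred_class,
        accuracy_test=acc,
    )


def permutation_test(
    pt: PeakTable,
    y,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = 0.05,
    seed: int = 0,
    n_ortho: int = 0,
    exhaustive: bool = False,
) -> PermutationResult:
    """Permutation-based extraction of significantly class-separating variables.

    The class vector is permuted ``n_perm`` times; for each permutation an
    OPLS model (same orthogonal component count as the original) is fitted
    and every variable's |w1| recorded. A variable is significant when its
    original |w1| exceeds the (1 - alpha) quantile of its own null
    distribution. ``exhaustive=True`` enumerates all n! label orderings
    instead of sampling (small n only).
    """
    X, y = _validate_xy(pt, y)
    if not exhaustive and n_perm < 100:
        raise InputError("n_perm must be >= 100 for quantile resolution")
    keep = _drop_constant(X, pt.profile_ids)
    Xk = X[:, keep]
    ids = [pid for pid, k in zip(pt.profile_ids, keep) if k]
    means = Xk.mean(axis=0)
    scales = Xk.std(axis=0, ddof=1)
    Z = (Xk - means) / scales
    yc = y - y.mean()

    def w_abs(y_vec: np.ndarray) -> np.ndarray:
        w, *_ = _opls_core(Z, y_vec, n_ortho)
        return np.abs(w)

    original = w_abs(yc)
    if exhaustive:
        n = len(y)
        if factorial(n) > 50_000:
            raise InputError("exhaustive enumeration limited to small n")
        perms = [np.asarray(p) for p in _all_permutations(range(n))]
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(len(y)) for _ in range(n_perm)]

    null = np.empty((len(perms), Z.shape[1]))
    for i, perm in enumerate(perms):
        yp = yc[perm]
        if np.linalg.norm(Z.T @ yp) < 1e-12:  # pathological permutation
            null[i] = 0.0
        else:
            null[i] = w_abs(yp)
    quant = np.quantile(null, 1.0 - alpha, axis=0)
    return PermutationResult(
        n_perm=len(perms),
        alpha=alpha,
        original_w=original,
        null_quantile=quant,
        significant=original > quant,
        profile_ids=ids,
    )


def update_and_predict_longitudinal(
    model: OplsDaModel,
    pt_test1: PeakTable,
    pt_test2: PeakTable,
    significant: PermutationResult | list[str] | None = None,
    y_test2=None,
    folds: int = DEFAULT_FOLDS,
    stage1_labels=None,
) -> tuple[PredictionReport, OplsDaModel]:
    """Model updating for longitudinal prediction.

    Stage 1 assigns predicted class labels to ``pt_test1``; stage 2 refits
    the model on the original training samples plus ``pt_test1`` (with its
    predicted labels), restricted to the permutation-significant variables;
    stage 3 predicts ``pt_test2`` with the updated model. An empty
    significant set falls back to all variables with a warning.
    ``stage1_labels`` overrides the predicted stage-1 labels (sensitivity
    analysis of label-error propagation).
    """
    if model.x_train is None or model.y_train is None:
        raise InputError("model carries no training data; cannot update")
    stage1 = predict_samples(model, pt_test1)
    if stage1_labels is not None:
        stage1.predicted_class = np.asarray(stage1_labels, dtype=int)

    if isinstance(significant, PermutationResult):
        sig_ids = significant.significant_ids()
    else:
        sig_ids = list(significant) if significant is not None else model.profile_ids
    if not sig_ids:
        logger.warning("empty significant set; falling back to all variables")
        sig_ids = model.profile_ids

    cols_model = [model.profile_ids.index(p) for p in sig_ids]
    cols_new = [pt_test1.profile_ids.index(p) for p in sig_ids]
    X_comb = np.vstack([model.x_train[:, cols_model], pt_test1.areas[:, cols_new]])
    y_comb = np.concatenate([model.y_train, stage1.predicted_class.astype(float)])
    ids_comb = list(model.sample_ids) + list(pt_test1.sample_ids)
    pt_comb = PeakTable(areas=X_comb, sample_ids=ids_comb, profile_ids=sig_ids)
    updated = fit_oplsda(pt_comb, y_comb, n_ortho=model.n_ortho, folds=folds)

    cols_t2 = [pt_test2.profile_ids.index(p) for p in updated.profile_ids]
    pt2 = PeakTable(
        areas=pt_test2.areas[:, cols_t2],
        sample_ids=list(pt_test2.sample_ids),
        profile_ids=list(updated.profile_ids),
    )
    stage3 = predict_samples(updated, pt2, y_true=y_test2)
    return stage3, updated
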