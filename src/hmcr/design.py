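"""Representative-subset selection: PCA scores + maximin space-filling design.

A subset is representative when it spans the systematic between-sample
variation. That variation is captured by PCA of either a metadata table
(one row per subject) or compressed analytical data (one row per sample),
and the subset is chosen in score space by a greedy maximin design: start
from the two mutually farthest points, then repeatedly add the point whose
minimum distance to the already-selected set is largest. Subjects are
selected as units — both the pre- and post-condition samples of a selected
subject enter the subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "PcaModel",
    "SelectionResult",
    "fit_pca",
    "maximin_select",
    "maximin_exhaustive",
    "screen_outliers",
    "diversity_select_metadata",
]


class ScalingError(ValueError):
    pass


class SelectionError(ValueError):
    pass


@dataclass
class PcaModel:
    """Mean-centered, unit-variance-scaled PCA via SVD."""

    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray  # n_vars x A, orthonormal columns
    scores: np.ndarray  # n_obs x A, mutually orthogonal columns
    r2x_per_component: np.ndarray
    columns: list[str] = field(default_factory=list)

    @property
    def cumulative_r2x(self) -> float:
        return float(self.r2x_per_component.sum())

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.means) / self.scales @ self.loadings


def fit_pca(X, n_components: int) -> PcaModel:
    """Fit PCA after mean-centering and unit-variance scaling.

    ``X`` may be a DataFrame (column names are kept for error messages) or
    an array. Constant columns cannot be scaled and raise ``ScalingError``.
    """
    if isinstance(X, pd.DataFrame):
        columns = [str(c) for c in X.columns]
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        columns = [f"x{j}" for j in range(arr.shape[1])]
    if np.isnan(arr).any():
        raise ValueError("PCA input must not contain missing values")
    n_obs, n_vars = arr.shape
    if not 1 <= n_components <= min(n_obs - 1, n_vars):
        raise ValueError(
            f"n_components must lie in [1, {min(n_obs - 1, n_vars)}] for this table"
        )
    means = arr.mean(axis=0)
    scales = arr.std(axis=0, ddof=1)
    dead = np.nonzero(scales == 0)[0]
    if dead.size:
        raise ScalingError(f"constant column cannot be scaled: {columns[dead[0]]!r}")
    Z = (arr - means) / scales
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for a in range(len(s)):
        j = int(np.argmax(np.abs(Vt[a])))
        if Vt[a, j] < 0:
            Vt[a] *= -1.0
            U[:, a] *= -1.0
    total = float((s**2).sum())
    A = n_components
    return PcaModel(
        means=means,
        scales=scales,
        loadings=Vt[:A].T.copy(),
        scores=(U[:, :A] * s[:A]).copy(),
        r2x_per_component=(s[:A] ** 2) / total,
        columns=columns,
    )


@dataclass
class SelectionResult:
    """Outcome of a space-filling selection."""

    selected_indices: list[int]
    criterion_value: float
    space: str
    selected_groups: list = field(default_factory=list)
    outliers: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        crit = self.criterion_value
        return {
            "selected_indices": [int(i) for i in self.selected_indices],
            "criterion_value": None if not np.isfinite(crit) else float(crit),
            "space": self.space,
            "selected_groups": [str(g) for g in self.selected_groups],
            "outliers": [int(i) for i in self.outliers],
        }


def _min_nn_distance(D: np.ndarray, idx: list[int]) -> float:
    if len(idx) < 2:
        return np.inf
    sub = D[np.ix_(idx, idx)]
    return float(min(sub[i, j] for i, j in combinations(range(len(idx)), 2)))


def _greedy_maximin(D: np.ndarray, k: int, candidates: list[int]) -> list[int]:
    if k == 1:
        return [candidates[0]]
    # seed with the mutually farthest pair, ties to lowest (i, j)
    best_pair, best_d = None, -1.0
    for i, j in combinations(candidates, 2):
        if D[i, j] > best_d + 1e-12:
            best_pair, best_d = (i, j), D[i, j]
    selected = list(best_pair)
    while len(selected) < k:
        best_c, best_d = None, -1.0
        for c in candidates:
            if c in selected:
                continue
            d = min(D[c, s] for s in selected)
            if d > best_d + 1e-12:
                best_c, best_d = c, d
        selected.append(best_c)
    return selected


def maximin_exhaustive(points: np.ndarray, k: int) -> tuple[list[int], float]:
    """Brute-force optimal maximin subset (small instances only)."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    D = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    best, best_val = None, -1.0
    for combo in combinations(range(n), k):
        v = _min_nn_distance(D, list(combo))
        if v > best_val + 1e-12:
            best, best_val = list(combo), v
    return best, best_val


#: exhaustive search is used whenever C(n, k) is at most this
EXHAUSTIVE_LIMIT = 5000


def _best_subset(D: np.ndarray, k: int, candidates: list[int]) -> list[int]:
    """Exhaustive below EXHAUSTIVE_LIMIT subsets, greedy beyond."""
    from math import comb

    if comb(len(candidates), k) <= EXHAUSTIVE_LIMIT:
        best, best_val = None, -1.0
        for combo in combinations(candidates, k):
            v = _min_nn_distance(D, list(combo))
            if v > best_val + 1e-12:
                best, best_val = list(combo), v
        return best
    return _greedy_maximin(D, k, candidates)


def maximin_select(
    scores: np.ndarray,
    k: int,
    groups=None,
    space: str = "scores",
    exclude: list[int] | None = None,
    method: str = "auto",
) -> SelectionResult:
    """Maximin space-filling selection in score space.

    Small instances are solved exactly by enumeration; larger ones by the
    greedy farthest-point heuristic (``method`` forces one or the other).
    With ``groups`` (a per-observation label vector, e.g. subject), the
    design operates on group centroids, ``k`` counts groups, and the
    result contains every member observation of each selected group — so
    selecting 8 subjects with pre/post pairing returns 16 samples.
    ``exclude`` removes observations (e.g. flagged outliers) from the
    candidate pool.
    """
    if method == "greedy":
        solver = _greedy_maximin
    elif method == "exhaustive":
        def solver(D, kk, cand):
            best, best_val = None, -1.0
            for combo in combinations(cand, kk):
                v = _min_nn_distance(D, list(combo))
                if v > best_val + 1e-12:
                    best, best_val = list(combo), v
            return best
    elif method == "auto":
        solver = _best_subset
    else:
        raise SelectionError(f"unknown method {method!r}")
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n_obs = scores.shape[0]
    exclude = set(exclude or [])

    if groups is not None:
        groups = np.asarray(groups)
        if groups.shape != (n_obs,):
            raise SelectionError("groups must have one label per observation")
        labels = list(dict.fromkeys(groups.tolist()))  # first-appearance order
        members = {g: np.nonzero(groups == g)[0].tolist() for g in labels}
        labels = [g for g in labels if not set(members[g]) & exclude]
        points = np.vstack([scores[members[g]].mean(axis=0) for g in labels])
        if not 1 <= k <= len(labels):
            raise SelectionError(f"k must lie in [1, {len(labels)}] groups")
        D = np.linalg.norm(points[:, None] - points[None, :], axis=2)
        chosen = solver(D, k, list(range(len(labels))))
        sel_groups = [labels[i] for i in sorted(chosen)]
        indices = sorted(i for g in sel_groups for i in members[g])
        crit = _min_nn_distance(D, chosen)
        return SelectionResult(
            selected_indices=indices,
            criterion_value=crit,
            space=space,
            selected_groups=sel_groups,
            outliers=sorted(exclude),
        )

    candidates = [i for i in range(n_obs) if i not in exclude]
    if not 1 <= k <= len(candidates):
        raise SelectionError(f"k must lie in [1, {len(candidates)}]")
    D = np.linalg.norm(scores[:, None] - scores[None, :], axis=2)
    chosen = solver(D, k, candidates)
    return SelectionResult(
        selected_indices=sorted(chosen),
        criterion_value=_min_nn_distance(D, chosen),
        space=space,
        outliers=sorted(exclude),
    )


def screen_outliers(model: PcaModel, quantile: float = 0.99) -> list[int]:
    """Flag deviating observations by squared score distance.

    The per-observation statistic sum_a t_ia^2 / var(t_a) is compared to a
    chi-square quantile with A degrees of freedom (a Hotelling-T2-style
    screen with the large-n reference distribution).
    """
    t = model.scores
    var = t.var(axis=0, ddof=1)
    var[var == 0] = 1.0
    d2 = (t**2 / var).sum(axis=1)
    cut = chi2.ppf(quantile, df=t.shape[1])
    return [int(i) for i in np.nonzero(d2 > cut)[0]]


def diversity_select_metadata(
    metadata: pd.DataFrame,
    n_components: int,
    k_subjects: int,
    sample_metadata: pd.DataFrame | None = None,
    screen: bool = True,
) -> SelectionResult:
    """PCA of a subject metadata table followed by maximin subject selection.

    ``metadata`` has one row per subject. If ``sample_metadata`` (with a
    ``subject`` column) is given, the selected subjects are expanded to all
    their samples, so k subjects with pre/post sampling yield 2k samples.
    """
    model = fit_pca(metadata, n_components)
    outliers = screen_outliers(model) if screen else []
    result = maximin_select(
        model.scores, k_subjects, space="metadata", exclude=outliers
    )
    subjects = [str(metadata.index[i]) for i in result.selected_indices]
    if sample_metadata is not None:
        mask = sample_metadata["subject"].astype(str).isin(subjects)
        result.selected_indices = [int(i) for i in np.nonzero(mask.to_numpy())[0]]
    result.selected_groups = subjects
    return result
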