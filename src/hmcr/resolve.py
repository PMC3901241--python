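"""Hierarchical multivariate curve resolution (H-MCR).

Stacked multi-sample GC/MS data in a retention-time window is factored as

    X = C S^T + E,    C >= 0, S >= 0, ||S_k|| = 1,

where S holds mass spectra common to all samples and C holds one
chromatographic profile per sample per component; E is the residual.
Resolution is alternating non-negative least squares per time window
(the "hierarchical" part: windows are resolved independently after
alignment). With S fixed, new samples are resolved *predictively* by a
single non-negative projection, so independent data yields the same
metabolite set as the training reference table.

An internal A/B cross-validation guards against unstable profiles: the
samples are split into two representative halves, each half is resolved
independently, each is predicted with the other's spectra, and a profile
is kept only when spectra and cross-predicted profiles agree (Pearson
correlation above 0.95 by default, for all three comparisons).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    GCMSDataset,
    ReferenceTable,
    ResolvedWindow,
    SpectralProfile,
    TimeWindow,
)
from .nnls import nnls_multi

__all__ = [
    "split_windows",
    "choose_rank",
    "resolve_window",
    "predict_window",
    "stability_validate",
    "extract_profiles",
    "build_reference_table",
    "integrate_areas",
    "quantify",
    "match_factor",
    "compare_reference_tables",
    "MatchReport",
]

logger = logging.getLogger("hmcr")

STABILITY_THRESHOLD = 0.95  # Pearson correlation criterion for profile stability
MATCH_FACTOR_MIN = 700  # spectra are equivalent above this match factor...
RT_TOLERANCE_S = 1.0  # ...and within this retention-time difference


class ConfigurationError(ValueError):
    pass


class InputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# window splitting


def split_windows(dataset: GCMSDataset, target_width: int) -> list[TimeWindow]:
    """Tile the retention axis into windows of roughly ``target_width`` scans.

    Cut points are placed at the local minimum of the mean TIC nearest to
    each multiple of ``target_width`` (searched within a third of a window
    on either side), so peaks are not cut mid-elution; on a flat TIC the
    cuts fall exactly on the multiples. Windows tile ``[0, n_scans)``.
    """
    if target_width < 3:
        raise ConfigurationError("target_width must be at least 3 scans")
    n_scans = len(dataset.rt_axis)
    mean_tic = np.mean([s.tic for s in dataset.samples], axis=0)
    n_windows = max(1, int(round(n_scans / target_width)))
    radius = max(1, target_width // 3)

    cuts = [0]
    for j in range(1, n_windows):
        nominal = j * target_width
        lo = max(cuts[-1] + 3, nominal - radius)
        hi = min(n_scans - 3, nominal + radius)
        if lo > hi:
            continue
        cand = np.arange(lo, hi + 1)
        order = sorted(cand, key=lambda i: (mean_tic[i], abs(i - nominal), i))
        cuts.append(int(order[0]))
    cuts.append(n_scans)

    windows = []
    for wid, (a, b) in enumerate(zip(cuts[:-1], cuts[1:])):
        blocks = [s.intensities[a:b] for s in dataset.samples]
        windows.append(
            TimeWindow(
                window_id=wid,
                scan_range=(a, b),
                stacked_data=np.vstack(blocks),
                n_samples=len(dataset),
            )
        )
    return windows


# ---------------------------------------------------------------------------
# MCR-ALS


def choose_rank(
    X: np.ndarray,
    variance_target: float = 0.995,
    gap_ratio: float = 10.0,
    noise_factor: float = 3.0,
) -> int:
    """Component count from the singular spectrum of a stacked window.

    Three truncation rules, the earliest wins: cumulative variance
    reaching ``variance_target``; a singular-value ratio gap larger than
    ``gap_ratio``; and a noise floor — singular values below
    ``noise_factor`` times the median singular value, which tracks the
    flat plateau that measurement noise produces, do not count. The noise
    rule keeps the variance rule from absorbing dozens of noise
    components when the data is not close to noise-free.
    """
    s_full = np.linalg.svd(X, compute_uv=False)
    if s_full.size == 0 or s_full[0] <= 0:
        return 1
    s = s_full[s_full > 1e-12 * s_full[0]]
    energy = s**2
    cum = np.cumsum(energy) / energy.sum()
    k_cum = int(np.argmax(cum >= variance_target)) + 1
    k_gap = s.size
    for i in range(s.size - 1):
        if s[i + 1] <= 0 or s[i] / s[i + 1] > gap_ratio:
            k_gap = i + 1
            break
    # the plateau median must come from the FULL spectrum: after the eps
    # filter a noise-free window would have only signal values left
    k_noise = max(1, int((s > noise_factor * np.median(s_full)).sum()))
    return max(1, min(k_cum, k_gap, k_noise))


def _purest_scan_init(X: np.ndarray, k: int) -> np.ndarray:
    """Deterministic initial spectra: the k most mutually independent scans.

    Greedy orthogonal selection — first the scan with the largest norm,
    then repeatedly the scan with the largest residual after projecting
    out the span of the already-chosen scans.
    """
    resid = X.copy()
    chosen: list[int] = []
    basis: list[np.ndarray] = []
    for _ in range(k):
        norms = np.linalg.norm(resid, axis=1)
        if chosen:
            norms[chosen] = -1.0
        i = int(np.argmax(norms))
        chosen.append(i)
        v = X[i].astype(float).copy()
        for b in basis:
            v -= (v @ b) * b
        nv = np.linalg.norm(v)
        if nv > 1e-12:
            basis.append(v / nv)
            resid = resid - np.outer(resid @ basis[-1], basis[-1])
    S0 = np.clip(X[chosen].astype(float), 0.0, None)
    norms = np.linalg.norm(S0, axis=1)
    norms[norms == 0] = 1.0
    return (S0 / norms[:, None]).T  # n_mz x k


def resolve_window(
    window: TimeWindow,
    n_components: int | str = "auto",
    max_iter: int = 500,
    tol: float = 1e-8,
) -> ResolvedWindow:
    """Alternating non-negative least squares on one stacked time window.

    Both block updates are exact NNLS solves, so the Frobenius residual is
    non-increasing across iterations; spectra are renormalized to unit
    Euclidean norm each round with the magnitude carried into C. Stops
    when the relative residual change drops below ``tol`` or after
    ``max_iter`` iterations.
    """
    X = window.stacked_data
    if np.any(X < 0):
        raise InputError("stacked window data must be non-negative")
    rank_bound = min(X.shape)
    if n_components == "auto":
        k = choose_rank(X)
        logger.info("window %d: auto component count = %d", window.window_id, k)
    else:
        k = int(n_components)
        if k < 1:
            raise ConfigurationError("n_components must be >= 1")
    if k > rank_bound:
        logger.warning(
            "window %d: n_components %d exceeds rank bound %d, reduced",
            window.window_id,
            k,
            rank_bound,
        )
        k = rank_bound

    x_norm2 = float((X**2).sum())
    if x_norm2 == 0:
        S = np.zeros((X.shape[1], k))
        C = np.zeros((X.shape[0], k))
        return ResolvedWindow(
            window_id=window.window_id,
            scan_range=window.scan_range,
            spectra=S.T,
            chrom_profiles=_split_blocks(C, window),
            residual_fraction=0.0,
            residual_history=np.zeros(1),
        )

    S = _purest_scan_init(X, k)  # n_mz x k, unit columns
    history = []
    prev = np.inf
    for _ in range(max_iter):
        C = nnls_multi(S, X.T).T  # rows x k
        S = nnls_multi(C, X).T  # n_mz x k
        norms = np.linalg.norm(S, axis=0)
        norms[norms == 0] = 1.0
        S /= norms
        C *= norms
        resid = float(((X - C @ S.T) ** 2).sum()) / x_norm2
        history.append(resid)
        if prev - resid < tol * max(prev, 1e-15):
            break
        prev = resid

    return ResolvedWindow(
        window_id=window.window_id,
        scan_range=window.scan_range,
        spectra=S.T.copy(),
        chrom_profiles=_split_blocks(C, window),
        residual_fraction=history[-1],
        residual_history=np.asarray(history),
    )


def _split_blocks(C: np.ndarray, window: TimeWindow) -> list[np.ndarray]:
    w = window.n_scans
    return [C[i * w : (i + 1) * w].copy() for i in range(window.n_samples)]


def predict_window(
    new_window: TimeWindow,
    spectra: np.ndarray,
    method: str = "nnls",
) -> list[np.ndarray]:
    """Resolve new samples against fixed spectra (predictive resolution).

    Each scan's spectrum is projected onto the given S by non-negative
    least squares (or plain least squares with ``method="plain"``); the
    spectra themselves are never updated. Returns one window_scans x k
    chromatographic block per sample.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))  # k x n_mz
    X = new_window.stacked_data
    if spectra.shape[1] != X.shape[1]:
        raise InputError(
            f"m/z axis mismatch: spectra have {spectra.shape[1]} channels, "
            f"window has {X.shape[1]}"
        )
    S = spectra.T  # n_mz x k
    if method == "nnls":
        C = nnls_multi(S, X.T).T
    elif method == "plain":
        C = np.linalg.lstsq(S, X.T, rcond=None)[0].T
    else:
        raise ConfigurationError(f"unknown prediction method {method!r}")
    return _split_blocks(C, new_window)


def residual_fraction(window: TimeWindow, spectra: np.ndarray, blocks) -> float:
    """||X - C S^T||^2 / ||X||^2 for predicted chromatographic blocks."""
    X = window.stacked_data
    C = np.vstack(blocks)
    den = float((X**2).sum())
    if den == 0:
        return 0.0
    return float(((X - C @ np.atleast_2d(spectra)) ** 2).sum()) / den


def prediction_residuals(
    window: TimeWindow, spectra: np.ndarray, blocks, threshold: float | None = None
) -> np.ndarray:
    """Per-sample residual fractions of a predictive resolution.

    A sample containing variation the reference spectra cannot explain
    (an unseen component) shows an elevated residual; with ``threshold``
    given, a boolean out-of-model flag per sample is returned instead.
    """
    S = np.atleast_2d(spectra)
    w = window.n_scans
    out = np.empty(window.n_samples)
    for i in range(window.n_samples):
        X = window.stacked_data[i * w : (i + 1) * w]
        den = float((X**2).sum())
        resid = float(((X - blocks[i] @ S) ** 2).sum())
        out[i] = resid / den if den > 0 else 0.0
    return out > threshold if threshold is not None else out


# ---------------------------------------------------------------------------
# A/B stability validation


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def _greedy_match(SA: np.ndarray, SB: np.ndarray) -> list[tuple[int, int, float]]:
    """One-to-one matching of spectra rows by maximal cosine, greedy."""
    ka, kb = SA.shape[0], SB.shape[0]
    pairs = sorted(
        ((i, j, _cosine(SA[i], SB[j])) for i in range(ka) for j in range(kb)),
        key=lambda p: (-p[2], p[0], p[1]),
    )
    used_a, used_b, out = set(), set(), []
    for i, j, c in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((i, j, c))
    return out


def ab_split(window: TimeWindow, n_samples: int) -> tuple[list[int], list[int]]:
    """Representative A/B split of the samples in one window.

    Each sample is characterized by its total mass spectrum (sum of all
    scans in the window); PCA of these vectors followed by a maximin
    design selects half the samples as set A — a dynamic, per-window
    selection that spreads the compositional diversity over both halves.
    """
    from .design import maximin_select

    w = window.n_scans
    totals = np.vstack(
        [window.stacked_data[i * w : (i + 1) * w].sum(axis=0) for i in range(n_samples)]
    )
    Z = totals - totals.mean(axis=0)
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    A = max(1, min(2, n_samples - 1))
    scores = U[:, :A] * s[:A]
    k = n_samples // 2
    sel = maximin_select(scores, k, space="total-mass-spectrum")
    set_a = list(sel.selected_indices)
    set_b = [i for i in range(n_samples) if i not in set_a]
    return set_a, set_b


def _subset_window(window: TimeWindow, indices: list[int]) -> TimeWindow:
    w = window.n_scans
    blocks = [window.stacked_data[i * w : (i + 1) * w] for i in indices]
    return TimeWindow(
        window_id=window.window_id,
        scan_range=window.scan_range,
        stacked_data=np.vstack(blocks),
        n_samples=len(indices),
    )


def stability_validate(
    dataset: GCMSDataset,
    window: TimeWindow,
    threshold: float = STABILITY_THRESHOLD,
    n_components: int | str = "auto",
    split: tuple[list[int], list[int]] | None = None,
) -> list[SpectralProfile]:
    """Resolve a window and flag profiles that survive A/B cross-validation.

    The window's samples are split into sets A and B (by PCA + maximin on
    total mass spectra unless an explicit ``split`` is given), each set is
    resolved independently, A is predicted with S_B and B with S_A, and a
    profile is stable iff the Pearson correlations of the matched spectra
    and of both cross-predicted chromatographic profiles all exceed
    ``threshold``. With fewer than 4 samples validation is skipped and
    every profile is flagged unstable.
    """
    resolved = resolve_window(window, n_components)
    profiles = extract_profiles(resolved, dataset.rt_axis)
    n = window.n_samples
    if n < 4:
        logger.warning(
            "window %d: %d samples is too few for A/B validation; "
            "all profiles flagged unstable",
            window.window_id,
            n,
        )
        return profiles

    set_a, set_b = split if split is not None else ab_split(window, n)
    win_a = _subset_window(window, set_a)
    win_b = _subset_window(window, set_b)
    # each half picks its own component count: forcing the full-data rank
    # onto a half that lacks a component would split a real profile there
    res_a = resolve_window(win_a, "auto")
    res_b = resolve_window(win_b, "auto")

    pairs = _greedy_match(res_a.spectra, res_b.spectra)
    ca_pred = predict_window(win_a, res_b.spectra)  # profiles of A under S_B
    cb_pred = predict_window(win_b, res_a.spectra)

    CA = np.vstack(res_a.chrom_profiles)
    CB = np.vstack(res_b.chrom_profiles)
    CAp = np.vstack(ca_pred)
    CBp = np.vstack(cb_pred)

    stable_a: set[int] = set()
    for i, j, _ in pairs:
        r_s = _pearson(res_a.spectra[i], res_b.spectra[j])
        r_ca = _pearson(CA[:, i], CAp[:, j])
        r_cb = _pearson(CB[:, j], CBp[:, i])
        if r_s > threshold and r_ca > threshold and r_cb > threshold:
            stable_a.add(i)

    # map full-resolution profiles onto set-A profiles by spectral match
    full_pairs = _greedy_match(resolved.spectra, res_a.spectra)
    for i, j, c in full_pairs:
        profiles[i].stable = bool(j in stable_a and c > threshold)
    return profiles


def extract_profiles(
    resolved: ResolvedWindow, rt_axis: np.ndarray, prefix: str | None = None
) -> list[SpectralProfile]:
    """Spectral profiles with apex retention times from a resolved window.

    The apex is the scan where the component's mean chromatographic
    profile (over samples) peaks.
    """
    prefix = prefix if prefix is not None else f"w{resolved.window_id:02d}"
    mean_c = np.mean(resolved.chrom_profiles, axis=0)  # window_scans x k
    out = []
    for j in range(resolved.n_components):
        apex_scan = resolved.scan_range[0] + int(np.argmax(mean_c[:, j]))
        spec = resolved.spectra[j]
        nrm = np.linalg.norm(spec)
        out.append(
            SpectralProfile(
                profile_id=f"{prefix}_m{j:02d}",
                spectrum=spec / nrm if nrm > 0 else spec,
                apex_rt=float(rt_axis[apex_scan]),
                window_id=resolved.window_id,
                stable=False,
            )
        )
    return out


def build_reference_table(
    window_profiles: list[list[SpectralProfile]],
    mz_axis: np.ndarray,
    window_ranges: dict[int, tuple[int, int]] | None = None,
    stable_only: bool = True,
    provenance: dict | None = None,
) -> ReferenceTable:
    """Concatenate (stable) profiles across windows into a reference table.

    Profiles are ordered deterministically by (window, apex retention
    time); an empty result yields an explicit empty table. Duplicated
    split-peak profiles in adjacent windows are retained — de-duplication
    is the job of downstream reference-table comparison.
    """
    flat = [p for plist in window_profiles for p in plist]
    if stable_only:
        flat = [p for p in flat if p.stable]
    flat.sort(key=lambda p: (p.window_id, p.apex_rt, p.profile_id))
    prov = dict(provenance or {})
    if window_ranges is not None:
        prov["windows"] = {str(k): [int(a), int(b)] for k, (a, b) in window_ranges.items()}
    return ReferenceTable(profiles=flat, mz_axis=np.asarray(mz_axis), provenance=prov)


# ---------------------------------------------------------------------------
# quantification


def integrate_areas(chrom_blocks: list[np.ndarray]) -> np.ndarray:
    """Trapezoidal areas (unit scan spacing) per sample per component.

    ``chrom_blocks`` holds one window_scans x k matrix per sample; the
    result is n_samples x k. Empty input yields an empty array.
    """
    if not chrom_blocks:
        return np.empty((0, 0))
    return np.vstack([np.trapezoid(np.atleast_2d(c), axis=0) for c in chrom_blocks])


def quantify(
    dataset: GCMSDataset,
    reference: ReferenceTable,
    method: str = "nnls",
):
    """Predictively resolve every sample against a reference table.

    Windows are taken from the table's provenance; each window's stable
    spectra are fixed and the per-sample chromatographic profiles are
    obtained by non-negative projection, then integrated to areas.
    Returns a :class:`~hmcr.datatypes.PeakTable` (samples x profiles).
    """
    from .datatypes import PeakTable

    windows = reference.provenance.get("windows")
    if windows is None:
        raise InputError("reference table carries no window ranges in provenance")
    if len(reference.mz_axis) != len(dataset.mz_axis):
        raise InputError("dataset m/z axis does not match the reference table")

    n = len(dataset)
    cols: list[np.ndarray] = []
    ids: list[str] = []
    by_window: dict[int, list[SpectralProfile]] = {}
    for p in reference.profiles:
        by_window.setdefault(p.window_id, []).append(p)
    for wid in sorted(by_window):
        a, b = windows[str(wid)]
        plist = by_window[wid]
        S = np.vstack([p.spectrum for p in plist])
        blocks = [s.intensities[a:b] for s in dataset.samples]
        win = TimeWindow(
            window_id=wid, scan_range=(a, b), stacked_data=np.vstack(blocks), n_samples=n
        )
        C = predict_window(win, S, method=method)
        cols.append(integrate_areas(C))
        ids.extend(p.profile_id for p in plist)
    areas = np.hstack(cols) if cols else np.empty((n, 0))
    return PeakTable(
        areas=np.clip(areas, 0.0, None),
        sample_ids=dataset.sample_ids,
        profile_ids=ids,
    )


# ---------------------------------------------------------------------------
# spectral matching


def match_factor(a, b, mz_axis: np.ndarray | None = None) -> int:
    """NIST-style 0..999 similarity between two mass spectra.

    Spectra are weighted by sqrt(intensity) * m/z and compared by squared
    cosine, scaled to 999 for a perfect match and 0 for spectra with no
    peaks in common. Symmetric and invariant to intensity scaling; a zero
    spectrum scores 0.
    """
    if isinstance(a, SpectralProfile):
        sa, sb = a.spectrum, b.spectrum
    else:
        sa, sb = np.asarray(a, float), np.asarray(b, float)
    if mz_axis is None:
        mz_axis = np.arange(1, len(sa) + 1, dtype=float)
    if sa.shape != sb.shape or sa.shape != mz_axis.shape:
        raise InputError("spectra must share one m/z axis")
    wa = np.sqrt(np.clip(sa, 0, None)) * mz_axis
    wb = np.sqrt(np.clip(sb, 0, None)) * mz_axis
    na, nb = np.linalg.norm(wa), np.linalg.norm(wb)
    if na == 0 or nb == 0:
        return 0
    cos = float(wa @ wb / (na * nb))
    return int(round(999 * cos * cos))


@dataclass
class MatchReport:
    """Outcome of comparing two reference tables."""

    matches: list[tuple[str, str, int, float]]  # (id_a, id_b, mf, |dRT| seconds)
    n_a: int
    n_b: int
    unmatched_a: list[str] = field(default_factory=list)
    unmatched_b: list[str] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.matches)

    @property
    def shared_fraction(self) -> float:
        return self.n_matched / self.n_a if self.n_a else 0.0

    def to_dict(self) -> dict:
        return {
            "matches": [
                {"id_a": a, "id_b": b, "match_factor": mf, "rt_diff_s": dt}
                for a, b, mf, dt in self.matches
            ],
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_matched": self.n_matched,
            "shared_fraction": self.shared_fraction,
        }


def compare_reference_tables(
    table_a: ReferenceTable,
    table_b: ReferenceTable,
    mf_min: int = MATCH_FACTOR_MIN,
    rt_tol: float = RT_TOLERANCE_S,
) -> MatchReport:
    """Greedy best-match pairing of two reference tables.

    Two profiles are candidate matches only when their match factor
    exceeds ``mf_min`` AND their retention times differ by at most
    ``rt_tol`` seconds; candidates are paired one-to-one in order of
    decreasing match factor (ties by retention proximity, then by index).
    """
    if len(table_a.mz_axis) != len(table_b.mz_axis):
        raise InputError("reference tables must share the m/z axis")
    cands = []
    for i, pa in enumerate(table_a.profiles):
        for j, pb in enumerate(table_b.profiles):
            dt = abs(pa.apex_rt - pb.apex_rt)
            if dt > rt_tol:
                continue
            mf = match_factor(pa.spectrum, pb.spectrum, table_a.mz_axis)
            if mf > mf_min:
                cands.append((i, j, mf, dt))
    cands.sort(key=lambda c: (-c[2], c[3], c[0], c[1]))
    used_a, used_b, matches = set(), set(), []
    for i, j, mf, dt in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append(
            (table_a.profiles[i].profile_id, table_b.profiles[j].profile_id, mf, dt)
        )
    return MatchReport(
        matches=matches,
        n_a=len(table_a),
        n_b=len(table_b),
        unmatched_a=[
            p.profile_id for i, p in enumerate(table_a.profiles) if i not in used_a
        ],
        unmatched_b=[
            p.profile_id for j, p in enumerate(table_b.profiles) if j not in used_b
        ],
    )
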