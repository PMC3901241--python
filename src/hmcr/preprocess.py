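"""Chromatographic alignment, crude hierarchical compression, normalization.

Alignment undoes a global integer retention drift per sample by maximizing
the cross-correlation of each total-ion chromatogram against a medoid
reference; the common offset left over is fixed by forcing the median
applied shift to zero, so alignment recovers per-sample drift up to the
cohort's median drift.

Compression produces a short fixed-length intensity vector per sample
(windowed base-peak and total-ion sums) — a fast, crude description of
compositional differences that retains the systematic between-sample
variation and is cheap enough to run on every sample before any curve
resolution.
"""

from __future__ import annotations

import numpy as np

from .datatypes import CompressionVector, GCMSDataset, IonMap, PeakTable

__all__ = ["align", "compress", "normalize_peaktable", "window_edges"]


class InputError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


def _shift_rows(x: np.ndarray, s: int) -> np.ndarray:
    """Shift a (scans x m/z) matrix forward by ``s`` scans, zero-filling edges."""
    if s == 0:
        return x.copy()
    out = np.zeros_like(x)
    if s > 0:
        out[s:] = x[:-s]
    else:
        out[:s] = x[-s:]
    return out


def _best_shift(tic: np.ndarray, ref: np.ndarray, max_shift: int) -> int:
    """Integer shift in [-max_shift, max_shift] maximizing the dot product
    of the shifted TIC with the reference; ties go to the smallest |shift|,
    then to the negative candidate."""
    best, best_score = 0, -np.inf
    for s in sorted(range(-max_shift, max_shift + 1), key=lambda v: (abs(v), v)):
        if s > 0:
            score = float(tic[:-s] @ ref[s:]) if s < len(tic) else 0.0
        elif s < 0:
            score = float(tic[-s:] @ ref[:s])
        else:
            score = float(tic @ ref)
        if score > best_score + 1e-12:
            best, best_score = s, score
    return best


def align(dataset: GCMSDataset, max_shift: int) -> GCMSDataset:
    """Align samples along the retention axis by global integer shifts.

    The reference is the medoid sample (maximal summed Pearson correlation
    of TICs, ties to the lowest index). Each sample's applied shift is
    recorded in the returned metadata column ``applied_shift``. Shifts
    beyond ``max_shift`` cannot be corrected: the search is bounded, so a
    sample drifted by more than ``max_shift`` retains the excess
    misalignment.
    """
    if len(dataset) == 0:
        raise InputError("cannot align an empty dataset")
    if max_shift < 0:
        raise InputError("max_shift must be non-negative")

    tics = np.vstack([s.tic for s in dataset.samples])
    centered = tics - tics.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms[norms == 0] = 1.0
    corr = (centered / norms[:, None]) @ (centered / norms[:, None]).T
    ref_idx = int(np.argmax(corr.sum(axis=1)))
    ref = tics[ref_idx]

    shifts = np.array(
        [_best_shift(tics[i], ref, max_shift) for i in range(len(dataset))], dtype=int
    )
    # remove the common offset: the cohort's median shift defines "no drift"
    offset = int(np.floor(np.median(shifts) + 0.5))
    shifts = np.clip(shifts - offset, -max_shift, max_shift)

    samples = [
        IonMap(
            sample_id=s.sample_id,
            intensities=_shift_rows(s.intensities, int(shifts[i])),
            rt_axis=s.rt_axis,
            mz_axis=s.mz_axis,
        )
        for i, s in enumerate(dataset.samples)
    ]
    metadata = dataset.metadata.copy()
    metadata["applied_shift"] = shifts
    return GCMSDataset(samples=samples, metadata=metadata)


def window_edges(n_scans: int, n_windows: int) -> np.ndarray:
    """Evenly spaced integer partition edges (length n_windows + 1)."""
    return np.round(np.linspace(0, n_scans, n_windows + 1)).astype(int)


def compress(dataset: GCMSDataset, n_windows: int) -> list[CompressionVector]:
    """Windowed base-peak + TIC summaries, one fixed-length vector per sample.

    The retention axis is split into ``n_windows`` contiguous windows; for
    each window the sum over scans of the per-scan base peak (max over m/z)
    and the summed total ion current are recorded. The vector is the
    base-peak block followed by the TIC block (length ``2 * n_windows``).
    """
    if len(dataset) == 0:
        raise InputError("cannot compress an empty dataset")
    n_scans = len(dataset.rt_axis)
    if n_windows < 1 or n_windows > n_scans:
        raise InputError(f"n_windows must lie in [1, {n_scans}]")
    edges = window_edges(n_scans, n_windows)
    out = []
    for s in dataset.samples:
        bp = s.intensities.max(axis=1)
        tic = s.tic
        bp_part = np.add.reduceat(bp, edges[:-1])
        tic_part = np.add.reduceat(tic, edges[:-1])
        out.append(
            CompressionVector(
                sample_id=s.sample_id, values=np.concatenate([bp_part, tic_part])
            )
        )
    return out


def normalize_peaktable(
    pt: PeakTable, standard_ids: list[str], weights: np.ndarray | None = None
) -> PeakTable:
    """Divide every sample's areas by its weighted sum of internal-standard areas.

    Weights default to equal. Raises if a standard is missing or its area
    is not strictly positive in some sample (the offending sample and
    standard are named).
    """
    missing = [s for s in standard_ids if s not in pt.profile_ids]
    if missing:
        raise NormalizationError(f"standards not in peak table: {missing}")
    if not standard_ids:
        raise NormalizationError("at least one internal standard required")
    cols = [pt.profile_ids.index(s) for s in standard_ids]
    if weights is None:
        weights = np.full(len(cols), 1.0 / len(cols))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(cols),) or np.any(weights < 0) or weights.sum() == 0:
        raise NormalizationError("weights must be non-negative, same length as standards")

    std = pt.areas[:, cols]
    bad = np.argwhere(std <= 0)
    if bad.size:
        i, j = bad[0]
        raise NormalizationError(
            f"non-positive area for standard {standard_ids[j]!r} "
            f"in sample {pt.sample_ids[i]!r}"
        )
    factors = std @ weights
    return PeakTable(
        areas=pt.areas / factors[:, None],
        sample_ids=list(pt.sample_ids),
        profile_ids=list(pt.profile_ids),
        normalized=True,
    )
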