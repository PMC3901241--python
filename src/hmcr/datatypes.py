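"""Core containers shared across the processing chain.

The pipeline moves data through a fixed sequence of shapes: raw per-sample
ion maps (retention time x nominal m/z), stacked time windows, resolved
spectral/chromatographic profiles, a reference table of validated spectra,
and finally a samples x metabolites peak table that feeds classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "IonMap",
    "GCMSDataset",
    "CompressionVector",
    "TimeWindow",
    "SpectralProfile",
    "ResolvedWindow",
    "ReferenceTable",
    "PeakTable",
]


@dataclass
class IonMap:
    """One sample's intensity matrix over retention time and nominal m/z.

    ``intensities`` has shape ``(n_scans, n_mz)``; ``rt_axis`` is in seconds
    and strictly increasing, ``mz_axis`` holds nominal (integer) masses.
    """

    sample_id: str
    intensities: np.ndarray
    rt_axis: np.ndarray
    mz_axis: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.rt_axis = np.asarray(self.rt_axis, dtype=float)
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D (scans x m/z) matrix")
        n_scans, n_mz = self.intensities.shape
        if self.rt_axis.shape != (n_scans,):
            raise ValueError("rt_axis length must equal the scan count")
        if self.mz_axis.shape != (n_mz,):
            raise ValueError("mz_axis length must equal the m/z channel count")
        if np.any(np.diff(self.rt_axis) <= 0):
            raise ValueError("rt_axis must be strictly increasing")
        if np.any(np.diff(self.mz_axis) <= 0):
            raise ValueError("mz_axis must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def tic(self) -> np.ndarray:
        """Total ion chromatogram (sum over m/z per scan)."""
        return self.intensities.sum(axis=1)


@dataclass
class GCMSDataset:
    """An ordered collection of ion maps sharing axes, plus sample metadata.

    ``metadata`` rows correspond one-to-one with ``samples`` and carry at
    least ``sample_id``; class labels (``class``: 0 = pre, 1 = post),
    ``subject`` and ``occasion`` columns are used by selection and modeling.
    """

    samples: list[IonMap]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.metadata):
            raise ValueError("metadata rows must correspond 1:1 with samples")
        if self.samples:
            rt0, mz0 = self.samples[0].rt_axis, self.samples[0].mz_axis
            for s in self.samples[1:]:
                if s.rt_axis.shape != rt0.shape or not np.allclose(s.rt_axis, rt0):
                    raise ValueError("all samples must share the rt axis")
                if s.mz_axis.shape != mz0.shape or not np.allclose(s.mz_axis, mz0):
                    raise ValueError("all samples must share the m/z axis")
        self.metadata = self.metadata.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def rt_axis(self) -> np.ndarray:
        return self.samples[0].rt_axis

    @property
    def mz_axis(self) -> np.ndarray:
        return self.samples[0].mz_axis

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def subset(self, indices) -> "GCMSDataset":
        """New dataset restricted to ``indices`` (order preserved)."""
        indices = list(indices)
        return GCMSDataset(
            samples=[self.samples[i] for i in indices],
            metadata=self.metadata.iloc[indices].reset_index(drop=True),
        )


@dataclass
class CompressionVector:
    """Fixed-length windowed intensity summary of one sample."""

    sample_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("compression values must be non-negative")


@dataclass
class TimeWindow:
    """A contiguous retention-time slice with samples stacked row-wise.

    ``scan_range`` is half-open ``[start, end)`` in scan indices and
    ``stacked_data`` has shape ``(n_samples * window_scans, n_mz)`` with
    sample blocks in dataset order.
    """

    window_id: int
    scan_range: tuple[int, int]
    stacked_data: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        start, end = self.scan_range
        if end <= start:
            raise ValueError("scan_range end must exceed start")
        self.stacked_data = np.asarray(self.stacked_data, dtype=float)

    @property
    def n_scans(self) -> int:
        return self.scan_range[1] - self.scan_range[0]

    def sample_block(self, i: int) -> np.ndarray:
        w = self.n_scans
        return self.stacked_data[i * w : (i + 1) * w]


@dataclass
class SpectralProfile:
    """A resolved mass spectrum (unit Euclidean norm, non-negative)."""

    profile_id: str
    spectrum: np.ndarray
    apex_rt: float
    window_id: int
    stable: bool = False

    def __post_init__(self) -> None:
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        if np.any(self.spectrum < -1e-12):
            raise ValueError("spectrum must be non-negative")
        nrm = float(np.linalg.norm(self.spectrum))
        if nrm > 0 and abs(nrm - 1.0) > 1e-8:
            raise ValueError("spectrum must have unit Euclidean norm")


@dataclass
class ResolvedWindow:
    """MCR output for one time window: X ~= C S^T + E.

    ``spectra`` is k x n_mz (rows are unit-norm spectra, i.e. S^T);
    ``chrom_profiles[i]`` is the window_scans x k block of C for sample i;
    ``residual_fraction`` is ||E||_F^2 / ||X||_F^2.
    """

    window_id: int
    scan_range: tuple[int, int]
    spectra: np.ndarray
    chrom_profiles: list[np.ndarray]
    residual_fraction: float
    residual_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_components(self) -> int:
        return self.spectra.shape[0]


@dataclass
class ReferenceTable:
    """Ordered collection of validated spectral profiles with provenance."""

    profiles: list[SpectralProfile]
    mz_axis: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.profile_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("profile_ids must be unique")
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def profile_ids(self) -> list[str]:
        return [p.profile_id for p in self.profiles]

    def spectra_matrix(self) -> np.ndarray:
        """k x n_mz matrix of spectra in table order."""
        if not self.profiles:
            return np.empty((0, len(self.mz_axis)))
        return np.vstack([p.spectrum for p in self.profiles])


@dataclass
class PeakTable:
    """Samples x profiles matrix of integrated chromatographic areas."""

    areas: np.ndarray
    sample_ids: list[str]
    profile_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != (len(self.sample_ids), len(self.profile_ids)):
            raise ValueError("areas shape inconsistent with sample/profile ids")
        if np.any(self.areas < 0):
            raise ValueError("areas must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.areas, index=self.sample_ids, columns=self.profile_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, normalized: bool = False) -> "PeakTable":
        return cls(
            areas=df.to_numpy(dtype=float),
            sample_ids=[str(i) for i in df.index],
            profile_ids=[str(c) for c in df.columns],
            normalized=normalized,
        )

    def copy_with(self, **kw) -> "PeakTable":
        return replace(self, **kw)
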