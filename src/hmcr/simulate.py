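"""Ground-truthed simulation of multi-sample GC/MS-like data.

The generator emulates the statistical structure the processing chain
assumes: a set of components shared across samples, each with a fixed
mass spectrum and a Gaussian elution peak; per-sample concentrations with
a multiplicative two-class effect; spiked internal standards at constant
concentration; a global integer retention drift per sample; and additive
heteroscedastic-free Gaussian noise clipped at zero.

Sample ``i``'s ion map is

    X_i = sum_k conc[i, k] * g_k(t - shift_i) s_k^T   (+ noise, clipped at 0)

where ``g_k`` is a Gaussian in scan index normalized to unit trapezoidal
area and ``s_k`` is a unit-norm non-negative spectrum, so integrating a
component's elution profile recovers its concentration exactly in the
noiseless case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GCMSDataset, IonMap

__all__ = ["SimulationConfig", "GroundTruth", "simulate_dataset", "simulate_metadata"]

#: seconds between consecutive scans on the simulated retention axis
SCAN_PERIOD_S = 0.5


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of one simulated multi-sample GC/MS experiment.

    The last ``n_standards`` of the ``n_components`` components are spiked
    internal standards: constant concentration across samples and an
    effect size of exactly 1.
    """

    n_samples: int = 16
    n_components: int = 10
    n_scans: int = 300
    mz_channels: int = 120
    class_labels: np.ndarray | None = None
    effect_sizes: np.ndarray | None = None
    noise_sd: float = 0.0
    drift_max: int = 0
    n_standards: int = 0
    seed: int = 0
    width_range: tuple[float, float] = (3.0, 5.0)
    conc_range: tuple[float, float] = (80.0, 200.0)
    bio_cv: float = 0.0
    peaks_per_spectrum: int = 8
    presence: np.ndarray | None = None
    #: when set, concentrations/drift/noise come from this second seed while
    #: the metabolome (spectra, widths, apexes, base levels) stays a function
    #: of ``seed`` — the way to simulate new cohorts of the same metabolome
    conc_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_components < 1:
            raise ConfigurationError("n_samples and n_components must be >= 1")
        if self.n_scans < 8 or self.mz_channels < 2:
            raise ConfigurationError("n_scans/mz_channels too small")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.drift_max < 0:
            raise ConfigurationError("drift_max must be non-negative")
        if not 0 <= self.n_standards <= self.n_components:
            raise ConfigurationError("n_standards must lie in [0, n_components]")
        if self.class_labels is None:
            self.class_labels = np.arange(self.n_samples) % 2
        self.class_labels = np.asarray(self.class_labels, dtype=int)
        if self.class_labels.shape != (self.n_samples,):
            raise ConfigurationError("class_labels length must equal n_samples")
        if not np.isin(self.class_labels, (0, 1)).all():
            raise ConfigurationError("class_labels must be binary 0/1")
        if self.effect_sizes is None:
            self.effect_sizes = np.ones(self.n_components)
        self.effect_sizes = np.asarray(self.effect_sizes, dtype=float)
        if self.effect_sizes.shape != (self.n_components,):
            raise ConfigurationError("effect_sizes length must equal n_components")
        if self.n_standards and not np.all(self.effect_sizes[-self.n_standards :] == 1.0):
            raise ConfigurationError("internal standards must have effect size exactly 1")
        if self.presence is not None:
            self.presence = np.asarray(self.presence, dtype=bool)
            if self.presence.shape != (self.n_samples, self.n_components):
                raise ConfigurationError("presence must be n_samples x n_components")


@dataclass
class GroundTruth:
    """What the simulator actually put into the data."""

    true_spectra: np.ndarray  # n_components x mz_channels, unit-norm rows
    true_concentrations: np.ndarray  # n_samples x n_components
    true_retention: np.ndarray  # per-component apex scan index
    true_widths: np.ndarray  # per-component Gaussian sigma in scans
    true_shifts: np.ndarray  # per-sample integer scan shift
    standard_ids: list[str] = field(default_factory=list)
    component_ids: list[str] = field(default_factory=list)

    def elution_profile(self, component: int, n_scans: int, shift: int = 0) -> np.ndarray:
        """Unit-area Gaussian elution profile of a component (shifted)."""
        t = np.arange(n_scans, dtype=float)
        apex = self.true_retention[component] + shift
        g = np.exp(-0.5 * ((t - apex) / self.true_widths[component]) ** 2)
        return g / np.trapezoid(g)

    def reconstruct(self, sample: int, n_scans: int, mz_channels: int) -> np.ndarray:
        """Noiseless ion map of one sample from the ground truth."""
        x = np.zeros((n_scans, mz_channels))
        for k in range(self.true_spectra.shape[0]):
            c = self.true_concentrations[sample, k]
            if c == 0:
                continue
            g = self.elution_profile(k, n_scans, shift=int(self.true_shifts[sample]))
            x += c * np.outer(g, self.true_spectra[k])
        return x


def _draw_spectra(rng: np.random.Generator, k: int, n_mz: int, n_peaks: int) -> np.ndarray:
    """Sparse non-negative unit-norm spectra, one row per component."""
    spectra = np.zeros((k, n_mz))
    for j in range(k):
        n = min(n_peaks, n_mz)
        channels = rng.choice(n_mz, size=n, replace=False)
        heights = rng.uniform(0.05, 1.0, size=n)
        heights[rng.integers(n)] = 1.0  # guarantee a base peak
        spectra[j, channels] = heights
        spectra[j] /= np.linalg.norm(spectra[j])
    return spectra


def _place_apexes(
    rng: np.random.Generator, k: int, n_scans: int, margin: float
) -> np.ndarray:
    """Apex positions spread over the usable scan range with jitter."""
    lo, hi = margin, n_scans - 1 - margin
    if hi <= lo:
        raise ConfigurationError("n_scans too small for the requested components")
    base = np.linspace(lo, hi, k)
    gap = (hi - lo) / max(k - 1, 1)
    jitter = rng.uniform(-0.2 * gap, 0.2 * gap, size=k) if k > 1 else np.zeros(1)
    return base + jitter


def simulate_dataset(config: SimulationConfig) -> tuple[GCMSDataset, GroundTruth]:
    """Generate a multi-sample dataset together with its ground truth.

    The same configuration (which includes the seed) always yields a
    bit-identical dataset.
    """
    rng = np.random.default_rng(config.seed)
    k, n = config.n_components, config.n_samples
    n_std = config.n_standards

    spectra = _draw_spectra(rng, k, config.mz_channels, config.peaks_per_spectrum)
    widths = rng.uniform(*config.width_range, size=k)
    margin = 4.0 * widths.max() + config.drift_max
    apexes = _place_apexes(rng, k, config.n_scans, margin)

    base_conc = rng.uniform(*config.conc_range, size=k)
    if config.conc_seed is not None:
        rng = np.random.default_rng(config.conc_seed)  # new cohort, same metabolome
    conc = np.tile(base_conc, (n, 1))
    # class effect: multiplicative fold change applied to class-1 samples
    conc *= np.where(
        config.class_labels[:, None] == 1, config.effect_sizes[None, :], 1.0
    )
    if config.bio_cv > 0:
        biovar = rng.lognormal(mean=0.0, sigma=config.bio_cv, size=(n, k))
        if n_std:
            biovar[:, -n_std:] = 1.0  # standards are spiked, not biological
        conc *= biovar
    if config.presence is not None:
        conc = conc * config.presence

    shifts = (
        rng.integers(-config.drift_max, config.drift_max + 1, size=n)
        if config.drift_max > 0
        else np.zeros(n, dtype=int)
    )

    component_ids = [f"comp_{j:02d}" for j in range(k - n_std)] + [
        f"istd_{j:02d}" for j in range(n_std)
    ]
    truth = GroundTruth(
        true_spectra=spectra,
        true_concentrations=conc,
        true_retention=apexes,
        true_widths=widths,
        true_shifts=np.asarray(shifts, dtype=int),
        standard_ids=component_ids[k - n_std :],
        component_ids=component_ids,
    )

    rt_axis = np.arange(config.n_scans) * SCAN_PERIOD_S
    mz_axis = np.arange(50, 50 + config.mz_channels, dtype=float)
    samples = []
    for i in range(n):
        x = truth.reconstruct(i, config.n_scans, config.mz_channels)
        if config.noise_sd > 0:
            x = x + rng.normal(0.0, config.noise_sd, size=x.shape)
        np.clip(x, 0.0, None, out=x)
        samples.append(
            IonMap(
                sample_id=f"S{i:03d}",
                intensities=x,
                rt_axis=rt_axis,
                mz_axis=mz_axis,
            )
        )

    metadata = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "class": config.class_labels,
            "subject": [f"subj_{i // 2:02d}" for i in range(n)],
            "occasion": [1] * n,
        }
    )
    return GCMSDataset(samples=samples, metadata=metadata), truth


def simulate_metadata(
    n_subjects: int,
    n_vars: int,
    seed: int,
    latent_rank: int = 3,
    noise_sd: float = 0.3,
) -> pd.DataFrame:
    """Correlated multivariate-Gaussian covariate table with planted low rank.

    Emulates a subject-characterization table (anthropometrics, physiology,
    blood chemistry): ``latent_rank`` latent factors with decaying scales
    drive all variables, plus independent Gaussian noise. Draw order is
    latents, loadings, then noise, so rerunning with ``noise_sd=0`` and the
    same seed yields the noiseless latent construction.
    """
    if n_subjects < 2:
        raise ConfigurationError("n_subjects must be >= 2")
    if n_vars < 1:
        raise ConfigurationError("n_vars must be >= 1")
    rank = min(latent_rank, n_vars)
    rng = np.random.default_rng(seed)
    scales = 2.0 ** -np.arange(rank)  # factor 1 dominates, then decay
    latents = rng.normal(size=(n_subjects, rank)) * scales
    loadings = rng.normal(size=(rank, n_vars))
    table = latents @ loadings
    noise = rng.normal(size=(n_subjects, n_vars))
    table = table + noise_sd * noise
    return pd.DataFrame(
        table,
        index=[f"subj_{i:02d}" for i in range(n_subjects)],
        columns=[f"var_{j:02d}" for j in range(n_vars)],
    )
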