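import numpy as np
import pytest

from hmcr.datatypes import PeakTable, TimeWindow
from hmcr.simulate import SimulationConfig, simulate_dataset


def single_window(dataset) -> TimeWindow:
    """Stack a whole dataset into one time window."""
    X = np.vstack([s.intensities for s in dataset.samples])
    return TimeWindow(
        window_id=0,
        scan_range=(0, len(dataset.rt_axis)),
        stacked_data=X,
        n_samples=len(dataset),
    )


@pytest.fixture
def three_component_window():
    """Noiseless 10-sample dataset with 3 well-separated components in one window."""
    cfg = SimulationConfig(
        n_samples=10,
        n_components=3,
        n_scans=80,
        mz_channels=60,
        width_range=(2.0, 3.0),
        bio_cv=0.3,
        seed=3,
    )
    dataset, truth = simulate_dataset(cfg)
    # the recovery guarantees assume spectrally distinct components
    for i in range(3):
        for j in range(i + 1, 3):
            assert truth.true_spectra[i] @ truth.true_spectra[j] < 0.7
    return dataset, truth, single_window(dataset)


@pytest.fixture
def noiseless_dataset():
    cfg = SimulationConfig(
        n_samples=10,
        n_components=3,
        n_scans=200,
        mz_channels=80,
        bio_cv=0.2,
        seed=1,
    )
    return simulate_dataset(cfg)


def planted_oplsda(
    seed: int,
    n: int = 40,
    p: int = 30,
    effect: float = 2.0,
    n_effect_vars: int | None = 5,
    confounder_sd: float = 3.0,
    noise_sd: float = 0.3,
):
    """Peak-table-shaped data with a planted class effect and one confounder.

    With ``n_effect_vars`` set, the class effect lives on that many
    variables, each separated by ``2 * effect * noise_sd`` between classes
    (so ``effect`` counts within-class SD units of separation per variable,
    halved); with ``n_effect_vars=None`` the effect is a dense random
    latent direction over all variables. The confounder loads on a
    direction orthogonal to the effect and its scores are orthogonalized
    against the class vector, so it is y-orthogonal by construction.
    Returns (PeakTable, y, effect_direction, confounder_direction) in raw
    variable space.
    """
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    if n_effect_vars is None:
        d_pred = rng.normal(size=p)
    else:
        d_pred = np.zeros(p)
        d_pred[:n_effect_vars] = 1.0
    d_pred /= np.linalg.norm(d_pred)
    d_orth = rng.normal(size=p)
    d_orth -= (d_orth @ d_pred) * d_pred
    d_orth /= np.linalg.norm(d_orth)
    yc = y - y.mean()
    conf = rng.normal(size=n)
    conf -= (conf @ yc) / (yc @ yc) * yc
    conf *= confounder_sd / conf.std() if confounder_sd > 0 else 0.0
    n_eff = p if n_effect_vars is None else n_effect_vars
    diff = effect * noise_sd * 2 * np.sqrt(n_eff) * d_pred
    X = (
        30.0
        + np.outer(y - 0.5, diff)
        + np.outer(conf, d_orth)
        + noise_sd * rng.normal(size=(n, p))
    )
    X = np.clip(X, 0.0, None)
    pt = PeakTable(
        areas=X,
        sample_ids=[f"s{i:03d}" for i in range(n)],
        profile_ids=[f"v{j:02d}" for j in range(p)],
    )
    return pt, y.astype(float), d_pred, d_orth


def null_peaktable(seed: int, n: int = 24, p: int = 30):
    """Peak table with no class effect at all."""
    rng = np.random.default_rng(seed)
    X = np.clip(10.0 + rng.normal(size=(n, p)), 0.0, None)
    y = np.arange(n) % 2
    pt = PeakTable(
        areas=X,
        sample_ids=[f"s{i:03d}" for i in range(n)],
        profile_ids=[f"v{j:02d}" for j in range(p)],
    )
    return pt, y.astype(float)
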