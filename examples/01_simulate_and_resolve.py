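"""Simulate a small GC/MS cohort and resolve it by windowed MCR-ALS.

Builds a 10-sample dataset with 3 shared components, stacks it into one
retention-time window, factors it into chromatographic profiles and mass
spectra, and checks the recovered spectra against the simulator's ground
truth.
"""

import numpy as np

from hmcr import SimulationConfig, simulate_dataset, resolve_window, integrate_areas
from hmcr.datatypes import TimeWindow

cfg = SimulationConfig(
    n_samples=10, n_components=3, n_scans=80, mz_channels=60,
    width_range=(2.0, 3.0), bio_cv=0.3, seed=3,
)
dataset, truth = simulate_dataset(cfg)

stacked = np.vstack([s.intensities for s in dataset.samples])
window = TimeWindow(window_id=0, scan_range=(0, 80), stacked_data=stacked,
                    n_samples=len(dataset))

resolved = resolve_window(window, n_components="auto")
print(f"components resolved: {resolved.n_components}")
print(f"residual fraction  : {resolved.residual_fraction:.2e}")

# best match of each recovered spectrum to a true one (cosine similarity)
for j, spec in enumerate(resolved.spectra):
    cosines = [abs(spec @ t) for t in truth.true_spectra]
    print(f"spectrum {j}: best cosine to ground truth = {max(cosines):.6f}")

areas = integrate_areas(resolved.chrom_profiles)
print(f"peak areas (samples x components): {areas.shape}")
# a cosine of 1 and a residual near 0 mean the noiseless mixture was
# resolved exactly into its underlying spectra and elution profiles
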