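"""Select a representative subject subset with PCA + maximin design.

Simulates a 24-subject metadata table (34 covariates with planted
low-rank structure), screens for deviating subjects, and picks the 6
subjects that span the score space maximally; with pre/post sampling the
selection expands to 12 model samples.
"""

import numpy as np
import pandas as pd

from hmcr import simulate_metadata, diversity_select_metadata, fit_pca

metadata = simulate_metadata(n_subjects=24, n_vars=34, seed=8)
model = fit_pca(metadata, n_components=2)
print(f"PCA of metadata: R2X(2 comps) = {model.cumulative_r2x:.3f}")

samples = pd.DataFrame({
    "sample_id": [f"S{i:03d}" for i in range(48)],
    "subject": np.repeat(metadata.index, 2),
    "class": [0, 1] * 24,  # 0 = pre, 1 = post
})

result = diversity_select_metadata(metadata, n_components=2, k_subjects=6,
                                   sample_metadata=samples)
print(f"selected subjects : {result.selected_groups}")
print(f"selected samples  : {len(result.selected_indices)} (6 subjects x pre/post)")
print(f"min nearest-neighbor distance in score space: {result.criterion_value:.3f}")
# the criterion is the distance between the two closest selected subjects:
# the larger it is, the better the subset spans the between-subject variation
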