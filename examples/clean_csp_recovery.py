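"""Fit CSP filters on clean synthetic motor-imagery EEG and check that they
recover the known unmixing direction of the class-dependent source.

The generator mixes one mu-band source with class-dependent variance plus
background sources into the sensors; on clean data both the classical (L2)
and the L1-dispersion spatial filters should point at the direction that
isolates that source.
"""

import numpy as np

from robustcsp import (
    SyntheticConfig,
    estimate_class_covariance,
    fit_csp_l1,
    generate_mi_dataset,
    solve_csp_l2,
)

cfg = SyntheticConfig(n_channels=4, n_trials_per_class=300,
                      class_variance_ratio=16.0, snr=1e6,
                      n_background_sources=3, mixing_seed=1, noise_seed=2)
train, test, truth = generate_mi_dataset(cfg)

C1 = estimate_class_covariance(train, 1)
C2 = estimate_class_covariance(train, 2)

u = truth.discriminative_direction
u = u / np.linalg.norm(u)

for fset in (solve_csp_l2(C1, C2, n_pairs=2), fit_csp_l1(C1, C2, n_pairs=2)):
    w = fset.filters[:, 0]
    cosine = abs(w @ u) / np.linalg.norm(w)
    print(f"{fset.method}: |cos(top filter, true unmixing)| = {cosine:.4f}, "
          f"top score = {fset.scores[0]:.3f}")

print("\nA cosine near 1 means the filter isolates the class-discriminative "
      "source; the top score is the generalized eigenvalue (L2) or the L1 "
      "dispersion (L1-SVD).")
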