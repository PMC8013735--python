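"""Tapered sliding-window connectivity of one subject.

A 40-s rectangle (20 TRs at TR = 2 s) smoothed by a Gaussian (sigma = 3 s)
slides over the z-scored node signals; each window's weighted covariance is
vectorized into 21 node-pair features.
"""

import numpy as np

from dfcstates import build_taper, cobre_like_config, generate_cohort, sliding_dfc

taper = build_taper(window_trs=20, sigma_seconds=3.0, tr_seconds=2.0)
print(f"taper: {len(taper.weights)} samples, sum = {taper.weights.sum():.6f}, "
      f"center weight {taper.weights[10]:.4f} vs edge {taper.weights[0]:.4f}")

cohort = generate_cohort(cobre_like_config(n_hc=1, n_sz=0, seed=2))
subject = cohort.subjects[0]
dfc = sliding_dfc(subject.signal, taper, subject_id=subject.id,
                  node_labels=cohort.node_labels)

print(f"{subject.signal.shape[0]} timepoints -> {dfc.n_windows} windows "
      f"x {dfc.n_features} pair features")  # 144 -> 124 windows
i, j = dfc.feature_index[0]
series = dfc.features[:, 0]
print(f"feature C1 = {i}-{j} connectivity: mean {series.mean():+.3f}, "
      f"range [{series.min():+.3f}, {series.max():+.3f}] across windows")
print("the fluctuation across windows is the dynamics the state analysis "
      "decomposes")
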