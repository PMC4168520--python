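"""Wavelet-packet entropy features from synthetic mental-task EEG.

Generates two task classes that differ only in alpha-band (8-12 Hz)
power, extracts one Shannon entropy per (channel, rhythm band) with a
4-level db4 wavelet-packet tree, and shows that the alpha columns
separate the classes.
"""

import numpy as np

from neuromkl import synthdata, wpe

specs = [
    synthdata.MentalTaskSpec(
        name="task_hi_alpha",
        band_power={"delta": 1, "theta": 1, "alpha": 4, "beta": 1},
    ),
    synthdata.MentalTaskSpec(
        name="task_lo_alpha",
        band_power={"delta": 1, "theta": 1, "alpha": 1, "beta": 1},
    ),
]
eeg = synthdata.gen_mental_eeg(specs, trials_per_class=20, seed=1)
print(f"{eeg.n_trials} trials x {eeg.n_channels} channels x {eeg.n_samples} samples "
      f"at {eeg.fs:g} Hz")

# the edge-accurate band map aligns tree nodes with the nominal Hz band
# edges (the default literal node map reproduces the published node
# selection instead, whose nodes straddle the band edges at 250 Hz)
feats = wpe.wpe_features(eeg, band_map=wpe.edge_band_map(eeg.fs), levels=5)
print(f"feature matrix: {feats.values.shape[0]} x {feats.values.shape[1]} "
      f"({eeg.n_channels} channels x 4 bands)")

hi = feats.labels == "task_hi_alpha"
for col in ("C3_alpha", "O1_alpha", "C3_theta"):
    i = feats.columns.index(col)
    a, b = feats.values[hi, i], feats.values[~hi, i]
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
    print(f"{col:<9s} class means {a.mean():9.1f} vs {b.mean():9.1f}  "
          f"|Cohen d| = {abs(a.mean() - b.mean()) / pooled:.2f}")
# The alpha columns show by far the largest standardized group
# difference; the theta column (equal power in both classes) still moves
# a little because the wavelet filters' transition bands let some alpha
# energy leak into the neighbouring node.
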