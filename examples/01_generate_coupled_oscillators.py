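"""Simulate phase-coupled alpha oscillations and recover the planted PLV.

Builds a two-module coupling specification (strong within-module phase
locking, weak between), generates epoched 10 Hz signals and estimates the
phase-locking value matrix back from the signals.
"""

import numpy as np

from plvnet import generate_epochs, instantaneous_phase, plant_communities, plv_matrix

spec = plant_communities(
    n_nodes=6,
    membership=[0, 0, 0, 1, 1, 1],
    within_plv=0.8,
    between_plv=0.1,
    noise_sd=0.1,
)
epochs = generate_epochs(("s01", "overt", "fear"), spec, n_trials=100, seed=42)
print(f"epochs: {epochs.data.shape} (trials x nodes x samples), fs={epochs.fs_hz} Hz")

phases = instantaneous_phase(epochs)
conn = plv_matrix(phases, window=(0.0, 0.8), edge_trim_s=0.1)

within = np.mean([conn.plv[i, j] for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]])
between = conn.plv[:3, 3:].mean()
print(f"estimated within-module PLV:  {within:.3f}  (planted 0.8)")
print(f"estimated between-module PLV: {between:.3f}  (planted 0.1)")
print(
    "PLV = 1 means perfectly locked phases, 0 means no consistent phase "
    "relation; the block structure planted by the generator survives the "
    "signal synthesis + Hilbert phase estimation round trip."
)
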