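"""Simulate phase-coupled EEG and watch the synchronization metrics respond.

Generates two-channel narrowband recordings at increasing coupling
strength and prints the whole-series PLV/PLI/wPLI. PLV should climb from
near 0 (independent phases) to 1 (rigid lock); the lag-based metrics
follow because the planted lag is nonzero.
"""

import numpy as np

from eegsync import CouplingSpec, extract_sync_features, generate_coupled_recording

N_SEEDS = 5

print(f"{'coupling':>9} {'PLV':>7} {'PLI':>7} {'wPLI':>7}")
for coupling in (0.0, 0.25, 0.5, 0.75, 1.0):
    spec = CouplingSpec(band_name="alpha", coupling_strength=coupling,
                        phase_lag=0.6, noise_sd=1.0)
    vals = np.zeros(3)
    for seed in range(N_SEEDS):
        rec = generate_coupled_recording(2, 60, 500, spec, seed=seed)
        vec = extract_sync_features(rec, bands=["alpha"], montage_pairs=None,
                                    hilbert_mode="whole")
        vals += [vec.values[f"{m}_alpha"] for m in ("plv", "pli", "wpli")]
    vals /= N_SEEDS
    print(f"{coupling:>9.2f} {vals[0]:>7.3f} {vals[1]:>7.3f} {vals[2]:>7.3f}")

print(f"\nEach row averages {N_SEEDS} 60-s two-channel recordings; the mean "
      "metrics rise monotonically with the planted coupling strength.")
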