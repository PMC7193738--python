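"""The established comparator biomarkers on a synthetic coupled signal.

Computes the beta-band power fraction, a single-pair phase-amplitude
modulation index, and the full 6x6 coupling grid for a tone whose 45 Hz
amplitude rides the phase of a 6 Hz rhythm.
"""

import numpy as np

from lpcsep import BandSpec, beta_power, gen_pac_signal, pac_grid, pac_mi

fs = 1000.0
coupled = gen_pac_signal(fs, 60.0, f_phase=6.0, f_amp=45.0, depth=0.8, seed=3)
uncoupled = gen_pac_signal(fs, 60.0, f_phase=6.0, f_amp=45.0, depth=0.0, seed=3)

theta = BandSpec("theta", 5, 7)
gamma = BandSpec("gamma", 31, 60)
print(f"beta (12-30 Hz) power fraction: {beta_power(coupled, fs):.3f}")
print(f"modulation index, coupled (depth 0.8):   {pac_mi(coupled, fs, theta, gamma):.4f}")
print(f"modulation index, uncoupled (depth 0.0): {pac_mi(uncoupled, fs, theta, gamma):.2e}")

grid = pac_grid([coupled], fs)[0]
i, j = np.unravel_index(np.argmax(grid.mi), grid.mi.shape)
print(f"grid: {grid.mi.size} indices; maximum {grid.mi[i, j]:.4f} in "
      f"({grid.phase_bands[i].name} phase, {grid.amp_bands[j].name} amplitude)")
print("-> the index is ~0 without coupling and localizes the coupled band pair.")
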