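"""Estimate a signal's dominant frequency from the order-2 model's poles.

Fits a two-coefficient predictive model to a synthetic oscillatory field
potential; the conjugate pole pair's phase gives the peak frequency and its
radius the peak sharpness.  Also evaluates the fitted all-pole spectrum.
"""

import dataclasses

import numpy as np

from lpcsep import SALINE_LIKE, ar_psd, fit_lpc, gen_ar2_source

spec = dataclasses.replace(SALINE_LIKE, duration_min=1.0, seed=7)
x = gen_ar2_source(spec)  # true peak: 12.2 Hz, pole radius 0.995

model = fit_lpc(x, spec.fs, order=2)
p = model.poles[0]
print(f"coefficients a = ({model.coeffs[0]:.5f}, {model.coeffs[1]:.5f})")
print(f"pole {p.real:.4f} {p.imag:+.4f}j, radius {model.pole_radius:.4f}")
print(f"dominant frequency: {model.dominant_freq_hz:.2f} Hz (truth 12.2 Hz)")

grid = np.arange(0.5, 50.0, 0.05)
psd = ar_psd(model, grid)
print(f"all-pole spectrum peaks at {grid[np.argmax(psd)]:.2f} Hz")
print("-> one minute of data pins the spectral peak to within a fraction of a Hz;")
print("   radius near 1 marks a narrow (small-bandwidth) oscillation.")
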