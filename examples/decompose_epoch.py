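"""Empirical Mode Decomposition and marginal spectra of a two-tone epoch.

EMD splits a 25 Hz + 5 Hz mixture into its components (fastest first);
the Hilbert marginal spectrum then localizes each mode's energy in
frequency, which is where the HHT band features come from.
"""

import numpy as np

from neurogait import analytic_mode, emd, hilbert_spectrum, marginal_spectrum

FS = 500.0
t = np.arange(500) / FS
x = np.sin(2 * np.pi * 25 * t) + np.sin(2 * np.pi * 5 * t)

imf_set = emd(x)
print(f"{len(imf_set.imfs)} IMFs extracted; reconstruction error "
      f"{np.max(np.abs(imf_set.reconstruct() - x)):.2e}")
interior = slice(50, 450)
for i, m in enumerate(imf_set.imfs):
    mode = analytic_mode(m, FS)
    f_med = np.median(mode.frequency_hz[interior])
    a_med = np.median(mode.amplitude[interior])
    print(f"IMF {i}: median instantaneous frequency {f_med:5.2f} Hz, amplitude {a_med:.3f} µV")

H = hilbert_spectrum([analytic_mode(m, FS) for m in imf_set.imfs], len(x), FS)
h = marginal_spectrum(H)
top = np.argsort(h.h)[::-1][:2]
print("marginal-spectrum peaks at", sorted(float(f) for f in h.freqs_hz[top]), "Hz")
print("\nThe first IMF recovers the fast 25 Hz tone, the second the 5 Hz tone;")
print("later IMFs (if any) carry residual end effects with negligible energy.")
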