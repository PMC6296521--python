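"""Decompose a two-tone signal with NA-MEMD and read off mode frequencies.

Noise-assisted multivariate EMD appends white-noise channels (d = n + k) and
sifts all channels jointly along 64 Hammersley directions; each intrinsic
mode function (IMF) then gets an instantaneous amplitude and frequency via
the Hilbert transform. A 4 Hz + 40 Hz mixture should split cleanly into one
mode per tone, with exact additive reconstruction.
"""

import numpy as np

import spikememd as sm
from spikememd.hht import amplitude_weighted_if, analytic_signal, imf_frequency_summary, instantaneous

fs = 256.0
t = np.arange(int(3 * fs)) / fs
x = (np.sin(2 * np.pi * 4 * t) + 0.7 * np.sin(2 * np.pi * 40 * t))[:, None]

imfs = sm.namemd(x, n_dirs=64, k_noise=4, noise_sd=0.3, seed=0)
recon_err = np.abs(imfs.reconstruct()[0] - x[:, 0]).max()
freqs, sds = imf_frequency_summary(imfs, fs)

print(f"{imfs.n_imfs} IMFs, reconstruction error {recon_err:.2e}")
for m, f in enumerate(freqs):
    e = imfs.imfs[0, m].var()
    print(f"  IMF {m}: {f:6.2f} Hz   variance {e:.4f}")
# The two dominant-variance modes should sit near 40 Hz (first) and 4 Hz;
# low-variance modes are decomposition residuals. Reconstruction is exact to
# floating point: the decomposition is strictly additive.
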