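"""Build a discriminability map between two ISI conditions.

The per-trial population channels of both conditions are decomposed jointly
(NA-MEMD aligns mode indices across channels), each mode's instantaneous
amplitude is compared across trials with a two-sided Wilcoxon rank-sum test
at every (IMF, time) cell, and Storey q-values correct the whole map. Cells
with q < 0.05 are "significant", q < 0.1 "statistically relevant".
"""

import numpy as np

import spikememd as sm
from spikememd.hht import imf_amplitudes
from spikememd.pipeline import RunConfig, preprocess_animal
from spikememd.stats import discriminability_spectrum

protocol = sm.ProtocolConfig(isi_set=(1.0, 3.0), n_trials=10, n_electrodes=8, n_animals=1)
dataset = sm.generate_dataset(protocol, sm.GeneratorParams(seed=11))
config = RunConfig(protocol=protocol, rebin_factor=5, seed=11)

_, norm = preprocess_animal(dataset, "A1", config)
mats = {isi: norm[isi].data[:, :, 0].T for isi in (1.0, 3.0)}
x = np.hstack([mats[1.0], mats[3.0]])
imfs = sm.namemd(x, n_dirs=64, k_noise=4, seed=11)
ia = imf_amplitudes(imfs, 1.0 / norm[1.0].bin_width)

n = mats[1.0].shape[1]
dmap = discriminability_spectrum(
    ia[:n], ia[n:], times=norm[1.0].times(), labels=("1s", "3s"), time_decimate=10
)
sig = dmap.significant()
print(f"map shape (IMFs x time bins): {dmap.p.shape}, pi0 = {dmap.pi0:.2f}")
print(f"fraction of cells significant (q < 0.05): {sig.mean():.3f}")
per_imf = sig.mean(axis=1)
print("per-IMF significant fraction:", np.round(per_imf, 2))
# With the default generator the 3 s condition has a stronger evoked
# response, so significant cells concentrate in the modes that carry it:
# mostly the slow plateau-following modes, plus the grating band.
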