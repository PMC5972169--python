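"""Resolve mixture spectra into pure-component spectra three ways.

White classical: hard Stern-Volmer decays, only the constants free.
White fractional: the same on row-normalized data with the wavelength
window reduced to the informative region.  Grey MCR-ALS: decays are free
non-negative digitized profiles initialized from a hard model.
"""

import numpy as np

from quenchmcr import (
    NoiseSpec,
    match_components,
    mcr_als,
    sv_decay_matrix,
    synthesize_series,
    white_classical,
    white_fractional,
)

noise = NoiseSpec(spectral_permille=0.5, concentration_percent=5.0, seed=1)
series, truth = synthesize_series(noise=noise)
K0 = [4.0, 120.0, 15.0]  # deliberately rough initial constants
order = np.argsort(truth["K"])

classical = white_classical(series, K0)
fractional = white_fractional(series, K0, window=(420.0, 500.0))
grey = mcr_als(series, sv_decay_matrix(K0, series.quencher_concs))

print(f"truth K:          {np.sort(truth['K'])}")
print(f"white classical:  K = {np.round(classical.K, 2)}  ssq {classical.ssq:.3g}")
print(f"white fractional: K = {np.round(fractional.K, 2)}  (420-500 nm window)")
print(f"grey MCR-ALS:     {grey.n_iter} cycles, ssq {grey.ssq:.3g} "
      "(no functional decay form)")

for name, res in [("classical", classical), ("mcr-als", grey)]:
    m = match_components(res, reference_S=truth["S"][:, order])
    print(f"  {name}: spectral similarity to truth per component "
          f"{np.round(m.similarity, 4)}")

print("\nSimilarity is the normalized inner product of the resolved and "
      "true pure spectra; 1.0 means shapes match exactly.")
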