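"""Estimate Stern-Volmer constants by rank annihilation (τ- and κ-RAFA).

The indirect τ-RAFA scans the factor τ in D = M0 - τ·M_Q for every
quencher level of a multi-excitation set; the per-level minima of the
third covariance eigenvalue lie on τ = 1 + K·Q and the fitted slope is
the constant.  The direct κ-RAFA scans κ on a single-excitation series
and reads the constants off the minima locations directly.
"""

import warnings

import numpy as np

from quenchmcr import (
    NoiseSpec,
    kappa_rafa,
    series_from_excitation,
    synthesize_multi_excitation,
    tau_rafa,
)

for label, noise in [("noise-free", None),
                     ("Q5%/S0.5 per-mille",
                      NoiseSpec(spectral_permille=0.5,
                                concentration_percent=5.0, seed=1))]:
    mset, truth = synthesize_multi_excitation(noise=noise)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tau = tau_rafa(mset)
        kap = kappa_rafa(series_from_excitation(mset, 0))
    print(f"[{label}] truth K = {np.sort(truth['K'])}")
    print(f"  tau-RAFA   K = {np.round(tau.K, 2)}   "
          f"intercepts {np.round(tau.intercepts, 3)} (should be ~1)")
    print(f"  kappa-RAFA K = {np.round(kap.K, 2)}")

print("\nNote the direct method drifts under noise (its minima shift), "
      "while the indirect slope fit averages the error out.")
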