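"""Per-wavelength (point) Stern-Volmer fits and their means.

At each emission wavelength the decay F/F0 over the quencher ladder is
fit with the sum-of-hyperbolas model (FRA) and, as 1 - F/F0, with the
reduced third-degree rational model (DIF).  Per-wavelength constants
scatter strongly on noisy data; the component-matched means over
wavelengths are the method's summary numbers.
"""

import warnings

import numpy as np

from quenchmcr import NoiseSpec, aggregate_pointwise, fit_series, synthesize_series

noise = NoiseSpec(spectral_permille=0.5, concentration_percent=5.0, seed=1)
series, truth = synthesize_series(noise=noise)
print(f"truth K = {np.sort(truth['K'])} 1/M")

for model in ("fra", "dif"):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records = fit_series(series, model=model)
    agg = aggregate_pointwise(records)
    print(f"{model.upper()}: mean K = {np.round(agg.K_mean, 2)}  "
          f"(std {np.round(agg.K_std, 2)}) from {agg.n_used}/{agg.n_total} "
          "wavelengths")

print("\nThe smallest constant is estimated best; the largest is weakly "
      "identified per wavelength (its component is almost fully quenched "
      "over most of the ladder), so its per-wavelength spread is wide.")
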