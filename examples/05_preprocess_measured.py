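"""Preprocessing chain for measured quenching spectra.

Measured data go through solvent-baseline subtraction, inner-filter
(self-absorption) correction from the absorbances of the two outermost
samples, rank-truncated SVD smoothing, and reduction to an informative
wavelength window.  Here a synthetic stand-in with the experimental
geometry (21 levels, 0 .. 0.2056 M) demonstrates the pathway.
"""

import numpy as np

from quenchmcr import (
    inner_filter_correct,
    load_series,
    reduce_range,
    save_series,
    subtract_baseline,
    svd_reproduce,
    synthesize_series,
)

Q = np.linspace(0.0, 0.2056, 21)
series, _ = synthesize_series(Q=Q)
save_series(series, "scratch_measured_like.csv")

work = load_series("scratch_measured_like.csv")
print(f"loaded {work.intensities.shape} matrix, "
      f"Q = {work.quencher_concs[0]} .. {work.quencher_concs[-1]} M")

work = subtract_baseline(work, np.full(work.wavelengths.size, 0.0))
A_em = np.vstack([np.full(work.wavelengths.size, 0.01),
                  np.full(work.wavelengths.size, 0.03)])
work = inner_filter_correct(work, (0.02, 0.08), A_em)
work = work.with_intensities(svd_reproduce(work.intensities, 3),
                             "SVD reproduction at rank 3")
work = reduce_range(work, 420.0, 500.0)

print(f"after preprocessing: {work.intensities.shape} "
      f"({work.wavelengths[0]:.0f}-{work.wavelengths[-1]:.0f} nm)")
print("steps applied:", "; ".join(work.history))
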