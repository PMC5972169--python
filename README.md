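# quenchmcr

Multivariate curve resolution of multi-component fluorescence quenching
spectra.

When a mixture of fluorophores is titrated with a collisional quencher,
the emission spectrum recorded at each quencher concentration is a sum of
pure-component spectra whose intensities decay at different rates.
`quenchmcr` resolves such a series into pure-component emission spectra
and per-component Stern–Volmer quenching constants, for people doing
fluorimetric mixture analysis: photophysics and chemometrics groups,
protein-fluorescence labs (selective quenching of tryptophan classes), or
anyone with a quencher-titration data matrix and overlapping emitters.

## The model

For collisional quenching each component *n* obeys the linear
Stern–Volmer law

    F0(λ) / F(λ) = 1 + K_n · Q

with `K_n` (M⁻¹) the quenching constant and `Q` the quencher
concentration.  A series of mixture spectra is then bilinear,

    Y = C Sᵀ,      C(Q, n) = 1 / (1 + K_n Q),

where rows of `Y` are spectra at increasing `Q` (first row unquenched),
columns of `C` are decay profiles and columns of `S` pure spectra.  Once
`C` is known, `Sᵀ = (CᵀC)⁻¹CᵀY`.  The package implements the standard
routes from `Y` to `(K, C, S)`:

* **τ-RAFA** (indirect rank annihilation): from matrices recorded at
  several excitation lines per quencher level, scan τ in
  `D = M0 − τ·M_Q`; the n-th eigenvalue of `D Dᵀ` collapses at
  `τ = 1 + K_n Q`, and the slope of τ versus `Q` is the constant.
* **κ-RAFA** (direct): one excitation line; difference rows
  `y0 − (1 + κQ)·y_Q` across the ladder; minima over κ are the constants.
* **Point fits** at each emission wavelength: the Acuña sum of
  hyperbolas `F/F0 = Σ f_n / (1 + K_n Q)` (FRA) and the Lehrer
  third-degree rational difference model for `ΔF/F0` in its reduced
  five-coefficient form, with constants recovered as the roots of
  `−K³ + b₁K² − b₂K + b₃ = 0` (DIF); component-matched means over
  wavelengths summarize them.
* **White (hard) matrix resolution**: Newton–Gauss/Levenberg–Marquardt
  fit of the constants on the whole matrix, classical (`Y`) or
  fractional (`Y` row-normalized by the unquenched spectrum, with
  wavelength-range reduction).
* **Grey MCR-ALS**: alternating non-negative least squares where the
  decay profiles are free digitized curves initialized from a hard
  model — only non-negativity is imposed.

A simulator generates bilinear datasets from Gaussian-band component
spectra with the two noise models of real titrations: additive
instrumental (spectral) noise and proportional concentration
(sample-preparation) noise.

## Worked example

```python
import numpy as np
from quenchmcr import (NoiseSpec, synthesize_series, white_classical,
                       kappa_rafa, match_components)

noise = NoiseSpec(spectral_permille=0.5, concentration_percent=5.0, seed=1)
series, truth = synthesize_series(noise=noise)   # K = [5, 100, 20] 1/M

print(np.round(kappa_rafa(series).K, 2))        # direct RAFA estimates
res = white_classical(series, K0=[4.0, 120.0, 15.0])
print(np.round(res.K, 2))                       # hard-model optimum
order = np.argsort(truth["K"])
sim = match_components(res, reference_S=truth["S"][:, order]).similarity
print(np.round(sim, 4))
```

prints

```
[  3.64  16.49 109.58]
[  4.94  26.26 142.47]
[0.9998 0.9961 0.9987]
```

The direct RAFA scan drifts under noise (smallest constant 3.64 versus
the true 5.0), the whole-matrix fit lands closer for the smallest
constant but overshoots the largest on this noise realization, and the
resolved spectra still match the true pure spectra to better than 0.4%
in shape (normalized inner product).  The scripts in `examples/` walk
through simulation, RAFA, point fits, matrix resolution and the
preprocessing chain for measured data, each printing and explaining its
numbers.

A thin CLI mirrors the library:
`quenchmcr simulate | preprocess | rafa | pointfit | resolve | compare | run`
(see `quenchmcr --help`); `run` executes a YAML-configured pipeline and
writes a manifest with the config hash and per-stage summaries.

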