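# Methods

## Model and assumptions

All methods in this package assume (i) linear Stern–Volmer quenching for
every component — the unquenched/quenched intensity ratio at any emission
wavelength is `1 + K_n Q`, which holds for purely collisional quenching
at moderate quencher concentrations (static quenching, upward-curving
Stern–Volmer plots and quencher–fluorophore complexation are out of
scope) — and (ii) bilinearity of the data matrix, `Y = C Sᵀ`: the shape
of each component's emission spectrum does not change with quenching,
only its amplitude.  The unquenched sample (`Q = 0`) must be the first
row; hard methods anchor every decay column to 1 there, which also fixes
the intensity scale of the resolved spectra.

The number of components is an input everywhere.  Rank-estimation
heuristics are deliberately not provided: the intended workflow is to
inspect the singular value spectrum (see `svd_reproduce`) and the RAFA
eigenvalue profiles, which make the component count visible, and then to
pass `n` explicitly.

## Estimating the constants

**τ-RAFA** needs data at several excitation lines (at least as many as
components) because annihilating one component must leave a
lower-rank — but still structured — residual.  The profile of the n-th
covariance eigenvalue against τ is scanned on
`[1, 1.2·(1 + K_max·Q)]`, where `K_max` comes from a coarse pre-scan;
grids are 2000 points, and each located minimum is refined by two local
zoom scans (81 points each) plus a parabolic interpolation on the
log-eigenvalue.  On exact data this reproduces the constants to ~1e-6
relative.  Minima are associated across quencher levels by ascending
order, which is exact because `K → 1 + KQ` preserves order for every
`Q > 0`.  The line fit τ(Q) keeps a free intercept; its deviation from 1
is reported as a diagnostic.  Levels yielding fewer minima than
components are excluded from the fits and listed.

**κ-RAFA** scans `κ ∈ [0, 1.2·K_max]` the same way.  Its minima are the
constants directly, so a coherent error in the concentration ladder
shifts them with nothing to average against — the reason the direct
method degrades much faster under concentration noise than the indirect
one (whose per-level minima errors largely cancel in the slope).

**Point fits** (three-component systems only, as the closed-form
coefficient algebra is cubic): the FRA model optimizes fractions and
constants directly; the DIF model optimizes the five reduced rational
coefficients `(a₁, a₂, a₃, b₁, b₂)` with the cubic coefficient shared
between numerator and denominator (`a₃ = b₃`, which is exact when the
fractions close to 1), then recovers constants as cubic roots and
fractions from a 3×3 linear solve.  Repeated real roots surface
numerically as conjugate pairs with small imaginary parts, so roots with
relative imaginary part below 1e-4 are treated as real.  Records enter
the component-matched means only if the optimizer converged and all
constants are positive, finite, and inside the identifiable range of the
ladder: a constant with `1/K` far below the first nonzero quencher level
(`K ≥ 10 / Q_min`) decays entirely between the first two samples and is
indistinguishable from "fully quenched", so such records are flagged
invalid rather than averaged.  Identical initial fractions make the
Jacobian columns of exchangeable parameters coincide (a rank-deficient,
stall-prone start); they are automatically jittered by 1e-4 with a
warning, which can be disabled.

## The optimizer

`nglm_fit` is a damped Gauss–Newton iteration: forward-difference
Jacobian (relative step 1e-6, absolute floor 1 for near-zero
parameters), step `δp = −J⁺r` via an SVD least-squares solve with the
singular-value cutoff at machine epsilon times the larger matrix
dimension, and Levenberg–Marquardt damping by augmenting `J` with `m·I`
and padding the residual with zeros.  The schedule: `m` starts at 0; the
first rejected step sets it to the problem scale `sqrt(mean diag JᵀJ)`;
each further rejection multiplies by 10, each accepted step divides by
3, and `m` snaps to 0 once below 1e-6 of the scale.  Convergence is a
relative ssq change below `tol` (default 1e-4, the classic choice for
this family of fitters); a rejected step whose ssq increase is already
within `tol` counts as a converged stall.  Runaway damping (1e12 × the
scale) reports non-convergence.  On linear problems the first step is
exact.  No analytic gradients and no bound constraints: positivity of
the white-model constants is enforced by rejecting non-positive trial
steps through an inflated residual, and non-negativity of profiles
belongs to the ALS stage, not the optimizer.

## Matrix resolution

The white fits optimize only the constants; the residual is the
projection `Y − C(K) C(K)⁺ Y`, flattened column-major (the order is
irrelevant to the optimum and fixed for reproducibility).  The
fractional variant divides every row point-wise by the unquenched row
first.  Wavelengths where the reference intensity is below 5% of its
maximum are dropped by default — after division those columns are pure
amplified noise; an explicit wavelength window, when given, takes
precedence over the floor.  Spectra are rebuilt entry-wise as
`s_ij = f_ij · y0_i`, which on exact data equals the pseudoinverse
spectra (tested as an identity).  Components are ordered by ascending
constant.

MCR-ALS alternates exact non-negative least squares per column
(spectra step) and per row (decay step), then rescales each decay column
by its `Q = 0` element so `C[0, j] = 1` — this pins the bilinear scale
ambiguity without changing `C Sᵀ`, so the per-cycle ssq sequence stays
non-increasing.  Stopping: relative ssq change below 0.1% (the usual
MCR-ALS rule) or 500 cycles; the ALS tail converges only sublinearly on
strongly overlapped spectra, so tighter tolerances mostly buy
iterations.  A decay column collapsing to zero (or a non-positive
anchor) raises an error naming the component.  Only non-negativity is
imposed — no unimodality, closure or equality constraints.  For
multi-excitation data, each line is resolved independently and the
component-matched, max-normalized spectra are averaged (emission shape
is excitation-independent; only the weights change).

Component matching (for comparisons against a reference) maximizes total
cosine similarity between spectra via the Hungarian assignment.

## Preprocessing measured data

Baseline subtraction is row-wise over the shared grid.  The inner-filter
correction multiplies each intensity by `10^((A_ex + A_em)/2)` — the
standard half-path correction for right-angle geometry — with the
absorbances interpolated linearly in `Q` between the two measured
endpoint samples (`Q = 0` and `Q = Q_max`); this is a declared
convention, since only primary/secondary endpoint absorbances are
typically recorded.  Negative absorbances are clipped to zero with a
warning.  SVD reproduction truncates to a user-chosen rank (no silent
default).  Every step appends to the series' history log.

## The simulator

Pure spectra are sums of Gaussian bands (`width` = standard deviation,
so a lone band peaks at its amplitude).  The default system emulates a
mixture of three anthracene-like emitters with strongly overlapping
vibronic bands on a 380–600 nm grid at 0.5 nm (441 points), constants
K = [5.00, 100, 20.0] M⁻¹, and 21 quencher levels from 0 to 0.2 M; the
band positions are fixed package defaults, loosely modeled on
cyanoanthracene emission in methanol.  Two imperfections are modeled:

* additive spectral noise `F + y·r·max(F)`, `r ~ U(−1, 1)` i.i.d. per
  entry, `max(F)` over the whole series, `y` in per mille — instrumental
  noise, signal-independent;
* proportional concentration noise `Q(1 + x·r)`, one draw per quencher
  level (one cuvette), `x` in percent — a sample-preparation error.  The
  perturbed ladder builds the data; the *nominal* ladder is what the
  dataset reports, because downstream algorithms never know the true
  amounts.

Multi-excitation sets weight the components per line by a strictly
positive 5×3 matrix (condition number < 50, drawn once from a fixed
seed); rank-deficient weight matrices are rejected since annihilation is
undefined without distinct mixes.

What the simulator does not emulate: Rayleigh/Raman scatter, inner
filter effects, baseline drift, wavelength-dependent detector response,
static quenching, or correlated (pink) noise.  Passing tests on
simulated data therefore demonstrate the algebra and the noise-response
trends, not robustness to every artifact of real spectra; the
preprocessing module exists precisely because measured data need those
corrections before the clean model applies.

## Problem sizes and reproducibility

Monte-Carlo checks in the test suite use 20 seeds per condition and the
default 441-point grid; the per-wavelength benchmark means average a
handful of realizations.  These sizes make every trend assertion stable
while keeping the whole suite around a minute.  All stochastic stages
take explicit seeds; the CLI pipeline records a config hash and
per-stage summaries in a manifest, and refuses unseeded noisy runs in
strict mode.

## Known limitations

* A single noisy realization carries a coherent concentration-noise
  bias: every per-wavelength fit sees the same wrong ladder, so means
  over wavelengths scatter by tens of percent between realizations.
  Trend claims need many seeds; single-realization numbers are
  illustrative.
* The largest constant is intrinsically weakly identified on a ladder
  reaching `K·Q ≈ 20`: that component is nearly fully quenched over most
  samples.  Per-wavelength DIF fits often push it beyond the
  identifiable range (the same degeneracy that historically plagued the
  rational-function parameterization), which is why DIF keeps far fewer
  valid records than FRA.
* The two smaller constants (5 and 20 M⁻¹) are close enough that their
  spectra trade off against each other in noisy resolutions; the
  middle component is typically the worst resolved.
* Point-fit algebra is three-component only; the matrix methods handle
  general `n`.
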