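"""Per-wavelength ("point") Stern-Volmer fits for three-component mixtures.

Two classical parameterizations of the quenched-intensity decay at a
single emission wavelength are fit by the Newton-Gauss optimizer:

* FRA (Acuña): F/F0 = Σ_j f_j / (1 + K_j Q) — a sum of three hyperbolas
  whose parameters are the intensity fractions and the constants directly;
* DIF (Lehrer): ΔF/F0 = 1 - F/F0 as a third-degree rational function of Q
  in the reduced five-coefficient form
  (a1 Q + a2 Q² + a3 Q³) / (1 + b1 Q + b2 Q² + a3 Q³), where the shared
  leading coefficient a3 = b3 = K_A K_B K_C follows from the closure of
  the fractions.  The constants are recovered afterwards as the roots of
  -K³ + b1 K² - b2 K + b3 = 0 and the fractions from a 3x3 linear system.

Per-wavelength estimates scatter strongly on noisy data; component-wise
means over wavelengths (after ascending-K matching and removal of
unphysical records) are the method's headline numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import QuenchingSeries
from .nglm import nglm_fit

__all__ = [
    "PointFitRecord",
    "PointAggregate",
    "DEFAULT_INIT_FRACTIONS",
    "DEFAULT_INIT_CONSTANTS",
    "fra_model",
    "dif_model",
    "dif_coefficients",
    "dif_extract_constants",
    "dif_extract_fractions",
    "fit_point",
    "fit_series",
    "aggregate_pointwise",
]

# conventional starting vectors for a three-component quenching fit
DEFAULT_INIT_FRACTIONS = np.array([0.3000, 0.3333, 0.3337])
DEFAULT_INIT_CONSTANTS = np.array([4.00, 15.0, 120.0])


@dataclass
class PointFitRecord:
    """Result of one per-wavelength fit; ``valid`` marks records whose
    constants are finite, real and positive and whose fit converged —
    only those enter aggregation."""

    wavelength: float
    model: str
    K: np.ndarray
    f: np.ndarray
    ssq: float
    converged: bool
    valid: bool
    message: str = ""


@dataclass
class PointAggregate:
    """Component-matched means over wavelengths (ascending-K order)."""

    K_mean: np.ndarray
    K_std: np.ndarray
    n_used: int
    n_total: int
    wavelengths: np.ndarray
    fractions: np.ndarray  # (n_used, 3), matched to ascending K


def fra_model(Q, f, K) -> np.ndarray:
    """Sum-of-hyperbolas decay F/F0 = Σ_j f_j / (1 + K_j Q)."""
    Q = np.asarray(Q, float)
    f = np.asarray(f, float)
    K = np.asarray(K, float)
    return (f[None, :] / (1.0 + np.outer(Q, K))).sum(axis=1)


def dif_model(Q, p) -> np.ndarray:
    """Reduced third-degree rational ΔF/F0 with p = (a1, a2, a3, b1, b2)
    and the cubic denominator coefficient tied to a3."""
    Q = np.asarray(Q, float)
    a1, a2, a3, b1, b2 = np.asarray(p, float)
    num = Q * (a1 + Q * (a2 + Q * a3))
    den = 1.0 + Q * (b1 + Q * (b2 + Q * a3))
    if np.any(den <= 0) or np.any(np.abs(den) < 1e-12):
        raise ValueError("rational model has a pole inside the Q range")
    return num / den


def dif_coefficients(f, K):
    """Forward map (f, K) → (a1, a2, a3, b1, b2) of the reduced rational
    form (a3 = b3 holds exactly when the fractions close to 1)."""
    fA, fB, fC = np.asarray(f, float)
    KA, KB, KC = np.asarray(K, float)
    a1 = fA * KA + fB * KB + fC * KC
    a2 = fA * KA * (KB + KC) + fB * KB * (KA + KC) + fC * KC * (KA + KB)
    a3 = KA * KB * KC * (fA + fB + fC)
    b1 = KA + KB + KC
    b2 = KA * KB + KB * KC + KA * KC
    return np.array([a1, a2, a3, b1, b2])


class UnphysicalRootsError(ValueError):
    """The denominator cubic has complex or non-positive roots."""

    def __init__(self, roots):
        self.roots = roots
        super().__init__(f"cubic roots are not three positive reals: {roots}")


def dif_extract_constants(b1, b2, b3) -> np.ndarray:
    """Roots of -K³ + b1 K² - b2 K + b3 = 0, which are the three
    Stern-Volmer constants by Vieta; returned ascending."""
    roots = np.roots([1.0, -b1, b2, -b3])
    # repeated real roots surface numerically as conjugate pairs with a
    # small imaginary part (O(eps^(1/3)) for a triple root)
    tol = 1e-4 * max(1.0, np.abs(roots).max())
    if np.any(np.abs(roots.imag) > tol):
        raise UnphysicalRootsError(roots)
    real = np.sort(roots.real)
    if np.any(real <= 0):
        raise UnphysicalRootsError(roots)
    return real


def dif_extract_fractions(a1, a2, a3, K):
    """Solve the 3x3 linear system mapping fractions to the numerator
    coefficients.  Returns ``(f, f_sum)``; the fractions are reported
    unnormalized (their sum is 1 only for a perfectly consistent fit)."""
    KA, KB, KC = np.asarray(K, float)
    M = np.array([
        [KA, KB, KC],
        [KA * (KB + KC), KB * (KA + KC), KC * (KA + KB)],
        [KA * KB * KC, KA * KB * KC, KA * KB * KC],
    ])
    if np.linalg.cond(M) > 1e12:
        raise ValueError(
            f"singular fraction system: constants {K} are not distinct")
    f = np.linalg.solve(M, np.array([a1, a2, a3], float))
    return f, float(f.sum())


def _maybe_jitter_fractions(f0, enable):
    f0 = np.asarray(f0, float).copy()
    if enable and np.ptp(f0) < 1e-12:
        # identical starting fractions give linearly dependent update
        # directions and the optimizer stalls; nudge them apart
        f0 = f0 + 1e-4 * np.arange(f0.size)
        warnings.warn("identical initial fractions jittered by 1e-4",
                      stacklevel=3)
    return f0


def fit_point(series: QuenchingSeries, wavelength: float, model: str = "fra",
              f0=None, K0=None, jitter_equal: bool = True,
              tol: float = 1e-4, max_iter: int = 50) -> PointFitRecord:
    """Fit the decay at one emission wavelength.

    ``model`` is ``"fra"`` (sum of hyperbolas on F/F0) or ``"dif"``
    (reduced rational on 1 - F/F0, with constants and fractions extracted
    from the optimized coefficients afterwards).
    """
    model = model.lower()
    if model not in ("fra", "dif"):
        raise ValueError(f"model must be 'fra' or 'dif', got {model!r}")
    idx = int(np.argmin(np.abs(series.wavelengths - wavelength)))
    if abs(series.wavelengths[idx] - wavelength) > 1e-9:
        raise ValueError(f"wavelength {wavelength} nm not on the grid")
    # identifiability bound of the sampled ladder: a constant with
    # 1/K << Q_min decays entirely between Q=0 and the first sample, so
    # any larger value is indistinguishable from "fully quenched"
    q_min = series.quencher_concs[series.quencher_concs > 0].min()
    K_cap = 10.0 / q_min
    F = series.intensities[:, idx]
    if F[0] <= 0:
        raise ValueError(
            f"unquenched intensity at {wavelength} nm is not positive")
    ratio = F / F[0]
    Q = series.quencher_concs
    f0 = DEFAULT_INIT_FRACTIONS if f0 is None else np.asarray(f0, float)
    K0 = DEFAULT_INIT_CONSTANTS if K0 is None else np.asarray(K0, float)
    f0 = _maybe_jitter_fractions(f0, jitter_equal)

    if model == "fra":
        def residual(p):
            return ratio - fra_model(Q, p[:3], p[3:])

        fit = nglm_fit(residual, np.concatenate([f0, K0]),
                       tol=tol, max_iter=max_iter)
        f, K = fit.params[:3], fit.params[3:]
        order = np.argsort(K)
        K, f = K[order], f[order]
        valid = bool(fit.converged and np.all(np.isfinite(K))
                     and np.all(K > 0) and np.all(K < K_cap))
        return PointFitRecord(series.wavelengths[idx], "fra", K, f,
                              fit.ssq, fit.converged, valid, fit.message)

    delta = 1.0 - ratio

    def residual(p):
        a1, a2, a3, b1, b2 = p
        num = Q * (a1 + Q * (a2 + Q * a3))
        den = 1.0 + Q * (b1 + Q * (b2 + Q * a3))
        bad = np.abs(den) < 1e-12
        if bad.any():
            den = np.where(bad, np.nan, den)
        return delta - num / den

    p0 = dif_coefficients(f0, K0)
    fit = nglm_fit(residual, p0, tol=tol, max_iter=max_iter)
    a1, a2, a3, b1, b2 = fit.params
    try:
        K = dif_extract_constants(b1, b2, a3)
        f, _ = dif_extract_fractions(a1, a2, a3, K)
        valid = bool(fit.converged and np.all(K > 0) and np.all(K < K_cap))
        msg = fit.message
    except (UnphysicalRootsError, ValueError) as exc:
        K = np.full(3, np.nan)
        f = np.full(3, np.nan)
        valid = False
        msg = str(exc)
    return PointFitRecord(series.wavelengths[idx], "dif", K, f,
                          fit.ssq, fit.converged, valid, msg)


def fit_series(series: QuenchingSeries, model: str = "fra", f0=None, K0=None,
               min_rel_intensity: float = 0.01, wavelengths=None,
               **kwargs) -> list:
    """Fit every emission wavelength whose unquenched intensity exceeds
    ``min_rel_intensity`` times the maximum of the reference spectrum
    (the near-dark tails carry no decay information, only noise)."""
    if wavelengths is None:
        floor = min_rel_intensity * series.y0.max()
        wavelengths = series.wavelengths[series.y0 > floor]
    return [fit_point(series, wl, model=model, f0=f0, K0=K0, **kwargs)
            for wl in wavelengths]


def aggregate_pointwise(records) -> PointAggregate:
    """Component-matched mean constants and fraction profiles.

    Each valid record's constants are sorted ascending (with fractions
    permuted alongside) before averaging component-wise, so component
    identity is matched by the ordering of K across wavelengths.
    """
    records = list(records)
    if not records:
        raise ValueError("no point-fit records to aggregate")
    used = [r for r in records if r.valid]
    if not used:
        raise ValueError("no valid (converged, physical) records to aggregate")
    Ks, fs, wls = [], [], []
    for r in used:
        order = np.argsort(r.K)
        Ks.append(np.asarray(r.K)[order])
        fs.append(np.asarray(r.f)[order])
        wls.append(r.wavelength)
    Ks = np.asarray(Ks)
    fs = np.asarray(fs)
    return PointAggregate(
        K_mean=Ks.mean(axis=0),
        K_std=Ks.std(axis=0, ddof=1) if len(used) > 1 else np.zeros(Ks.shape[1]),
        n_used=len(used),
        n_total=len(records),
        wavelengths=np.asarray(wls),
        fractions=fs,
    )
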