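"""Rank annihilation factor analysis for Stern-Volmer constants.

Two variants are implemented.  The indirect τ-RAFA scans a floating
factor τ in the difference matrix D_Q = M0 - τ·M_Q built from
multi-excitation matrices at fixed quencher level Q: when τ = 1 + K_j Q
the j-th component is annihilated and the n-th eigenvalue of the
covariance D_Q D_Qᵀ collapses; the per-Q minima are then regressed on Q,
the slope being the Stern-Volmer constant.  The direct κ-RAFA builds one
difference row per quencher level of a single-excitation series,
d_Q = y0 - (1 + κQ)·y_Q, and the minima of the n-th eigenvalue over κ are
the constants themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import MultiExcitationSet, QuenchingSeries

__all__ = ["EigenProfile", "RafaResult", "tau_profile", "tau_rafa",
           "kappa_rafa", "fit_sv_line"]

_LOG_FLOOR = 1e-300  # keeps log of an exactly annihilated eigenvalue finite


@dataclass
class EigenProfile:
    """Scanned eigenvalue profile: ``third_eigenvalue[i]`` is the k-th
    (descending) eigenvalue of the difference-matrix covariance at
    ``grid[i]``; ``minima`` are the parabolic-refined minimum locations,
    ascending."""

    grid: np.ndarray
    third_eigenvalue: np.ndarray
    minima: np.ndarray
    at_boundary: bool = False


@dataclass
class RafaResult:
    """Constants estimated by a RAFA scan, ascending component order."""

    K: np.ndarray
    method: str
    intercepts: np.ndarray | None = None
    r_squared: np.ndarray | None = None
    minima_table: np.ndarray | None = None   # (n nonzero Q levels) x n, NaN = missing
    quencher_concs: np.ndarray | None = None
    excluded_levels: list = field(default_factory=list)
    profiles: list = field(default_factory=list)


def _eig_curve(gram_fn, grid, k):
    """k-th largest eigenvalue (1-based) of the covariance at each grid point."""
    vals = np.empty(grid.size)
    for i, t in enumerate(grid):
        ev = np.linalg.eigvalsh(gram_fn(t))
        vals[i] = max(ev[-k], 0.0)  # clip tiny negative round-off
    return vals


def _parabolic_vertex(x, y):
    """Vertex abscissa of the parabola through three points on a uniform
    grid; falls back to the middle point when curvature is not convex."""
    denom = y[0] - 2 * y[1] + y[2]
    if denom > 0:
        return x[1] + 0.5 * (x[2] - x[1]) * (y[0] - y[2]) / denom
    return x[1]


def _refine_minima(grid, vals, n_minima, eval_fn=None, context=""):
    """Locate interior local minima of log(vals), keep the ``n_minima``
    deepest, and refine each: a local fine re-scan between the coarse
    neighbors (when ``eval_fn`` is available) followed by a parabolic
    interpolation on the log-eigenvalue."""
    logv = np.log(np.maximum(vals, _LOG_FLOOR))
    idx = [i for i in range(1, grid.size - 1)
           if logv[i] <= logv[i - 1] and logv[i] <= logv[i + 1]
           and (logv[i] < logv[i - 1] or logv[i] < logv[i + 1])]
    if len(idx) < n_minima:
        warnings.warn(
            f"{context}: found {len(idx)} local minima, expected {n_minima} "
            "(grid too coarse, or annihilation minima merged/lost)",
            stacklevel=3,
        )
    idx = sorted(idx, key=lambda i: logv[i])[:n_minima]
    refined = []
    for i in sorted(idx):
        x = grid[i - 1:i + 2].copy()
        y = logv[i - 1:i + 2].copy()
        if eval_fn is not None:
            for _ in range(2):  # two zoom levels: ~1e-4 of the coarse step
                fine = np.linspace(x[0], x[2], 81)
                fv = np.log(np.maximum(eval_fn(fine), _LOG_FLOOR))
                j = int(np.clip(fv.argmin(), 1, fine.size - 2))
                x, y = fine[j - 1:j + 2], fv[j - 1:j + 2]
        refined.append(_parabolic_vertex(x, y))
    return np.sort(np.asarray(refined))


def tau_profile(M0, MQ, tau_grid, k_component: int = 3,
                n_minima: int | None = None) -> EigenProfile:
    """Scan τ in D = M0 - τ·M_Q and trace the k-th covariance eigenvalue.

    ``k_component`` is 1-based (3 = the "third eigenvalue" of a
    three-component system).  The Gram matrices of M0 and M_Q are
    precomputed so each grid point costs one small eigendecomposition.
    """
    M0 = np.asarray(M0, float)
    MQ = np.asarray(MQ, float)
    if M0.shape != MQ.shape:
        raise ValueError(f"shape mismatch: {M0.shape} vs {MQ.shape}")
    if M0.shape[0] < k_component:
        raise ValueError(
            f"need at least {k_component} excitation rows to track "
            f"eigenvalue {k_component}, got {M0.shape[0]}"
        )
    tau_grid = np.asarray(tau_grid, float)
    A = M0 @ M0.T
    B = M0 @ MQ.T
    Bs = B + B.T
    C = MQ @ MQ.T
    gram = lambda t: A - t * Bs + t * t * C
    vals = _eig_curve(gram, tau_grid, k_component)
    n_minima = k_component if n_minima is None else n_minima
    minima = _refine_minima(tau_grid, vals, n_minima,
                            eval_fn=lambda xs: _eig_curve(gram, xs, k_component),
                            context="tau_profile")
    return EigenProfile(grid=tau_grid, third_eigenvalue=vals, minima=minima)


def fit_sv_line(Q, tau):
    """Ordinary least-squares line τ = intercept + slope·Q.

    Returns ``(slope, intercept, r_squared)``.
    """
    Q = np.asarray(Q, float)
    tau = np.asarray(tau, float)
    if Q.size < 2:
        raise ValueError("need at least two points for a line fit")
    if np.ptp(Q) == 0:
        raise ValueError("all quencher concentrations are equal; line undefined")
    slope, intercept = np.polyfit(Q, tau, 1)
    resid = tau - (intercept + slope * Q)
    sst = np.sum((tau - tau.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / sst if sst > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def _prescan_kmax(gram_fn, Q_scale, k, kcap=1000.0, points=2000):
    """Coarse scan to bracket the largest annihilation point; returns a
    guess for the largest Stern-Volmer constant."""
    grid = np.linspace(0.0, kcap, points)
    tgrid = 1.0 + grid * Q_scale
    vals = _eig_curve(gram_fn, tgrid, k)
    logv = np.log(np.maximum(vals, _LOG_FLOOR))
    idx = [i for i in range(1, points - 1)
           if logv[i] <= logv[i - 1] and logv[i] <= logv[i + 1]]
    if not idx:
        return kcap
    return max(grid[max(idx)], 1e-3 * kcap)


def tau_rafa(mset: MultiExcitationSet, n_components: int = 3,
             tau_max_factor: float = 1.2, grid_points: int = 2000,
             K_max_guess: float | None = None) -> RafaResult:
    """Indirect RAFA on a multi-excitation set.

    For every nonzero quencher level the τ-profile is scanned on
    ``[1, tau_max_factor·(1 + K_max_guess·Q)]``; the ``n_components``
    deepest minima are associated across levels by ascending order (the
    map K → 1 + KQ is order-preserving for Q > 0) and each component's
    minima are regressed on Q with a free intercept.  Levels yielding
    fewer minima than components are excluded from the fits and listed in
    ``excluded_levels``.
    """
    if mset.n_excitations < n_components:
        raise ValueError("need at least as many excitation lines as components")
    Qs = mset.quencher_concs
    nz = np.nonzero(Qs > 0)[0]
    if nz.size < 2:
        raise ValueError("need at least two nonzero quencher levels")
    M0 = mset.M0

    if K_max_guess is None:
        MQ = mset.matrices[nz[-1]]
        A, B, C = M0 @ M0.T, M0 @ MQ.T, MQ @ MQ.T
        Bs = B + B.T
        K_max_guess = _prescan_kmax(
            lambda t: A - t * Bs + t * t * C, Qs[nz[-1]], n_components)

    minima_table = np.full((nz.size, n_components), np.nan)
    profiles = []
    excluded = []
    for row, k in enumerate(nz):
        q = Qs[k]
        grid = np.linspace(1.0, tau_max_factor * (1.0 + K_max_guess * q),
                           grid_points)
        prof = tau_profile(M0, mset.matrices[k], grid, k_component=n_components)
        profiles.append(prof)
        if prof.minima.size < n_components:
            excluded.append(int(k))
            continue
        minima_table[row] = prof.minima

    K = np.full(n_components, np.nan)
    intercepts = np.full(n_components, np.nan)
    r2 = np.full(n_components, np.nan)
    ok = ~np.isnan(minima_table[:, 0])
    if ok.sum() >= 2:
        for j in range(n_components):
            K[j], intercepts[j], r2[j] = fit_sv_line(Qs[nz][ok],
                                                     minima_table[ok, j])
    return RafaResult(K=K, method="tau-RAFA", intercepts=intercepts,
                      r_squared=r2, minima_table=minima_table,
                      quencher_concs=Qs[nz], excluded_levels=excluded,
                      profiles=profiles)


def kappa_rafa(series: QuenchingSeries, n_components: int = 3,
               kappa_grid=None, grid_points: int = 2000,
               K_max_guess: float | None = None) -> RafaResult:
    """Direct RAFA on a single-excitation series.

    The difference matrix has one row per nonzero quencher level,
    d_Q = y0 - (1 + κQ)·y_Q; the refined minima of the n-th covariance
    eigenvalue over κ are the Stern-Volmer constants directly.
    """
    Qs = series.quencher_concs
    nz = np.nonzero(Qs > 0)[0]
    if nz.size < 3:
        raise ValueError("need at least three nonzero quencher levels")
    y0 = series.y0
    Yq = series.intensities[nz]
    Qpos = Qs[nz]

    g00 = float(y0 @ y0)
    g0 = Yq @ y0            # (nQ,)
    G = Yq @ Yq.T           # (nQ, nQ)

    def gram(kappa):
        a = 1.0 + kappa * Qpos
        return (g00 - a[None, :] * g0[None, :] - a[:, None] * g0[:, None]
                + np.outer(a, a) * G)

    if kappa_grid is None:
        if K_max_guess is None:
            grid = np.linspace(0.0, 1000.0, grid_points)
            vals = _eig_curve(gram, grid, n_components)
            logv = np.log(np.maximum(vals, _LOG_FLOOR))
            idx = [i for i in range(1, grid.size - 1)
                   if logv[i] <= logv[i - 1] and logv[i] <= logv[i + 1]]
            K_max_guess = grid[max(idx)] if idx else 1000.0
        kappa_grid = np.linspace(0.0, 1.2 * max(K_max_guess, 1.0), grid_points)
    else:
        kappa_grid = np.asarray(kappa_grid, float)

    vals = _eig_curve(gram, kappa_grid, n_components)
    minima = _refine_minima(kappa_grid, vals, n_components,
                            eval_fn=lambda xs: _eig_curve(gram, xs, n_components),
                            context="kappa_rafa")
    at_boundary = bool(vals.argmin() in (0, vals.size - 1))
    if at_boundary:
        warnings.warn("kappa_rafa: global minimum at the grid boundary; "
                      "the scan range may not cover all constants", stacklevel=2)
    prof = EigenProfile(grid=kappa_grid, third_eigenvalue=vals,
                        minima=minima, at_boundary=at_boundary)
    K = np.full(n_components, np.nan)
    K[: minima.size] = minima
    return RafaResult(K=K, method="kappa-RAFA", profiles=[prof])
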