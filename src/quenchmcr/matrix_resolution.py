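"""Full-matrix resolution of quenching data into pure spectra.

Three routes from a data matrix Y (rows = quencher levels, columns =
emission wavelengths) to decays C and pure spectra Sᵀ:

* white classical — the decays are hard-modeled as Stern-Volmer
  hyperbolas C(Q, n) = 1/(1 + K_n Q); the only free parameters are the n
  constants, optimized by Newton-Gauss on the projection residual
  Y - C(K) C(K)⁺ Y, and Sᵀ = C⁺Y at the optimum;
* white fractional — the same hard model applied to the fractional data
  Y_f (every row divided point-by-point by the unquenched row), which
  makes noisy spectral regions visible and supports range reduction; the
  optimization yields fraction profiles fᵀ = C⁺Y_f, converted to spectra
  by s_ij = f_ij · y0_i;
* grey MCR-ALS — alternating non-negative least squares in which C is a
  free digitized profile matrix (no functional form), constrained only to
  be non-negative and anchored to C[0, j] = 1, initialized from a hard
  model (typically RAFA-estimated constants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls

from .data_model import MultiExcitationSet, QuenchingSeries, ResolutionResult
from .nglm import nglm_fit
from .simulate import sv_decay_matrix

__all__ = [
    "resolve_spectra",
    "white_classical",
    "to_fractional",
    "white_fractional",
    "mcr_als",
    "match_components",
    "MatchResult",
    "series_from_excitation",
    "resolve_multi_excitation",
]


def resolve_spectra(C, Y) -> np.ndarray:
    """Least-squares spectra Sᵀ = (CᵀC)⁻¹CᵀY = C⁺Y for known decays."""
    C = np.asarray(C, float)
    Y = np.asarray(Y, float)
    n = C.shape[1]
    if np.linalg.matrix_rank(C) < n:
        # name the offending columns: pairs with |cos angle| ~ 1
        norms = np.linalg.norm(C, axis=0)
        norms[norms == 0] = 1.0
        G = (C / norms).T @ (C / norms)
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)
                 if abs(G[i, j]) > 1 - 1e-10]
        raise ValueError(
            f"decay matrix is rank deficient; collinear column pairs: "
            f"{pairs or 'degenerate column(s)'} (identical constants?)"
        )
    ST, *_ = np.linalg.lstsq(C, Y, rcond=None)
    return ST


def _projection_residual(Y, C):
    """Y - C C⁺ Y flattened column-major (fixed order for reproducibility)."""
    ST, *_ = np.linalg.lstsq(C, Y, rcond=None)
    return (Y - C @ ST).ravel(order="F")


def _white_fit(Y, Q, K0, tol, max_iter):
    Y = np.asarray(Y, float)
    K0 = np.asarray(K0, float)
    if np.any(K0 <= 0):
        raise ValueError("initial Stern-Volmer constants must be > 0")
    big = 1e3 * np.linalg.norm(Y)

    def residual(K):
        if np.any(K <= 0):
            return np.full(Y.size, big)  # unphysical K: reject the step
        return _projection_residual(Y, 1.0 / (1.0 + np.outer(Q, K)))

    fit = nglm_fit(residual, K0, tol=tol, max_iter=max_iter)
    return fit


def white_classical(series: QuenchingSeries, K0,
                    tol: float = 1e-10, max_iter: int = 50) -> ResolutionResult:
    """Hard resolution on the raw data matrix: optimize the constants,
    then recover the spectra by the left pseudoinverse.  Components are
    returned in ascending-K order."""
    Y = series.intensities
    Q = series.quencher_concs
    fit = _white_fit(Y, Q, K0, tol, max_iter)
    K = np.sort(fit.params)
    C = sv_decay_matrix(K, Q)
    S = resolve_spectra(C, Y).T
    return ResolutionResult(K=K, C=C, S=S, method="white-classical",
                            ssq=fit.ssq, n_iter=fit.n_iter,
                            converged=fit.converged,
                            wavelengths=series.wavelengths,
                            quencher_concs=Q)


def to_fractional(series: QuenchingSeries, threshold: float = 0.05) -> QuenchingSeries:
    """Divide every row point-by-point by the unquenched row.

    Wavelengths where the reference intensity falls below ``threshold``
    times its maximum are dropped — there the division explodes the
    noise.  Row 0 of the result is all ones.
    """
    y0 = series.y0
    keep = y0 > threshold * y0.max()
    if not keep.any():
        raise ValueError("no wavelength passes the fractional intensity floor")
    Yf = series.intensities[:, keep] / y0[keep][None, :]
    from dataclasses import replace
    return replace(series, wavelengths=series.wavelengths[keep],
                   intensities=Yf,
                   history=[*series.history,
                            f"fractional form ({(~keep).sum()} dim columns dropped)"])


def white_fractional(series: QuenchingSeries, K0, window=None,
                     threshold: float = 0.05, tol: float = 1e-10,
                     max_iter: int = 50) -> ResolutionResult:
    """Hard resolution on fractional data.

    An explicit wavelength ``window=(lo, hi)`` takes precedence over the
    relative intensity ``threshold``.  Fractions close to 1 across
    components at every retained wavelength on exact data; spectra are
    rebuilt entry-wise as s_ij = f_ij · y0_i.
    """
    from .data_model import reduce_range
    work = series
    if window is not None:
        work = reduce_range(work, *window)
        frac = to_fractional(work, threshold=0.0)
    else:
        frac = to_fractional(work, threshold=threshold)
    Q = frac.quencher_concs
    fit = _white_fit(frac.intensities, Q, K0, tol, max_iter)
    K = np.sort(fit.params)
    C = sv_decay_matrix(K, Q)
    f = resolve_spectra(C, frac.intensities).T        # (nλ_kept, n)
    keep = np.isin(work.wavelengths, frac.wavelengths)
    y0 = work.intensities[0][keep]
    S = f * y0[:, None]
    return ResolutionResult(K=K, C=C, S=S, method="white-fractional",
                            fractions=f, ssq=fit.ssq, n_iter=fit.n_iter,
                            converged=fit.converged,
                            wavelengths=frac.wavelengths,
                            quencher_concs=Q)


def _nnls_columns(A, B):
    """Column-wise non-negative least squares: minimize ||A X - B||, X >= 0."""
    X = np.empty((A.shape[1], B.shape[1]))
    for j in range(B.shape[1]):
        try:
            X[:, j], _ = nnls(A, B[:, j])
        except RuntimeError:
            # rare nnls iteration failure: fall back to clipped least squares
            x, *_ = np.linalg.lstsq(A, B[:, j], rcond=None)
            X[:, j] = np.clip(x, 0.0, None)
    return X


def mcr_als(Y, C0, tol: float = 1e-3, max_iter: int = 500) -> ResolutionResult:
    """Grey (hard-soft) resolution by alternating non-negative least squares.

    ``C0`` is the initial decay matrix, usually built from pre-estimated
    Stern-Volmer constants.  Each cycle solves Sᵀ given C and C given Sᵀ
    under non-negativity, then rescales every C column by its Q = 0
    element (fixing the bilinear scale ambiguity and anchoring
    C[0, j] = 1).  Iteration stops when the relative ssq change per cycle
    drops below ``tol`` (default 0.1%, the usual MCR-ALS stopping rule;
    the ALS tail converges only sublinearly on strongly overlapped
    components, so a tighter tolerance mostly buys iterations).
    """
    if isinstance(Y, QuenchingSeries):
        series, Y = Y, Y.intensities
    else:
        series = None
        Y = np.asarray(Y, float)
    C = np.asarray(C0, float).copy()
    if C.shape[0] != Y.shape[0]:
        raise ValueError(
            f"C0 has {C.shape[0]} rows for {Y.shape[0]} quencher levels")
    n = C.shape[1]
    ssq_trace = []
    converged = False
    ST = np.zeros((n, Y.shape[1]))
    for it in range(1, max_iter + 1):
        ST = _nnls_columns(C, Y)                      # spectra step
        C = _nnls_columns(ST.T, Y.T).T                # decay step
        anchors = C[0].copy()
        if np.any(anchors <= 0) or np.any(np.linalg.norm(C, axis=0) == 0):
            dead = [j for j in range(n)
                    if anchors[j] <= 0 or np.linalg.norm(C[:, j]) == 0]
            raise RuntimeError(
                f"component(s) {dead} collapsed to zero during ALS")
        C /= anchors[None, :]
        ST *= anchors[:, None]
        ssq = float(np.sum((Y - C @ ST) ** 2))
        ssq_trace.append(ssq)
        if it > 1:
            prev = ssq_trace[-2]
            if prev == 0 or (prev - ssq) / prev < tol:
                converged = True
                break
    return ResolutionResult(K=None, C=C, S=ST.T, method="mcr-als",
                            ssq=ssq_trace[-1], n_iter=len(ssq_trace),
                            converged=converged,
                            wavelengths=None if series is None else series.wavelengths,
                            quencher_concs=None if series is None else series.quencher_concs,
                            ssq_trace=ssq_trace)


@dataclass
class MatchResult:
    permutation: np.ndarray     # resolved column matched to reference column j
    similarity: np.ndarray      # normalized inner product per reference component
    K_errors: np.ndarray | None


def match_components(result: ResolutionResult, reference_S=None,
                     reference_K=None) -> MatchResult:
    """Best assignment of resolved components to reference components.

    Similarity is the normalized inner product (cosine) of spectra; the
    assignment maximizes total similarity (Hungarian algorithm).  When
    both carry constants, per-component |ΔK| is reported too.
    """
    if reference_S is None and reference_K is None:
        raise ValueError("need a reference: spectra and/or constants")
    if reference_S is not None:
        A = np.asarray(result.S, float)
        B = np.asarray(reference_S, float)
        An = A / np.maximum(np.linalg.norm(A, axis=0), 1e-300)
        Bn = B / np.maximum(np.linalg.norm(B, axis=0), 1e-300)
        sim = An.T @ Bn                                # (n_res, n_ref)
        rows, cols = linear_sum_assignment(-sim)
        perm = np.empty(len(cols), int)
        perm[cols] = rows
        similarity = sim[perm, np.arange(len(perm))]
    else:
        # match on constants alone
        dK = np.abs(np.subtract.outer(np.asarray(result.K, float),
                                      np.asarray(reference_K, float)))
        rows, cols = linear_sum_assignment(dK)
        perm = np.empty(len(cols), int)
        perm[cols] = rows
        similarity = np.full(len(perm), np.nan)
    K_errors = None
    if reference_K is not None and result.K is not None:
        K_errors = np.abs(np.asarray(result.K, float)[perm]
                          - np.asarray(reference_K, float))
    return MatchResult(permutation=perm, similarity=similarity, K_errors=K_errors)


def series_from_excitation(mset: MultiExcitationSet, line: int) -> QuenchingSeries:
    """Extract the single-excitation quenching series of one line."""
    Y = np.vstack([m[line] for m in mset.matrices])
    return QuenchingSeries(wavelengths=mset.wavelengths,
                           quencher_concs=mset.quencher_concs,
                           intensities=Y,
                           excitation=float(mset.excitations[line]))


def resolve_multi_excitation(mset: MultiExcitationSet, K0,
                             method: str = "classical", **kwargs):
    """Resolve each excitation line independently and average the
    component-matched, max-normalized spectra (the emission shape of a
    fluorophore does not depend on the excitation line, only its weight).

    Returns ``(S_mean, results)`` with ``S_mean`` of shape (nλ, n) in the
    component order of the first line's result.
    """
    resolvers = {"classical": white_classical, "fractional": white_fractional}
    if method not in resolvers:
        raise ValueError(f"method must be one of {sorted(resolvers)}")
    results = [resolvers[method](series_from_excitation(mset, e), K0, **kwargs)
               for e in range(mset.n_excitations)]
    ref = results[0].S
    acc = np.zeros_like(ref)
    for res in results:
        match = match_components(res, reference_S=ref)
        S = res.S[:, match.permutation]
        acc += S / np.maximum(S.max(axis=0), 1e-300)
    return acc / len(results), results
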