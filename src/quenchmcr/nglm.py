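"""Newton-Gauss least-squares minimizer with a Levenberg-Marquardt guard.

Minimizes ssq = rᵀr for a residual vector r(p) by the damped Gauss-Newton
iteration: the parameter shift solves the linearized problem
δp = -J⁺ r, where the Jacobian J is obtained by forward differences and,
when a plain step fails to lower ssq, J is augmented by a diagonal block
m·I (with the residual padded by zeros), which shortens and rotates the
step toward steepest descent.  The Marquardt parameter m follows the
classic schedule: start at 0, jump to the problem scale on the first
failed step, grow x10 per further failure, shrink /3 per success, snap
back to 0 once negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FitResult", "numeric_jacobian", "nglm_fit"]


@dataclass
class FitResult:
    params: np.ndarray
    ssq: float
    ssq_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    marquardt_final: float = 0.0
    message: str = ""


def numeric_jacobian(residual_fn, p, step: float = 1e-6,
                     step_floor: float = 1.0) -> np.ndarray:
    """Forward-difference Jacobian J[i, j] = ∂r_i/∂p_j.

    The per-parameter increment is ``step * max(|p_j|, step_floor)`` so
    that parameters near zero still get a finite absolute step.
    """
    p = np.asarray(p, float)
    r0 = np.asarray(residual_fn(p), float)
    if not np.all(np.isfinite(r0)):
        raise ValueError("residual is not finite at the expansion point")
    J = np.empty((r0.size, p.size))
    for j in range(p.size):
        h = step * max(abs(p[j]), step_floor)
        pj = p.copy()
        pj[j] += h
        rj = np.asarray(residual_fn(pj), float)
        if not np.all(np.isfinite(rj)):
            raise ValueError(f"residual not finite when perturbing parameter {j}")
        J[:, j] = (rj - r0) / h
    return J


def _solve_step(J, r, m):
    """δp = -J⁺r with optional Marquardt augmentation [J; m·I], [r; 0]."""
    if m > 0:
        A = np.vstack([J, m * np.eye(J.shape[1])])
        b = np.concatenate([r, np.zeros(J.shape[1])])
    else:
        A, b = J, r
    # pseudoinverse via SVD with a machine-scale singular value cutoff
    dp, *_ = np.linalg.lstsq(A, -b, rcond=np.finfo(float).eps * max(A.shape))
    return dp


def nglm_fit(residual_fn, p0, tol: float = 1e-4, max_iter: int = 50,
             step: float = 1e-6) -> FitResult:
    """Fit parameters by damped Gauss-Newton iteration.

    Stops when the relative change of ssq over an iteration falls below
    ``tol`` (converged) or after ``max_iter`` Jacobian evaluations; runaway
    damping (m overflowing the problem scale by 1e12) reports
    ``converged=False``.
    """
    p = np.asarray(p0, float).copy()
    if not np.all(np.isfinite(p)):
        raise ValueError("initial parameters must be finite")
    r = np.asarray(residual_fn(p), float)
    ssq = float(r @ r)
    trace = [ssq]
    m = 0.0
    m_scale = None
    for it in range(1, max_iter + 1):
        try:
            J = numeric_jacobian(residual_fn, p, step)
        except ValueError as exc:
            return FitResult(p, ssq, trace, it, False, m, f"Jacobian failed: {exc}")
        if m_scale is None:
            d = np.einsum("ij,ij->j", J, J)  # diag(JᵀJ)
            m_scale = float(np.sqrt(d.mean())) or 1.0
        accepted = False
        while not accepted:
            dp = _solve_step(J, r, m)
            p_new = p + dp
            r_new = np.asarray(residual_fn(p_new), float)
            if np.all(np.isfinite(r_new)):
                ssq_new = float(r_new @ r_new)
            else:
                ssq_new = np.inf
            if ssq_new <= ssq:
                accepted = True
                rel = (ssq - ssq_new) / ssq if ssq > 0 else 0.0
                p, r, ssq = p_new, r_new, ssq_new
                trace.append(ssq)
                m /= 3.0
                if m < 1e-6 * m_scale:
                    m = 0.0
                if rel < tol:
                    return FitResult(p, ssq, trace, it, True, m, "converged")
            else:
                # failed step: raise damping and retry with the same Jacobian
                if ssq > 0 and (ssq_new - ssq) / ssq < tol and np.isfinite(ssq_new):
                    # flat to within tolerance: treat as converged stall
                    return FitResult(p, ssq, trace, it, True, m, "converged (flat)")
                m = m_scale if m == 0.0 else m * 10.0
                if m > 1e12 * m_scale:
                    return FitResult(p, ssq, trace, it, False, m,
                                     "diverged: Marquardt parameter overflow")
    return FitResult(p, ssq, trace, max_iter, False, m, "max_iter reached")
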