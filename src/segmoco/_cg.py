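"""Conjugate gradients for Hermitian positive (semi)definite operators on
complex volumes, with residual history."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CGResult:
    x: np.ndarray
    residuals: list[float]          # ||b - A x_k|| per iteration (incl. start)
    converged: bool
    flagged: bool = False           # NaN / persistent divergence encountered


def cg_hermitian(normal_op, b: np.ndarray, x0: np.ndarray | None = None,
                 n_iters: int = 10, tol: float = 0.0) -> CGResult:
    """Solve ``A x = b`` with A Hermitian PSD given ``normal_op(x) -> A x``.

    Stops after ``n_iters`` iterations or when the relative residual
    ``||b - A x|| / ||b||`` drops below ``tol``.
    """
    b = np.asarray(b)
    x = np.zeros_like(b) if x0 is None else x0.astype(b.dtype, copy=True)
    r = b - normal_op(x) if x.any() else b.copy()
    p = r.copy()
    rs = float(np.vdot(r, r).real)
    bnorm = float(np.linalg.norm(b)) or 1.0
    hist = [np.sqrt(rs)]
    flagged = False
    for _ in range(n_iters):
        if np.sqrt(rs) / bnorm <= tol:
            break
        ap = normal_op(p)
        denom = float(np.vdot(p, ap).real)
        if denom <= 0 or not np.isfinite(denom):
            flagged = denom < 0 or not np.isfinite(denom)
            break
        alpha = rs / denom
        x = x + alpha * p
        r = r - alpha * ap
        rs_new = float(np.vdot(r, r).real)
        if not np.isfinite(rs_new):
            flagged = True
            break
        hist.append(np.sqrt(rs_new))
        p = r + (rs_new / rs) * p
        rs = rs_new
    converged = np.sqrt(rs) / bnorm <= tol if tol > 0 else False
    return CGResult(x=x, residuals=hist, converged=converged, flagged=flagged)
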