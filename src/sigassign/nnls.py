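"""Nonnegative least squares and relative reconstruction error.

The solver is the Lawson-Hanson active-set method (scipy's implementation);
the contract is the KKT conditions of ``min ||v - S a||_2 s.t. a >= 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls as _lawson_hanson

from .exceptions import ValidationError

__all__ = ["NnlsResult", "solve_nnls", "relative_error", "calc_nnls", "nnls_fit"]


@dataclass
class NnlsResult:
    activities_real: np.ndarray
    relative_error: float
    residual_norm_sq: float


def solve_nnls(S: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimize ``||v - S a||_2`` over ``a >= 0`` (Lawson-Hanson active set)."""
    S = np.asarray(S, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if S.ndim != 2 or v.ndim != 1 or S.shape[0] != v.shape[0]:
        raise ValidationError(f"incompatible shapes S{S.shape}, v{v.shape}")
    if not (np.all(np.isfinite(S)) and np.all(np.isfinite(v))):
        raise ValidationError("NNLS inputs must be finite")
    try:
        a, _ = _lawson_hanson(S, v)
    except RuntimeError:
        # rare non-convergence at the default iteration cap
        a, _ = _lawson_hanson(S, v, maxiter=50 * max(S.shape))
    return a


def relative_error(v: np.ndarray, S: np.ndarray, a: np.ndarray) -> float:
    """``||v - S a||^2 / ||v||^2``; defined as 0 for a zero sample."""
    v = np.asarray(v, dtype=np.float64)
    denom = float(v @ v)
    if denom == 0.0:
        return 0.0
    r = v - np.asarray(S, dtype=np.float64) @ np.asarray(a, dtype=np.float64)
    return float(r @ r) / denom


def calc_nnls(v: np.ndarray, S: np.ndarray) -> tuple[float, np.ndarray]:
    """NNLS fit plus its relative error: ``(eps, a)``."""
    if float(np.asarray(v, dtype=np.float64) @ np.asarray(v, dtype=np.float64)) == 0.0:
        return 0.0, np.zeros(np.asarray(S).shape[1])
    a = solve_nnls(S, v)
    return relative_error(v, S, a), a


def nnls_fit(v: np.ndarray, S: np.ndarray) -> NnlsResult:
    eps, a = calc_nnls(v, S)
    v = np.asarray(v, dtype=np.float64)
    return NnlsResult(a, eps, eps * float(v @ v))
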