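"""Orthogonal matching pursuit over a unit-norm dictionary.

Greedy sparse approximation: starting from residual ``r = y``, repeatedly
select the atom with the largest absolute inner product with ``r`` (lowest
index wins ties, for cross-platform determinism), refit *all* selected
coefficients by ordinary least squares on the support, and update
``r = y - D[:, support] @ coeffs``.  Iteration stops when the residual norm
falls below ``tol * ||y||`` (relative by default; a flag switches to an
absolute threshold) or when ``k_max`` atoms have been selected.

After each refit the residual is orthogonal to every selected atom, so the
residual norm never increases and no atom is ever selected twice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List

import numpy as np

logger = logging.getLogger(__name__)

#: residuals at relative machine-precision level terminate the pursuit even
#: when tol == 0: further refits on an exactly-represented signal only churn
#: numerically rank-deficient supports.
_EPS_FLOOR = 1e-12

#: condition-number guard for the support submatrix; beyond this the pursuit
#: returns the current code with a warning instead of an unstable refit.
_COND_MAX = 1e12


@dataclass
class SparseCode:
    """Result of one pursuit: selected atoms, their coefficients, and the
    final residual norm.  ``support`` is in order of selection;
    ``coefficients`` solve the least-squares problem on that support.
    ``residual_trace`` records the residual norm after each iteration."""

    support: List[int]
    coefficients: np.ndarray
    residual_norm: float
    n_iterations: int
    residual_trace: List[float] = field(default_factory=list)


def omp(
    y: np.ndarray,
    D: np.ndarray,
    k_max: int = 8,
    tol: float = 1e-3,
    relative_tol: bool = True,
    normalize: bool = False,
) -> SparseCode:
    """Sparse-code ``y`` against dictionary ``D`` (columns = unit-norm atoms).

    Parameters
    ----------
    y : vector, length q
    D : ndarray, q x M, unit-norm columns (checked to 1e-9 unless
        ``normalize`` is set, in which case columns are normalized on entry)
    k_max : maximum number of atoms; ``k_max = 0`` (or ``y = 0``) returns an
        empty support with residual ``y``
    tol : stopping threshold on the residual Euclidean norm, relative to
        ``||y||`` by default
    """
    y = np.asarray(y, dtype=float).ravel()
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != y.size:
        raise ValueError(f"dictionary shape {D.shape} incompatible with signal length {y.size}")
    q, M = D.shape
    if k_max > min(q, M):
        raise ValueError(f"k_max {k_max} exceeds min(q, M) = {min(q, M)}")
    norms = np.linalg.norm(D, axis=0)
    if normalize:
        if np.any(norms == 0):
            raise ValueError("cannot normalize a dictionary with zero-norm columns")
        D = D / norms
    elif not np.allclose(norms, 1.0, atol=1e-9):
        raise ValueError(
            "dictionary columns are not unit-norm (pass normalize=True to fix on entry)"
        )

    y_norm = np.linalg.norm(y)
    threshold = tol * y_norm if relative_tol else tol
    support: List[int] = []
    coeffs = np.empty(0)
    r = y.copy()
    r_norm = y_norm
    trace: List[float] = []

    if k_max == 0 or y_norm == 0.0:
        return SparseCode(support, coeffs, float(r_norm), 0, trace)

    available = np.ones(M, dtype=bool)
    while len(support) < k_max and r_norm > threshold and r_norm > _EPS_FLOOR * y_norm:
        corr = np.abs(D.T @ r)
        corr[~available] = -1.0
        j = int(np.argmax(corr))  # argmax returns the lowest index on ties
        sub = D[:, support + [j]]
        if len(support) >= 1:
            cond = np.linalg.cond(sub)
            if cond > _COND_MAX:
                logger.warning(
                    "omp: support submatrix numerically rank-deficient "
                    "(cond %.3g) after %d atoms; returning current code",
                    cond, len(support),
                )
                break
        support.append(j)
        available[j] = False
        coeffs, *_ = np.linalg.lstsq(sub, y, rcond=None)
        r = y - sub @ coeffs
        r_norm = float(np.linalg.norm(r))
        trace.append(r_norm)

    return SparseCode(support, np.asarray(coeffs), float(r_norm), len(support), trace)
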