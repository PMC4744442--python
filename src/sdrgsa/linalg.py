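"""Symmetric-matrix powers via eigendecomposition.

Used for the pooled-covariance inverse square root in standardization and for
the within-slice covariance square roots inside the V-type statistics.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidInputError, SingularMatrixError

#: Eigenvalues below RANK_TOL times the largest eigenvalue are treated as zero
#: when an inverse square root is requested.
RANK_TOL = 1e-10

#: Largest tolerated relative asymmetry |M - M^T|.
SYM_TOL = 1e-10


def _check_symmetric(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise InvalidInputError(f"expected a square matrix, got shape {M.shape}")
    scale = max(1.0, float(np.abs(M).max(initial=0.0)))
    if float(np.abs(M - M.T).max(initial=0.0)) > SYM_TOL * scale:
        raise InvalidInputError("matrix is not symmetric within tolerance")
    return M


def sym_matrix_power(M: np.ndarray, exponent: float) -> np.ndarray:
    """Return the symmetric PSD square root or inverse square root of ``M``.

    Parameters
    ----------
    M
        Symmetric positive semi-definite ``p x p`` matrix.  Small negative
        eigenvalues arising from round-off are clipped at zero.
    exponent
        Either ``+0.5`` (square root) or ``-0.5`` (inverse square root).

    Raises
    ------
    InvalidInputError
        If ``M`` is not symmetric or the exponent is unsupported.
    SingularMatrixError
        If ``exponent == -0.5`` and ``M`` is numerically rank deficient
        (eigenvalues below ``RANK_TOL`` times the largest are treated as zero).
    """
    M = _check_symmetric(M)
    if exponent not in (0.5, -0.5):
        raise InvalidInputError(f"unsupported exponent {exponent!r}; use +0.5 or -0.5")
    w, U = np.linalg.eigh(M)
    w = np.clip(w, 0.0, None)
    if exponent == -0.5:
        cutoff = RANK_TOL * max(w[-1], 0.0)
        deficient = int(np.sum(w <= cutoff))
        if deficient > 0:
            rank = M.shape[0] - deficient
            raise SingularMatrixError(
                f"matrix of size {M.shape[0]} has numerical rank {rank}; "
                "inverse square root undefined (consider shrinkage "
                "standardization or the unstandardized T*/V* statistics)"
            )
        d = w ** -0.5
    else:
        d = np.sqrt(w)
    R = (U * d) @ U.T
    return 0.5 * (R + R.T)  # re-symmetrize round-off
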