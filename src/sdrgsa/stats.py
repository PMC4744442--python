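"""SAVE-type test statistics for gene set analysis.

The null hypothesis of no association between a gene set X and a phenotype Y
is the statement that the central dimension-reduction subspace of Y | X has
dimension zero.  After standardizing X to Z and slicing the sample on Y, that
null is tested through the sliced-average-variance-estimation kernel: the
weighted squared Frobenius deviation of the within-slice covariance of Z from
its pooled covariance,

    T = sum_s  p_s * tr(Sigma_{Z|s} - I_p)^2 ,

which decomposes gene-wise as T = sum_i T_i.  A mean-augmented variant

    V = sum_s  p_s * [ tr{ (Sigma_{Z|s}^{1/2} - I_p)^2 } + ||Zbar_s||^2 ]

puts extra weight on between-slice mean shifts.  T* and V* are the analogues
computed on centered but unstandardized data, with the pooled sample
covariance of X taking the place of the identity; they remain usable when the
pooled covariance is singular (p >= n).
"""

from __future__ import annotations

import numpy as np
from sklearn.covariance import ledoit_wolf

from .exceptions import ContractViolationError, InvalidInputError, SingularMatrixError
from .linalg import sym_matrix_power
from .types import ExpressionMatrix, SliceMoments, SlicePartition, StandardizedMatrix

#: Pooled covariance may deviate from its nominal value by at most this much
#: (max-norm) before a statistic refuses the input.
POOLED_TOL = 1e-6

#: Within-slice covariance eigenvalues below -PSD_TOL (relative) are treated
#: as genuine PSD violations rather than round-off.
PSD_TOL = 1e-10


def pooled_covariance(X: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Sample covariance of the rows of ``X`` (divisor ``n - ddof``)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    return Xc.T @ Xc / (n - ddof)


def standardize(
    X: ExpressionMatrix | np.ndarray,
    mode: str = "exact",
    ddof: int = 0,
) -> StandardizedMatrix:
    """Affine-standardize the expression block.

    Parameters
    ----------
    X
        Expression block, samples by genes.
    mode
        ``exact``     Z_(i) = Sigma_X^{-1/2} (X_(i) - Xbar); requires the
                      pooled covariance to be numerically nonsingular
                      (in practice n > p).
        ``shrinkage`` Ledoit-Wolf shrunk covariance in place of Sigma_X;
                      the shrinkage target keeps it positive definite, so
                      this works for p >= n.
        ``identity``  centering only (input to the T*/V* statistics).
        ``auto``      ``exact`` when possible, else ``shrinkage``.
    ddof
        Covariance divisor is ``n - ddof``; the default 0 is the
        maximum-likelihood convention, under which a single slice holding the
        whole sample reproduces the pooled covariance exactly.

    Raises
    ------
    SingularMatrixError
        In ``exact`` mode when the pooled covariance is rank deficient.
    """
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    n, p = V.shape
    center = V.mean(axis=0)
    Xc = V - center

    if mode not in ("exact", "shrinkage", "identity", "auto"):
        raise InvalidInputError(f"unknown standardization mode {mode!r}")

    if mode == "identity":
        return StandardizedMatrix(Xc, np.eye(p), center, "identity", ddof)

    S = Xc.T @ Xc / (n - ddof)
    if mode in ("exact", "auto"):
        try:
            W = sym_matrix_power(S, -0.5)
            return StandardizedMatrix(Xc @ W, W, center, "exact", ddof)
        except SingularMatrixError:
            if mode == "exact":
                raise
            # auto: fall through to shrinkage

    if ddof == 0:
        S_shrunk, _ = ledoit_wolf(V, assume_centered=False)
    else:
        # ledoit_wolf targets the ML covariance; redo the convex combination
        # with the n - ddof base covariance but keep the analytic intensity.
        _, intensity = ledoit_wolf(V, assume_centered=False)
        mu = np.trace(S) / p
        S_shrunk = (1.0 - intensity) * S + intensity * mu * np.eye(p)
    W = sym_matrix_power(S_shrunk, -0.5)
    return StandardizedMatrix(Xc @ W, W, center, "shrinkage", ddof)


def slice_moments(Z: StandardizedMatrix, part: SlicePartition) -> SliceMoments:
    """Per-slice means and covariances of the (standardized) data.

    The within-slice covariance is centered at the slice mean and uses the
    same divisor convention (``n_s - ddof``) as the pooled covariance, so a
    single slice containing the whole sample reproduces the pooled moments.
    """
    Zv = Z.values
    n, p = Zv.shape
    if len(part.labels) != n:
        raise InvalidInputError(
            f"partition labels length {len(part.labels)} != {n} samples"
        )
    H = part.H
    means = np.empty((H, p))
    covs = np.empty((H, p, p))
    for s in range(1, H + 1):
        rows = Zv[part.labels == s]
        ns = rows.shape[0]
        if ns < 2:
            raise InvalidInputError(f"slice {s} has {ns} sample(s); need >= 2")
        m = rows.mean(axis=0)
        A = rows - m
        means[s - 1] = m
        covs[s - 1] = A.T @ A / (ns - Z.ddof)
    if Z.mode == "identity":
        pooled = pooled_covariance(Zv, ddof=Z.ddof)
    else:
        pooled = np.eye(p)
    return SliceMoments(means, covs, pooled, part.proportions, mode=Z.mode)


def _require_pooled_identity(m: SliceMoments, statistic: str) -> None:
    p = m.n_genes
    if float(np.abs(m.pooled_cov - np.eye(p)).max()) > POOLED_TOL:
        raise ContractViolationError(
            f"{statistic} expects standardized moments (pooled covariance "
            f"= identity); got mode {m.mode!r} — use the *_star statistic"
        )


def _require_identity_mode(m: SliceMoments, statistic: str) -> None:
    if m.mode != "identity":
        raise ContractViolationError(
            f"{statistic} expects centered-but-unstandardized moments "
            f"(mode 'identity'); got mode {m.mode!r}"
        )


def _t_core(m: SliceMoments) -> tuple[float, np.ndarray]:
    """T = sum_s p_s ||C_s - pooled||_F^2 with its gene-wise row sums."""
    D = m.covariances - m.pooled_cov[None, :, :]
    per_gene = np.einsum("s,sij->i", m.proportions, D**2)
    return float(per_gene.sum()), per_gene


def _slice_sqrt_eigvals(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a within-slice covariance with PSD repair."""
    w, U = np.linalg.eigh(0.5 * (C + C.T))
    floor = -PSD_TOL * max(1.0, float(w[-1]))
    if w[0] < floor:
        raise InvalidInputError(
            f"within-slice covariance has eigenvalue {w[0]:.3e}; "
            "not PSD beyond round-off"
        )
    return np.clip(w, 0.0, None), U


def statistic_T(m: SliceMoments) -> tuple[float, np.ndarray]:
    """Marginal-dimension (SAVE) statistic T with per-gene contributions.

    Returns ``(T, T_i)`` where ``T_i`` sums, over slices and partner genes,
    the squared deviations of gene i's within-slice variances/covariances
    from the pooled values; ``sum_i T_i == T``.
    """
    _require_pooled_identity(m, "statistic_T")
    return _t_core(m)


def statistic_T_star(m: SliceMoments) -> tuple[float, np.ndarray]:
    """Unstandardized variant T*: pooled sample covariance replaces I_p."""
    _require_identity_mode(m, "statistic_T_star")
    return _t_core(m)


def _v_core(m: SliceMoments, pooled_sqrt: np.ndarray) -> float:
    total = 0.0
    for s in range(m.H):
        w, U = _slice_sqrt_eigvals(m.covariances[s])
        root = (U * np.sqrt(w)) @ U.T
        D = root - pooled_sqrt
        total += m.proportions[s] * (
            float(np.sum(D * D)) + float(m.means[s] @ m.means[s])
        )
    return total


def statistic_V(m: SliceMoments) -> float:
    """Mean-augmented statistic V.

    Adds the squared within-slice mean ``||Zbar_s||^2`` to the square-rooted
    covariance deviation ``tr{(Sigma_{Z|s}^{1/2} - I_p)^2}``, recovering
    sensitivity to between-slice mean shifts that T can miss.
    """
    _require_pooled_identity(m, "statistic_V")
    return _v_core(m, np.eye(m.n_genes))


def statistic_V_star(m: SliceMoments) -> float:
    """Unstandardized variant V*: pooled square root and mean replace I and 0."""
    _require_identity_mode(m, "statistic_V_star")
    return _v_core(m, sym_matrix_power(m.pooled_cov, 0.5))


STATISTICS = ("T", "V", "T_star", "V_star")

#: Statistics computed on centered-but-unstandardized data.
UNSTANDARDIZED = frozenset({"T_star", "V_star"})


def compute_statistic(
    name: str, m: SliceMoments
) -> tuple[float, np.ndarray | None]:
    """Dispatch by statistic name; per-gene vector is None for V-type."""
    if name == "T":
        return statistic_T(m)
    if name == "V":
        return statistic_V(m), None
    if name == "T_star":
        return statistic_T_star(m)
    if name == "V_star":
        return statistic_V_star(m), None
    raise InvalidInputError(f"unknown statistic {name!r}; choose from {STATISTICS}")
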