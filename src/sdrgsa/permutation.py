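"""Permutation significance for the SAVE-type statistics.

The phenotype labels are randomly permuted B times and the statistic is
recomputed for each permuted dataset; the p-value is the add-one estimator
(1 + #{replicates >= observed}) / (B + 1), so it is never zero and ties count
against the null.  Standardization depends on X only, so the transform is
computed once and reused across replicates; permuting labels preserves slice
sizes, so each replicate simply reassigns which samples fall in which slice.

Per-gene significance for the T-type statistics is read off the same
replicates: each observed T_i is compared with its own permutation stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import stats as _stats
from .exceptions import InvalidInputError
from .slicing import make_partition
from .types import ExpressionMatrix, GsaResult, Phenotype, SlicePartition

log = logging.getLogger(__name__)


@dataclass
class PermutationConfig:
    """Knobs for one permutation test."""

    n_permutations: int = 1000
    seed: int = 0
    statistic_name: str = "T"
    standardize: str = "auto"  # exact | shrinkage | auto; ignored for */star
    ddof: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise InvalidInputError("need at least 1 permutation")
        if self.statistic_name not in _stats.STATISTICS:
            raise InvalidInputError(
                f"unknown statistic {self.statistic_name!r}; "
                f"choose from {_stats.STATISTICS}"
            )
        if self.n_permutations < 99:
            log.warning(
                "only %d permutations; reported p-values are coarse "
                "(resolution %.3f)",
                self.n_permutations,
                1.0 / (self.n_permutations + 1),
            )


def _slice_index_blocks(part: SlicePartition) -> list[np.ndarray]:
    return [np.flatnonzero(part.labels == s) for s in range(1, part.H + 1)]


def _stats_for_index_blocks(
    Z: np.ndarray,
    blocks: list[np.ndarray],
    proportions: np.ndarray,
    pooled: np.ndarray,
    pooled_is_identity: bool,
    pooled_sqrt: np.ndarray | None,
    name: str,
    ddof: int,
) -> tuple[float, np.ndarray | None]:
    """Compute one statistic given explicit per-slice sample indices.

    Fast path used inside the permutation loop.  For V with an identity
    reference the square-rooted covariance trace is obtained from the
    singular values of the centered slice block (the p - min(n_s, p)
    structurally zero eigenvalues each contribute (0 - 1)^2 = 1), which is
    much cheaper than an eigendecomposition of the p x p covariance when
    p >> n_s.
    """
    p = Z.shape[1]
    total = 0.0
    per_gene = np.zeros(p) if name in ("T", "T_star") else None
    for w, idx in zip(proportions, blocks):
        rows = Z[idx]
        ns = rows.shape[0]
        A = rows - rows.mean(axis=0)
        if name in ("T", "T_star"):
            C = A.T @ A / (ns - ddof)
            D = C - pooled
            g = np.einsum("ij,ij->i", D, D)
            per_gene += w * g
            total += w * float(g.sum())
        elif name == "V" and pooled_is_identity:
            sv = np.linalg.svd(A, compute_uv=False)
            lam = sv**2 / (ns - ddof)
            tr_term = float(np.sum((np.sqrt(lam) - 1.0) ** 2)) + (p - len(lam))
            mbar = rows.mean(axis=0)
            total += w * (tr_term + float(mbar @ mbar))
        else:  # V_star, or V with a non-identity reference
            C = A.T @ A / (ns - ddof)
            wv, U = _stats._slice_sqrt_eigvals(C)
            root = (U * np.sqrt(wv)) @ U.T
            D = root - pooled_sqrt
            mbar = rows.mean(axis=0)
            total += w * (float(np.sum(D * D)) + float(mbar @ mbar))
    return total, per_gene


def permutation_test(
    X: ExpressionMatrix,
    y: Phenotype,
    cfg: PermutationConfig,
    slices: int | str | None = None,
) -> GsaResult:
    """Permutation test of association between a gene-set block and a phenotype.

    Parameters
    ----------
    X, y
        Expression block (samples x genes) and per-sample phenotype; sample
        order must already be aligned.
    cfg
        Statistic, permutation count, seed, standardization mode.
    slices
        Slice specification for continuous phenotypes (int, ``"auto"``, or
        None for the default H=2); ignored for categorical phenotypes.

    Returns
    -------
    GsaResult
        Observed statistic, permutation p-value, and — for the T-type
        statistics — per-gene contributions, fractions, and per-gene
        permutation p-values from the same replicates.
    """
    if len(y) != X.n_samples:
        raise InvalidInputError(
            f"phenotype length {len(y)} != {X.n_samples} samples"
        )
    part = make_partition(y, slices)
    name = cfg.statistic_name
    mode = "identity" if name in _stats.UNSTANDARDIZED else cfg.standardize
    Zs = _stats.standardize(X, mode=mode, ddof=cfg.ddof)

    m = _stats.slice_moments(Zs, part)
    observed, obs_gene = _stats.compute_statistic(name, m)

    pooled = m.pooled_cov
    pooled_is_identity = Zs.mode != "identity"
    pooled_sqrt = None
    if name == "V_star":
        from .linalg import sym_matrix_power

        pooled_sqrt = sym_matrix_power(pooled, 0.5)

    n = X.n_samples
    sizes = [int(c) for c in part.counts]
    offsets = np.cumsum([0] + sizes)
    B = cfg.n_permutations
    rng = np.random.default_rng(cfg.seed)
    # pre-generate all sample orders so results are independent of chunking
    orders = rng.permuted(np.tile(np.arange(n), (B, 1)), axis=1)

    perm_stats = np.empty(B)
    perm_gene = np.empty((B, X.n_genes)) if obs_gene is not None else None
    for b in range(B):
        order = orders[b]
        blocks = [
            order[offsets[s] : offsets[s + 1]] for s in range(part.H)
        ]
        t, g = _stats_for_index_blocks(
            Zs.values, blocks, part.proportions, pooled,
            pooled_is_identity, pooled_sqrt, name, cfg.ddof,
        )
        perm_stats[b] = t
        if perm_gene is not None:
            perm_gene[b] = g

    p_value = (1 + int(np.sum(perm_stats >= observed))) / (B + 1)

    gene_fracs = gene_p = None
    if obs_gene is not None:
        total = obs_gene.sum()
        gene_fracs = obs_gene / total if total > 0 else np.full_like(obs_gene, 1.0 / len(obs_gene))
        gene_p = (1 + np.sum(perm_gene >= obs_gene[None, :], axis=0)) / (B + 1)

    return GsaResult(
        statistic_name=name,
        statistic=float(observed),
        p_value=float(p_value),
        n_permutations=B,
        seed=cfg.seed,
        gene_contributions=obs_gene,
        gene_fractions=gene_fracs,
        gene_p_values=gene_p,
        gene_ids=X.gene_ids,
        mode=Zs.mode,
        H=part.H,
    )
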