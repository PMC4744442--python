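"""Core data containers.

The pipeline is: an :class:`ExpressionMatrix` (the gene-set block X, samples
by genes) is affine-standardized to a :class:`StandardizedMatrix` Z; the
phenotype is discretized into a :class:`SlicePartition`; per-slice first and
second moments are collected in :class:`SliceMoments`; the SAVE-type test
statistics and their permutation p-values are reported in a
:class:`GsaResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .exceptions import InvalidInputError


@dataclass
class ExpressionMatrix:
    """Expression block of one gene set: ``values`` is n_samples x p_genes."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, p = self.values.shape
        if n < 2:
            raise InvalidInputError(f"need at least 2 samples, got {n}")
        if p < 1:
            raise InvalidInputError("need at least 1 gene")
        if len(self.gene_ids) != p:
            raise InvalidInputError(f"{len(self.gene_ids)} gene ids for {p} columns")
        if len(self.sample_ids) != n:
            raise InvalidInputError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.gene_ids)) != p:
            raise InvalidInputError("gene ids are not unique")
        if len(set(self.sample_ids)) != n:
            raise InvalidInputError("sample ids are not unique")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            cells = ", ".join(
                f"(sample {self.sample_ids[i]}, gene {self.gene_ids[j]})"
                for i, j in bad[:5]
            )
            raise InvalidInputError(
                f"{len(bad)} missing/non-finite entries, e.g. {cells}; "
                "impute or drop upstream"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Extract the sub-block for ``gene_ids`` (order preserved)."""
        index = {g: j for j, g in enumerate(self.gene_ids)}
        try:
            cols = [index[g] for g in gene_ids]
        except KeyError as e:
            raise InvalidInputError(f"gene {e.args[0]!r} not in matrix") from None
        return ExpressionMatrix(self.values[:, cols], list(gene_ids), self.sample_ids)


@dataclass
class Phenotype:
    """Per-sample phenotype: categorical labels or real values."""

    values: np.ndarray
    kind: str  # "categorical" | "continuous"
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise InvalidInputError(f"unknown phenotype kind {self.kind!r}")
        if self.kind == "continuous":
            self.values = np.asarray(self.values, dtype=float)
            if not np.all(np.isfinite(self.values)):
                raise InvalidInputError("continuous phenotype has missing values")
        else:
            self.values = np.asarray(self.values)
            if len(np.unique(self.values)) < 2:
                raise InvalidInputError("categorical phenotype needs >= 2 levels")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class StandardizedMatrix:
    """Z = transform @ (X - center), rows are Z_(i).

    ``mode`` records how the transform was obtained: ``exact`` (inverse square
    root of the pooled sample covariance, so Z has identity pooled
    covariance), ``shrinkage`` (inverse square root of a Ledoit-Wolf shrunk
    covariance, always defined even when p >= n), or ``identity`` (centering
    only; used by the unstandardized T*/V* statistics).
    """

    values: np.ndarray
    transform: np.ndarray
    center: np.ndarray
    mode: str
    ddof: int = 0

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class SlicePartition:
    """Slice label per sample; labels take values in 1..H."""

    labels: np.ndarray
    H: int
    proportions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        counts = np.bincount(self.labels, minlength=self.H + 1)[1:]
        if self.H < 1 or len(counts) != self.H or np.any(counts == 0):
            raise InvalidInputError("every slice 1..H must be nonempty")
        if np.any(counts < 2):
            s = int(np.argmin(counts)) + 1
            raise InvalidInputError(
                f"slice {s} has {counts[s - 1]} sample(s); need >= 2 per slice"
            )
        n = len(self.labels)
        # exact rational proportions n_s/n, cast to float for arithmetic
        fracs = [Fraction(int(c), n) for c in counts]
        assert sum(fracs) == 1
        self.proportions = np.array([float(f) for f in fracs])
        self.counts = counts

    @property
    def n_samples(self) -> int:
        return len(self.labels)


@dataclass
class SliceMoments:
    """Per-slice mean vectors and covariance matrices of the standardized data.

    ``means[s-1]`` is the slice-s mean of Z (equivalently X̄_s - X̄ in identity
    mode); ``covariances[s-1]`` is the within-slice covariance, computed with
    the same divisor convention as the pooled covariance.  ``pooled_cov`` is
    the reference matrix the statistics deviate from: I_p after (exact or
    shrinkage) standardization, the pooled sample covariance of X otherwise.
    """

    means: np.ndarray  # H x p
    covariances: np.ndarray  # H x p x p
    pooled_cov: np.ndarray  # p x p
    proportions: np.ndarray  # H
    mode: str = "exact"

    @property
    def H(self) -> int:
        return self.means.shape[0]

    @property
    def n_genes(self) -> int:
        return self.means.shape[1]


@dataclass
class GsaResult:
    """Outcome of one permutation test on one gene set."""

    statistic_name: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    gene_contributions: np.ndarray | None = None  # T_i, only for T / T*
    gene_fractions: np.ndarray | None = None  # T_i / T
    gene_p_values: np.ndarray | None = None
    gene_ids: list[str] | None = None
    mode: str | None = None  # standardization actually used
    H: int | None = None
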