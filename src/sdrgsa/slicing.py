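"""Phenotype slicing.

Categorical phenotypes slice naturally (one slice per level).  Continuous
phenotypes are discretized monotonically: samples are ranked on the phenotype
and cut into H contiguous, as-equal-as-possible groups, which makes the
partition invariant under any strictly increasing transform of the phenotype.
"""

from __future__ import annotations

import logging

import numpy as np

from .exceptions import DegenerateSliceError, InvalidInputError
from .types import Phenotype, SlicePartition

log = logging.getLogger(__name__)


def slice_categorical(y: Phenotype) -> SlicePartition:
    """One slice per distinct level, in sorted level order."""
    if y.kind != "categorical":
        raise InvalidInputError("slice_categorical needs a categorical phenotype")
    levels, labels0 = np.unique(y.values, return_inverse=True)
    counts = np.bincount(labels0)
    for lev, c in zip(levels, counts):
        if c < 2:
            raise DegenerateSliceError(
                f"phenotype level {lev!r} has {c} sample(s); need >= 2"
            )
    return SlicePartition(labels0 + 1, H=len(levels))


def slice_continuous(y: Phenotype, H: int) -> SlicePartition:
    """Rank-based partition into ``H`` near-equal slices.

    Slice 1 holds the smallest phenotype values.  Slice sizes differ by at
    most one (any remainder goes to the lowest slices).  Ties are ordered by
    original sample index before cutting, so the result is deterministic; a
    tie group straddling a slice boundary is allowed but logged.
    """
    if y.kind != "continuous":
        raise InvalidInputError("slice_continuous needs a continuous phenotype")
    n = len(y)
    if H < 2:
        raise InvalidInputError(f"need H >= 2 slices, got {H}")
    if H > n // 2:
        raise InvalidInputError(
            f"too many slices: H={H} leaves a slice below 2 samples (n={n})"
        )
    order = np.argsort(y.values, kind="stable")
    labels = np.empty(n, dtype=int)
    for s, chunk in enumerate(np.array_split(order, H), start=1):
        labels[chunk] = s
    # warn when a slice boundary falls inside a group of tied values
    sorted_vals = np.asarray(y.values)[order]
    bounds = np.cumsum([len(c) for c in np.array_split(order, H)])[:-1]
    for b in bounds:
        if sorted_vals[b - 1] == sorted_vals[b]:
            log.warning(
                "slice boundary falls inside tied phenotype value %r; "
                "ties broken by sample order",
                sorted_vals[b],
            )
    return SlicePartition(labels, H=H)


def default_slice_count(n: int) -> int:
    """Rule-of-thumb slice count for continuous phenotypes: ~0.1 n, min 2."""
    return max(2, round(0.1 * n))


def make_partition(y: Phenotype, slices: int | str | None = None) -> SlicePartition:
    """Build a partition from a phenotype and a slice specification.

    ``slices`` is ignored for categorical phenotypes (natural slicing).  For
    continuous phenotypes it is an integer H, ``"auto"`` (the 0.1 n rule), or
    None (the default H=2, which keeps slices well-filled at genomic sample
    sizes).
    """
    if y.kind == "categorical":
        return slice_categorical(y)
    if slices is None:
        H = 2
    elif slices == "auto":
        H = default_slice_count(len(y))
    else:
        H = int(slices)
    return slice_continuous(y, H)
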