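"""File I/O, gene-set collections, and the per-collection analysis driver.

Formats are the plain-text standards of the field: a delimited expression
matrix with an identifier column (genes in rows by default, the microarray
convention), a two-column (sample_id, value) phenotype table, and GMT gene
set collections as distributed by MSigDB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, ParseError
from .permutation import PermutationConfig, permutation_test
from .types import ExpressionMatrix, Phenotype

log = logging.getLogger(__name__)


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(
    path: str | Path,
    samples_in_rows: bool = False,
    on_duplicate_gene: str = "error",  # or "first"
) -> ExpressionMatrix:
    """Read a delimited expression matrix with a header row and an id column.

    Genes are expected in rows (flip with ``samples_in_rows``).  Missing or
    non-numeric cells raise :class:`ParseError` naming the offending row and
    column; duplicated gene ids are an error unless ``on_duplicate_gene`` is
    ``"first"``.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if samples_in_rows:
        df = df.T
    # now: genes in rows, samples in columns
    bad = df.isna()
    if bad.to_numpy().any():
        cells = [
            f"(gene {df.index[i]}, sample {df.columns[j]})"
            for i, j in zip(*np.nonzero(bad.to_numpy()))
        ]
        raise ParseError(
            f"{len(cells)} empty/missing cell(s) in {path}: " + ", ".join(cells[:10])
        )
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                i = int(np.flatnonzero(coerced.isna().to_numpy())[0])
                raise ParseError(
                    f"non-numeric entry {df.iloc[i, j]!r} at "
                    f"(gene {df.index[i]}, sample {col}) in {path}"
                ) from None
        raise
    gene_ids = [str(g) for g in df.index]
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        if on_duplicate_gene == "first":
            keep = ~pd.Index(gene_ids).duplicated(keep="first")
            log.warning("keeping first occurrence of duplicated gene ids: %s", dupes)
            values = values[keep]
            gene_ids = [g for g, k in zip(gene_ids, keep) if k]
        else:
            raise InvalidInputError(
                f"duplicated gene ids in {path}: {dupes[:10]} "
                "(pass on_duplicate_gene='first' to keep first occurrences)"
            )
    return ExpressionMatrix(values.T, gene_ids, [str(s) for s in df.columns])


def write_expression(
    expr: ExpressionMatrix, path: str | Path, samples_in_rows: bool = False
) -> None:
    """Write an expression matrix (genes in rows by default)."""
    df = pd.DataFrame(expr.values.T, index=expr.gene_ids, columns=expr.sample_ids)
    if samples_in_rows:
        df = df.T
    df.to_csv(path, sep=_sep_for(path))


# ---------------------------------------------------------------------------
# phenotypes


def infer_phenotype_kind(values: pd.Series) -> str:
    """Categorical when non-numeric, or integer-valued with <= 10 levels."""
    numeric = pd.to_numeric(values, errors="coerce")
    if numeric.isna().any():
        return "categorical"
    v = numeric.to_numpy(dtype=float)
    if np.allclose(v, np.round(v)) and len(np.unique(v)) <= 10:
        return "categorical"
    return "continuous"


def read_phenotype(path: str | Path, kind: str | None = None) -> Phenotype:
    """Read a two-column (sample_id, value) phenotype table.

    The phenotype kind is inferred unless given; the inference is logged.
    """
    df = pd.read_csv(path, sep=_sep_for(path), header=0, dtype={0: str})
    if df.shape[1] != 2:
        raise ParseError(
            f"phenotype file {path} must have exactly 2 columns "
            f"(sample_id, value); found {df.shape[1]}"
        )
    sample_ids = [str(s) for s in df.iloc[:, 0]]
    if len(set(sample_ids)) != len(sample_ids):
        raise InvalidInputError(f"duplicated sample ids in {path}")
    col = df.iloc[:, 1]
    if col.isna().any():
        i = int(np.flatnonzero(col.isna().to_numpy())[0])
        raise ParseError(f"missing phenotype value for sample {sample_ids[i]} in {path}")
    if kind is None:
        kind = infer_phenotype_kind(col)
        log.info("phenotype kind inferred as %r from %s", kind, path)
    if kind == "continuous":
        values = pd.to_numeric(col).to_numpy(dtype=float)
    else:
        values = col.astype(str).to_numpy()
    return Phenotype(values, kind, sample_ids=sample_ids)


def write_phenotype(y: Phenotype, path: str | Path) -> None:
    ids = y.sample_ids or [f"s{i + 1}" for i in range(len(y))]
    pd.DataFrame({"sample_id": ids, "phenotype": y.values}).to_csv(
        path, sep=_sep_for(path), index=False
    )


# ---------------------------------------------------------------------------
# gene sets


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise InvalidInputError("gene set names are not unique")
        for s in self.sets:
            if not s.genes:
                raise InvalidInputError(f"gene set {s.name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT collection (name TAB description TAB gene ids), keeping file order.

    Duplicate gene ids within a set are removed (first occurrence kept) with
    a logged warning.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "need name, description, and at least one gene"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                log.warning(
                    "%s:%d: set %r has %d duplicated gene id(s); deduplicated",
                    path, lineno, name, len(genes) - len(unique),
                )
            sets.append(GeneSet(name, desc, unique))
    return GeneSetCollection(sets)


def filter_sets(
    collection: GeneSetCollection,
    expr: ExpressionMatrix,
    min_size: int = 10,
    max_size: int = 500,
) -> GeneSetCollection:
    """Intersect each set with the measured genes; keep sizes in [min, max].

    The defaults 10 and 500 are the conventional screening bounds for curated
    collections: smaller sets give unstable covariance estimates, larger ones
    are too generic to interpret.
    """
    present = set(expr.gene_ids)
    kept: list[GeneSet] = []
    for s in collection:
        genes = [g for g in s.genes if g in present]
        if min_size <= len(genes) <= max_size:
            kept.append(GeneSet(s.name, s.description, genes))
        else:
            log.info(
                "dropping set %r: %d of %d genes present (bounds [%d, %d])",
                s.name, len(genes), len(s.genes), min_size, max_size,
            )
    return GeneSetCollection(kept)


# ---------------------------------------------------------------------------
# collection-level driver


@dataclass
class GsaReport:
    """Per-set results table, plus an optional per-gene table."""

    table: pd.DataFrame
    gene_table: pd.DataFrame | None = None

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def write_gene_table(self, path: str | Path) -> None:
        if self.gene_table is None:
            raise InvalidInputError("no per-gene table was computed")
        self.gene_table.to_csv(path, sep="\t", index=False)


def _align(expr: ExpressionMatrix, y: Phenotype) -> tuple[ExpressionMatrix, Phenotype]:
    """Join expression and phenotype on sample id (order-insensitive)."""
    if y.sample_ids is None:
        if len(y) != expr.n_samples:
            raise InvalidInputError(
                f"phenotype length {len(y)} != {expr.n_samples} samples "
                "and carries no sample ids to join on"
            )
        return expr, y
    pos = {s: i for i, s in enumerate(y.sample_ids)}
    missing = [s for s in expr.sample_ids if s not in pos]
    extra = [s for s in y.sample_ids if s not in set(expr.sample_ids)]
    if missing or extra:
        raise InvalidInputError(
            f"sample-id mismatch: {len(missing)} expression sample(s) without "
            f"phenotype {missing[:5]}, {len(extra)} phenotype sample(s) "
            f"without expression {extra[:5]}"
        )
    order = [pos[s] for s in expr.sample_ids]
    return expr, Phenotype(y.values[order], y.kind, sample_ids=list(expr.sample_ids))


def default_statistic(kind: str) -> str:
    """T for categorical phenotypes (coexpression signal), V for continuous."""
    return "T" if kind == "categorical" else "V"


def run_gsa(
    expr: ExpressionMatrix,
    y: Phenotype,
    collection: GeneSetCollection,
    statistic: str = "auto",
    slices: int | str | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    min_size: int = 10,
    max_size: int = 500,
    standardize: str = "auto",
    gene_level: bool = False,
    bh_adjust: bool = False,
) -> GsaReport:
    """Screen a gene-set collection against a phenotype.

    Every surviving set (after presence filtering) is tested against the
    same permutation stream (the same reshufflings of sample labels), which
    keeps the report reproducible and makes the p-value invariant under a
    reordering of a set's genes.  With ``bh_adjust`` a
    Benjamini-Hochberg column is appended (an extension beyond the raw
    per-set p-values reported by default).
    """
    expr, y = _align(expr, y)
    surviving = filter_sets(collection, expr, min_size, max_size)
    if len(surviving) == 0:
        raise InvalidInputError(
            "no gene sets survive filtering against the expression matrix"
        )
    stat_name = default_statistic(y.kind) if statistic == "auto" else statistic

    rows = []
    gene_rows = []
    perm_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % 2**31)
    orig_sizes = {s.name: len(s.genes) for s in collection}
    for gs in surviving:
        sub = expr.subset_genes(gs.genes)
        cfg = PermutationConfig(
            n_permutations=n_permutations,
            seed=perm_seed,
            statistic_name=stat_name,
            standardize=standardize,
        )
        res = permutation_test(sub, y, cfg, slices=slices)
        log.info(
            "set %s: %d genes, statistic %s=%.4g, p=%.4g (mode %s, H=%d)",
            gs.name, len(gs.genes), stat_name, res.statistic, res.p_value,
            res.mode, res.H,
        )
        rows.append(
            dict(
                set_name=gs.name,
                set_size=orig_sizes[gs.name],
                genes_found=len(gs.genes),
                statistic_name=stat_name,
                statistic=res.statistic,
                p_value=res.p_value,
            )
        )
        if gene_level and res.gene_contributions is not None:
            for g, ti, fr, gp in zip(
                gs.genes, res.gene_contributions, res.gene_fractions,
                res.gene_p_values,
            ):
                gene_rows.append(
                    dict(set_name=gs.name, gene_id=g, T_i=ti, fraction=fr, gene_p=gp)
                )

    table = pd.DataFrame(rows)
    if bh_adjust:
        from scipy.stats import false_discovery_control

        table["p_value_bh"] = false_discovery_control(table["p_value"], method="bh")
    gene_table = pd.DataFrame(gene_rows) if gene_level and gene_rows else None
    return GsaReport(table, gene_table)
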