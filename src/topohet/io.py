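"""Expression-matrix, sample-metadata and gene-set (GMT) input/output.

File formats
------------
Expression
    Tab-separated text; first row = sample identifiers, first column =
    gene identifiers, body = log2-scale expression values.  Inputs are
    assumed already normalised (e.g. quantile- or RPKM-normalised and
    log2 transformed); no normalisation is performed here.
Metadata
    Two-column CSV ``sample_id,group`` with a header row.  Exactly two
    distinct group labels of equal size are required.
Gene sets
    Standard GMT: ``set_name<TAB>description<TAB>gene1<TAB>gene2...``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataFormatError, GroupContractError, IdentifierError

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "GeneSet",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "read_gmt",
    "write_gmt",
    "split_by_group",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise IdentifierError(f"duplicated {what} identifier {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2-scale expression values.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique gene identifiers, one per row.
    sample_ids : sequence of str
        Unique sample identifiers, one per column.
    values : ndarray of shape (n_genes, n_samples)
        Finite log2-scale expression values.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = tuple(str(g) for g in self.gene_ids)
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataFormatError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataFormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataFormatError(
                "non-finite expression value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        idx = []
        for g in genes:
            if g not in lookup:
                raise IdentifierError(f"unknown gene identifier {g!r}")
            idx.append(lookup[g])
        return np.asarray(idx, dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` (kept in the given order)."""
        idx = self.gene_index(genes)
        return ExpressionMatrix(tuple(genes), self.sample_ids, self.values[idx, :])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``samples`` (kept in the given order)."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = [lookup[s] for s in samples]
        except KeyError as exc:
            raise IdentifierError(f"unknown sample identifier {exc.args[0]!r}") from None
        return ExpressionMatrix(self.gene_ids, tuple(samples), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids),
                            columns=list(self.sample_ids))


@dataclass
class SampleMetadata:
    """Assignment of each sample to one of two equal-size groups.

    ``groups`` preserves the order in which labels first appear in the
    assignment, which downstream code uses as the (control, case)
    convention by default.
    """

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        self.assignment = {str(k): str(v) for k, v in self.assignment.items()}
        labels = self.groups
        if len(labels) != 2:
            raise GroupContractError(
                f"expected exactly two group labels, found {len(labels)}: {labels}"
            )
        sizes = [len(self.samples_in(g)) for g in labels]
        if sizes[0] != sizes[1]:
            raise GroupContractError(
                f"groups must have equal size (got {labels[0]!r}: {sizes[0]}, "
                f"{labels[1]!r}: {sizes[1]}); dimension-0 topology depends on "
                "the number of points, so unequal groups are not comparable"
            )

    @property
    def groups(self) -> tuple[str, ...]:
        out: list[str] = []
        for g in self.assignment.values():
            if g not in out:
                out.append(g)
        return tuple(out)

    def samples_in(self, group: str) -> tuple[str, ...]:
        return tuple(s for s, g in self.assignment.items() if g == group)

    def validate_against(self, expr: ExpressionMatrix) -> None:
        meta_samples = set(self.assignment)
        expr_samples = set(expr.sample_ids)
        missing = expr_samples - meta_samples
        extra = meta_samples - expr_samples
        if missing or extra:
            raise IdentifierError(
                f"metadata/matrix sample mismatch: missing from metadata "
                f"{sorted(missing)}, not in matrix {sorted(extra)}"
            )


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """An ordered collection of named gene sets (GMT semantics)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise IdentifierError(f"key {name!r} does not match set name {gs.name!r}")
            if not gs.genes:
                raise DataFormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated genes x samples expression matrix.

    The first row holds sample identifiers, the first column gene
    identifiers; every body cell must be numeric (missing values are
    rejected, not imputed).  Row and column order is preserved.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = tuple(header[1:])
    _check_unique(sample_ids, "sample")
    genes: list[str] = []
    rows: list[list[float]] = []
    with path.open() as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(sample_ids) + 1:
                raise DataFormatError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} fields, "
                    f"got {len(fields)}"
                )
            gene = fields[0]
            vals = []
            for sample, cell in zip(sample_ids, fields[1:]):
                try:
                    v = float(cell)
                except ValueError:
                    raise DataFormatError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} at gene "
                        f"{gene!r}, sample {sample!r}"
                    ) from None
                if not np.isfinite(v):
                    raise DataFormatError(
                        f"{path}:{lineno}: non-finite cell {cell!r} at gene "
                        f"{gene!r}, sample {sample!r}"
                    )
                vals.append(v)
            genes.append(gene)
            rows.append(vals)
    return ExpressionMatrix(tuple(genes), sample_ids, np.asarray(rows, dtype=float))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> Path:
    """Write an expression matrix as TSV with full float precision.

    ``repr`` formatting guarantees a bit-exact read/write round trip.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(expr.sample_ids) + "\n")
        for g, row in zip(expr.gene_ids, expr.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    return path


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a two-column ``sample_id,group`` CSV (with header)."""
    path = Path(path)
    assignment: dict[str, str] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise DataFormatError(f"{path}: expected a 'sample_id,group' header")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 2:
                raise DataFormatError(f"{path}:{lineno}: expected 2 columns")
            sample, group = row[0], row[1]
            if sample in assignment:
                raise IdentifierError(f"{path}:{lineno}: duplicated sample {sample!r}")
            assignment[sample] = group
    return SampleMetadata(assignment)


def write_metadata(meta: SampleMetadata, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "group"])
        for sample, group in meta.assignment.items():
            writer.writerow([sample, group])
    return path


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set collection.

    Duplicate genes within a line are removed (first occurrence kept);
    duplicate set names and lines with fewer than three fields are
    errors.
    """
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise DataFormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise IdentifierError(f"{path}:{lineno}: duplicated set name {name!r}")
            genes = tuple(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = GeneSet(name, desc, genes)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")
    return path


def split_by_group(
    expr: ExpressionMatrix, meta: SampleMetadata
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Split ``expr`` into its two (equal-size) group sub-matrices.

    Returns the groups in ``meta.groups`` order; within each group the
    samples keep their column order from ``expr``, so concatenating the
    outputs in the original column order reproduces the input.
    """
    meta.validate_against(expr)
    g1, g2 = meta.groups
    in_g1 = [s for s in expr.sample_ids if meta.assignment[s] == g1]
    in_g2 = [s for s in expr.sample_ids if meta.assignment[s] == g2]
    return expr.subset_samples(in_g1), expr.subset_samples(in_g2)
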