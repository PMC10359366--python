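"""Gene tables, expression matrices and tissue mappings.

Conventions used throughout the package:

* all genomic coordinates are 0-based, half-open;
* a gene is reduced to its transcription start site (TSS), stored as a
  single point -- for minus-strand genes the input table must already give
  the TSS coordinate, no gene-body inference is performed;
* expression values are non-negative (e.g. RPKM); regression targets are
  ``ln(x + pseudocount)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

STRANDS = ("+", "-")

#: default pseudocount for the log-expression target transform
DEFAULT_PSEUDOCOUNT = 1e-4


@dataclass(frozen=True)
class GeneRecord:
    """A gene reduced to its TSS point.

    Attributes
    ----------
    gene_id : unique identifier within a table
    chrom : chromosome name
    tss : 0-based genomic coordinate of the transcription start site
    strand : '+' or '-'
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise DataError(f"gene {self.gene_id}: negative TSS {self.tss}")
        if self.strand not in STRANDS:
            raise DataError(
                f"gene {self.gene_id}: strand {self.strand!r} not in {STRANDS}"
            )


@dataclass
class ExpressionMatrix:
    """Genes x tissues matrix of non-negative expression values."""

    gene_ids: list[str]
    tissue_names: list[str]
    values: np.ndarray  # shape (n_genes, n_tissues)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.tissue_names)):
            raise DataError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.tissue_names)} tissues"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression matrix contains non-finite values")
        if np.any(self.values < 0):
            raise DataError("expression values must be non-negative")

    def column(self, tissue: str) -> pd.Series:
        """Expression of every gene in one tissue, indexed by gene id."""
        if tissue not in self.tissue_names:
            raise DataError(f"unknown tissue {tissue!r}")
        j = self.tissue_names.index(tissue)
        return pd.Series(self.values[:, j], index=self.gene_ids, name=tissue)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.tissue_names
        )


def _check_unique_ids(ids: Sequence[str]) -> None:
    seen: set[str] = set()
    for gid in ids:
        if gid in seen:
            raise DataError(f"duplicate gene_id {gid!r}")
        seen.add(gid)


def read_gene_table(path: str | Path, format: str = "bed6") -> list[GeneRecord]:
    """Read a gene/TSS table.

    ``bed6`` expects chrom, start, end, name, score, strand with
    ``start`` the TSS point and ``end == start + 1``.  ``tsv`` expects a
    header with columns gene_id, chrom, tss, strand.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "bed6":
        records = []
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 6:
                    raise DataError(
                        f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}"
                    )
                chrom, start_s, end_s, name, _score, strand = fields[:6]
                try:
                    start, end = int(start_s), int(end_s)
                except ValueError:
                    raise DataError(
                        f"{path}:{lineno}: non-integer coordinate "
                        f"({start_s!r}, {end_s!r})"
                    ) from None
                if end != start + 1:
                    raise DataError(
                        f"{path}:{lineno}: TSS interval must be 1 bp "
                        f"(start={start}, end={end})"
                    )
                if strand not in STRANDS:
                    raise DataError(f"{path}:{lineno}: invalid strand {strand!r}")
                records.append(GeneRecord(name, chrom, start, strand))
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        required = {"gene_id", "chrom", "tss", "strand"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"{path}: missing columns {sorted(missing)}")
        if not pd.api.types.is_integer_dtype(df["tss"]):
            raise DataError(f"{path}: non-integer TSS column")
        records = [
            GeneRecord(r.gene_id, r.chrom, int(r.tss), r.strand)
            for r in df.itertuples()
        ]
    else:
        raise DataError(f"unknown gene table format {format!r}")
    _check_unique_ids([g.gene_id for g in records])
    return records


def write_gene_table(
    genes: Iterable[GeneRecord], path: str | Path, format: str = "bed6"
) -> None:
    path = Path(path)
    fmt = format.lower()
    with path.open("w") as fh:
        if fmt == "bed6":
            for g in genes:
                fh.write(f"{g.chrom}\t{g.tss}\t{g.tss + 1}\t{g.gene_id}\t0\t{g.strand}\n")
        elif fmt == "tsv":
            fh.write("gene_id\tchrom\ttss\tstrand\n")
            for g in genes:
                fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\n")
        else:
            raise DataError(f"unknown gene table format {format!r}")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene ids, header tissues).

    Unknown genes are retained; filtering against a gene table happens when
    features and targets are joined.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise DataError(f"{path}: malformed expression matrix: {exc}") from None
    if df.shape[1] == 0:
        raise DataError(f"{path}: expression matrix has no tissue columns")
    if any(str(c).strip() == "" or str(c).startswith("Unnamed:") for c in df.columns):
        raise DataError(f"{path}: empty tissue name in header")
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise DataError(f"{path}: negative expression value")
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        tissue_names=[str(c) for c in df.columns],
        values=values,
    )


def write_expression_matrix(em: ExpressionMatrix, path: str | Path) -> None:
    em.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_tissue_mapping(path: str | Path) -> dict[str, str]:
    """Read a cell-line/experiment -> tissue mapping.

    Accepts ``key=value`` lines or a 2-column TSV; '#' lines are comments.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" in line and "\t" not in line:
                key, _, value = line.partition("=")
            else:
                parts = line.split("\t")
                if len(parts) != 2:
                    raise DataError(f"{path}:{lineno}: expected 2 columns or key=value")
                key, value = parts
            key, value = key.strip(), value.strip()
            if not key or not value:
                raise DataError(f"{path}:{lineno}: empty key or tissue name")
            if key in mapping:
                raise DataError(f"{path}:{lineno}: duplicate mapping for {key!r}")
            mapping[key] = value
    return mapping


def write_tissue_mapping(mapping: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for key, value in mapping.items():
            fh.write(f"{key}\t{value}\n")


def validate_tissue_mapping(mapping: Mapping[str, str], em: ExpressionMatrix) -> None:
    """Every mapped tissue must exist in the expression matrix."""
    known = set(em.tissue_names)
    unknown = {t for t in mapping.values() if t not in known}
    if unknown:
        raise DataError(f"mapped tissues not in expression matrix: {sorted(unknown)}")


def transform_target(x, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """Log-space regression target ``ln(x + pseudocount)``.

    Strictly increasing in ``x``; invertible via
    :func:`inverse_transform_target`.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise DataError("expression values must be non-negative")
    out = np.log(arr + pseudocount)
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def inverse_transform_target(t, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """Invert :func:`transform_target`: ``exp(t) - pseudocount``."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    out = np.exp(np.asarray(t, dtype=float)) - pseudocount
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out
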