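"""Delimited-text I/O for genotype, expression, annotation and eQTL tables.

Conventions: tab-separated UTF-8 text, first row is a header of sample ids,
first column holds marker/gene ids, missing values written as ``NA``.
Genomic coordinates are 1-based base pairs; a gene's position is its
transcription start.  Samples are always matched by id, never by column
order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "EqtlRecord",
    "EqtlTable",
    "read_genotypes",
    "read_expression",
    "read_annotation",
    "read_eqtl_table",
    "write_genotypes",
    "write_expression",
    "write_annotation",
    "write_eqtl_table",
    "align_samples",
]

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"
VALID_GENOTYPES = (1, 2, 3)

EQTL_COLUMNS = [
    "snp_id",
    "gene_id",
    "relevance_bits",
    "mrmr_score",
    "loocv_accuracy",
    "cis_class",
    "distance_bp",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class GenotypeMatrix:
    """Markers x samples integer genotype matrix for an F2 intercross.

    Genotype codes: 1 = homozygous for the first parental allele,
    2 = heterozygous, 3 = homozygous for the second parental allele.
    ``missing`` is a boolean mask aligned with ``values`` (True = no call).
    """

    marker_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]
    positions: Optional[dict[str, tuple[str, int]]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.missing is None:
            self.missing = np.zeros(self.values.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        _check_unique(self.marker_ids, "marker")
        if self.values.shape != (len(self.marker_ids), len(self.sample_ids)):
            raise ValueError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.marker_ids)} markers x {len(self.sample_ids)} samples"
            )
        if self.missing.shape != self.values.shape:
            raise ValueError("missing mask shape must match values")
        observed = self.values[~self.missing]
        bad = ~np.isin(observed, VALID_GENOTYPES)
        if bad.any():
            raise ValueError(
                f"genotype values outside {{1,2,3}}: {np.unique(observed[bad])}"
            )

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class ExpressionMatrix:
    """Genes (or probes) x samples continuous expression matrix."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    positions: Optional[dict[str, tuple[str, int]]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class EqtlRecord:
    snp_id: str
    gene_id: str
    relevance_bits: float
    mrmr_score: float
    loocv_accuracy: float
    cis_class: str  # "cis" | "trans" | "ambiguous"
    distance_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.cis_class not in ("cis", "trans", "ambiguous"):
            raise ValueError(f"invalid cis_class {self.cis_class!r}")
        if not 0.0 <= self.loocv_accuracy <= 1.0:
            raise ValueError("loocv_accuracy must lie in [0, 1]")


@dataclass
class EqtlTable:
    """(SNP, gene) association records; within a SNP, records keep selection order."""

    records: list[EqtlRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        pairs = [(r.snp_id, r.gene_id) for r in self.records]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (snp_id, gene_id) pairs in eQTL table")

    def __len__(self) -> int:
        return len(self.records)

    def pairs(self) -> set[tuple[str, str]]:
        return {(r.snp_id, r.gene_id) for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                r.snp_id,
                r.gene_id,
                r.relevance_bits,
                r.mrmr_score,
                r.loocv_accuracy,
                r.cis_class,
                r.distance_bp,
            )
            for r in self.records
        ]
        df = pd.DataFrame(rows, columns=EQTL_COLUMNS)
        df["distance_bp"] = df["distance_bp"].astype("Int64")
        return df


def _read_table(path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{what} file {path}: no data rows") from None
    if df.shape[0] == 0:
        raise ValueError(f"{what} file {path}: no data rows")
    return df


def read_genotypes(path) -> GenotypeMatrix:
    """Read a markers x samples genotype TSV (header = sample ids).

    Cells must be 1, 2, 3 or the missing token ``NA``.  A numeric cell
    outside {1,2,3} is a hard error naming the offending marker and sample;
    a non-numeric cell other than ``NA`` is treated as missing and counted
    in a log message.
    """
    df = _read_table(path, "genotype")
    marker_ids = [str(m) for m in df.index]
    _check_unique(marker_ids, "marker")
    sample_ids = [str(s) for s in df.columns]
    _check_unique(sample_ids, "sample")
    values = np.zeros(df.shape, dtype=np.int8)
    missing = np.zeros(df.shape, dtype=bool)
    n_unparseable = 0
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            token = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell).strip()
            if token == MISSING_TOKEN or token == "":
                missing[i, j] = True
                continue
            try:
                num = float(token)
            except ValueError:
                missing[i, j] = True
                n_unparseable += 1
                continue
            if num not in VALID_GENOTYPES or not num.is_integer():
                raise ValueError(
                    f"invalid genotype {token!r} at marker {marker_ids[i]!r}, "
                    f"sample {sample_ids[j]!r} (must be 1, 2, 3 or {MISSING_TOKEN})"
                )
            values[i, j] = int(num)
    if n_unparseable:
        logger.warning("read_genotypes(%s): %d unparseable cells set to missing", path, n_unparseable)
    return GenotypeMatrix(marker_ids, sample_ids, values, missing)


def read_expression(path) -> ExpressionMatrix:
    """Read a genes x samples expression TSV; every cell must be numeric."""
    df = _read_table(path, "expression")
    gene_ids = [str(g) for g in df.index]
    _check_unique(gene_ids, "gene")
    sample_ids = [str(s) for s in df.columns]
    _check_unique(sample_ids, "sample")
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"expression file {path}: missing/short cell at data row {i + 1} "
            f"(gene {gene_ids[i]!r}, sample column {j + 1})"
        )
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"expression file {path}: non-numeric cell ({exc})") from None
    return ExpressionMatrix(gene_ids, sample_ids, values)


def read_annotation(path) -> dict[str, tuple[str, int]]:
    """Read an ``id  chrom  pos`` TSV into a mapping id -> (chromosome, position).

    Positions are parsed strictly as plain integers (no thousands
    separators); ids absent from the file are simply unannotated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"annotation file {path}: no data rows") from None
    if df.shape[1] != 3:
        raise ValueError(f"annotation file {path}: expected 3 columns, got {df.shape[1]}")
    out: dict[str, tuple[str, int]] = {}
    for row_no, (ident, chrom, pos) in enumerate(df.itertuples(index=False), start=1):
        ident = str(ident)
        if ident in out:
            raise ValueError(f"annotation file {path}: duplicate id {ident!r}")
        pos_str = str(pos).strip()
        if not (pos_str.isdigit() or (pos_str.startswith("-") and pos_str[1:].isdigit())):
            raise ValueError(
                f"annotation file {path}, row {row_no}: position {pos_str!r} "
                "is not a plain integer"
            )
        out[ident] = (str(chrom), int(pos_str))
    return out


def read_eqtl_table(path) -> EqtlTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"eQTL table not found: {path}")
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if list(df.columns) != EQTL_COLUMNS:
        raise ValueError(f"eQTL table {path}: unexpected columns {list(df.columns)}")
    records = []
    for row in df.itertuples(index=False):
        dist = None if str(row.distance_bp) in (MISSING_TOKEN, "nan", "<NA>") else int(row.distance_bp)
        records.append(
            EqtlRecord(
                snp_id=str(row.snp_id),
                gene_id=str(row.gene_id),
                relevance_bits=float(row.relevance_bits),
                mrmr_score=float(row.mrmr_score),
                loocv_accuracy=float(row.loocv_accuracy),
                cis_class=str(row.cis_class),
                distance_bp=dist,
            )
        )
    return EqtlTable(records)


def _write_matrix(ids, sample_ids, body: pd.DataFrame, path) -> None:
    body.index = pd.Index(ids, name="id")
    body.columns = list(sample_ids)
    body.to_csv(path, sep="\t", na_rep=MISSING_TOKEN)


def write_genotypes(g: GenotypeMatrix, path) -> None:
    vals = g.values.astype(object)
    vals[g.missing] = MISSING_TOKEN
    _write_matrix(g.marker_ids, g.sample_ids, pd.DataFrame(vals), path)


def write_expression(e: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(e.values)
    df.index = pd.Index(e.gene_ids, name="id")
    df.columns = list(e.sample_ids)
    df.to_csv(path, sep="\t", float_format="%.12g")


def write_annotation(positions: Mapping[str, tuple[str, int]], path) -> None:
    df = pd.DataFrame(
        [(i, c, p) for i, (c, p) in positions.items()],
        columns=["id", "chrom", "pos"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_eqtl_table(table: EqtlTable, path) -> None:
    """Write an eQTL table, stably sorted by snp_id (selection order kept within SNP)."""
    df = table.to_frame()
    df = df.sort_values("snp_id", kind="stable")
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN, float_format="%.12g")


def align_samples(
    genotypes: GenotypeMatrix, expression: ExpressionMatrix
) -> tuple[GenotypeMatrix, ExpressionMatrix]:
    """Restrict both matrices to the sorted intersection of their sample ids."""
    shared = sorted(set(genotypes.sample_ids) & set(expression.sample_ids))
    if not shared:
        raise ValueError("genotype and expression matrices share no sample ids")
    gi = [genotypes.sample_ids.index(s) for s in shared]
    ei = [expression.sample_ids.index(s) for s in shared]
    g = GenotypeMatrix(
        list(genotypes.marker_ids),
        shared,
        genotypes.values[:, gi],
        genotypes.missing[:, gi],
        genotypes.positions,
    )
    e = ExpressionMatrix(
        list(expression.gene_ids),
        shared,
        expression.values[:, ei],
        expression.positions,
    )
    return g, e
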