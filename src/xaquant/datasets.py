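"""Core data containers and their on-disk formats.

Two substrates drive every transcriptomic analysis in this package:

* :class:`ExpressionDataset` — a cells × genes expression matrix on an
  FPKM/RPKM-like scale, with per-gene annotation (chromosome, which gene is
  the XIST-like / XACT-like focal lncRNA, lineage markers) and per-cell
  metadata (embryo, developmental stage, sex, lineage).
* :class:`AlleleCountTable` — per-cell reference/alternative read counts at
  heterozygous genomic positions.  Its derived *allelic ratio*
  ``min(ref, alt) / (ref + alt)`` is the minor-allele read fraction that the
  bi-allelic-position statistic thresholds.

On-disk representation is plain text: TSV for metadata and counts, TSV or an
MTX triplet for the matrix (see :func:`write_dataset` / :func:`read_dataset`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

ALLELE_COLUMNS = ["cell_id", "chrom", "pos", "gene", "ref_count", "alt_count"]
CELL_META_COLUMNS = ["cell_id", "embryo_id", "stage", "sex", "lineage"]


class ParseError(ValueError):
    """Malformed on-disk input; message carries the offending line number."""


@dataclass
class ExpressionDataset:
    """Cells × genes expression matrix plus cell and gene metadata.

    Parameters
    ----------
    values
        DataFrame indexed by cell id, columns gene names, nonnegative
        FPKM/RPKM-scale values.
    gene_meta
        DataFrame indexed by gene with columns ``chrom`` (plain string,
        e.g. ``"X"``, ``"7"``), boolean ``is_focal1`` (XIST-like) and
        ``is_focal2`` (XACT-like), and ``marker`` (lineage label or ``""``).
    cell_meta
        DataFrame indexed by cell id with columns ``embryo_id``, ``stage``,
        ``sex`` (``"F"``/``"M"``) and ``lineage`` (``"TE"``, ``"EPI"``,
        ``"PE"`` or ``"none"``).
    """

    values: pd.DataFrame
    gene_meta: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        if not self.values.index.equals(self.cell_meta.index):
            raise ValueError("values rows and cell_meta index must match")
        if not self.values.columns.equals(self.gene_meta.index):
            raise ValueError("values columns and gene_meta index must match")
        if self.cell_meta["stage"].isna().any():
            raise ValueError("every cell must carry a stage label")
        for col in ("is_focal1", "is_focal2"):
            focal = self.gene_meta.index[self.gene_meta[col].astype(bool)]
            if len(focal) and (self.gene_meta.loc[focal, "chrom"] != "X").any():
                raise ValueError(f"{col} genes must be X-linked")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def focal_gene(self, which: int) -> str:
        """Name of focal gene 1 (XIST-like) or 2 (XACT-like)."""
        col = {1: "is_focal1", 2: "is_focal2"}[which]
        hits = self.gene_meta.index[self.gene_meta[col].astype(bool)]
        if len(hits) != 1:
            raise ValueError(f"expected exactly one {col} gene, found {len(hits)}")
        return str(hits[0])


@dataclass
class AlleleCountTable:
    """Per-cell, per-position reference/alternative read counts.

    ``records`` columns: ``cell_id``, ``chrom``, ``pos`` (1-based, VCF
    convention), ``gene``, ``ref_count``, ``alt_count``; an optional
    ``true_biallelic`` column carries simulator ground truth.  The
    ``(cell_id, chrom, pos)`` triple is unique.
    """

    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=ALLELE_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in ALLELE_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"allele table missing columns: {missing}")
        counts = self.records[["ref_count", "alt_count"]]
        if len(self.records):
            arr = counts.to_numpy()
            if not np.issubdtype(arr.dtype, np.integer):
                raise ValueError("ref_count/alt_count must be integers")
            if (arr < 0).any():
                raise ValueError("read counts must be nonnegative")
            if self.records.duplicated(["cell_id", "chrom", "pos"]).any():
                raise ValueError("(cell_id, chrom, pos) must be unique")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def allelic_ratio(self) -> pd.Series:
        """Minor-allele fraction min(ref, alt) / (ref + alt); NaN at depth 0."""
        ref = self.records["ref_count"].to_numpy(dtype=float)
        alt = self.records["alt_count"].to_numpy(dtype=float)
        total = ref + alt
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(total > 0, np.minimum(ref, alt) / total, np.nan)
        return pd.Series(ratio, index=self.records.index, name="allelic_ratio")

    @property
    def depth(self) -> pd.Series:
        return (self.records["ref_count"] + self.records["alt_count"]).rename("depth")


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def write_dataset(
    dataset: ExpressionDataset,
    table: AlleleCountTable | None,
    path: str | Path,
    matrix_format: str = "tsv",
) -> Path:
    """Write a dataset (and optionally an allele table) to a directory.

    Layout: ``expression.tsv`` (genes × cells, header row of cell ids) or an
    MTX triplet (``expression.mtx`` + ``genes.txt`` + ``cells.txt``);
    ``gene_meta.tsv``; ``cell_meta.tsv``; ``allele_counts.tsv``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if matrix_format == "tsv":
        dataset.values.T.to_csv(path / "expression.tsv", sep="\t", index_label="gene")
    elif matrix_format == "mtx":
        mat = scipy.sparse.csr_matrix(dataset.values.T.to_numpy())
        buf = io.BytesIO()
        scipy.io.mmwrite(buf, mat)
        (path / "expression.mtx").write_bytes(buf.getvalue())
        (path / "genes.txt").write_text("\n".join(dataset.values.columns) + "\n")
        (path / "cells.txt").write_text("\n".join(dataset.values.index) + "\n")
    else:
        raise ValueError(f"unknown matrix_format {matrix_format!r}")
    dataset.gene_meta.to_csv(path / "gene_meta.tsv", sep="\t", index_label="gene")
    dataset.cell_meta.to_csv(path / "cell_meta.tsv", sep="\t", index_label="cell_id")
    if table is not None:
        table.records.to_csv(path / "allele_counts.tsv", sep="\t", index=False)
    return path


def read_allele_table(path: str | Path) -> AlleleCountTable:
    """Read an allele-count TSV, reporting the first offending line on error."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ALLELE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: header missing columns {missing}")
    if df.empty:
        empty = pd.DataFrame(columns=df.columns)
        for c in ("pos", "ref_count", "alt_count"):
            empty[c] = empty[c].astype(int)
        return AlleleCountTable(empty)
    for col in ("pos", "ref_count", "alt_count"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != np.floor(numeric))
        if bad.any():
            # +2: one for the header, one for 1-based numbering
            line = int(df.index[bad][0]) + 2
            raise ParseError(f"{path}: line {line}: non-integer {col} value {df[col][bad].iloc[0]!r}")
        df[col] = numeric.astype(int)
    dup = df.duplicated(["cell_id", "chrom", "pos"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ParseError(f"{path}: line {line}: duplicate (cell_id, chrom, pos)")
    if "true_biallelic" in df.columns:
        df["true_biallelic"] = df["true_biallelic"].map(
            {"True": True, "False": False, "1": True, "0": False}
        )
    return AlleleCountTable(df.reset_index(drop=True))


def read_dataset(path: str | Path) -> tuple[ExpressionDataset, AlleleCountTable | None]:
    """Inverse of :func:`write_dataset`; ``read(write(x)) == x``."""
    path = Path(path)
    gene_meta = pd.read_csv(path / "gene_meta.tsv", sep="\t", index_col="gene")
    gene_meta["chrom"] = gene_meta["chrom"].astype(str)
    cell_meta = pd.read_csv(
        path / "cell_meta.tsv", sep="\t", index_col="cell_id", keep_default_na=False
    )
    if (path / "expression.tsv").exists():
        values = pd.read_csv(path / "expression.tsv", sep="\t", index_col="gene").T
        values.index.name = "cell_id"
    elif (path / "expression.mtx").exists():
        mat = scipy.io.mmread(path / "expression.mtx").toarray()
        genes = (path / "genes.txt").read_text().splitlines()
        cells = (path / "cells.txt").read_text().splitlines()
        values = pd.DataFrame(
            mat.T,
            index=pd.Index(cells, name="cell_id"),
            columns=pd.Index(genes, name="gene"),
        )
    else:
        raise ParseError(f"{path}: no expression.tsv or expression.mtx found")
    for col in ("is_focal1", "is_focal2"):
        gene_meta[col] = gene_meta[col].astype(bool)
    if "marker" in gene_meta.columns:
        gene_meta["marker"] = gene_meta["marker"].fillna("")
    dataset = ExpressionDataset(values, gene_meta, cell_meta)
    table = None
    if (path / "allele_counts.tsv").exists():
        table = read_allele_table(path / "allele_counts.tsv")
    return dataset, table


def read_allele_counts_vcf(path: str | Path, gene_field: str = "GENE") -> AlleleCountTable:
    """Import per-sample allele depths (FORMAT/AD) from a VCF.

    Each sample becomes a cell; the first two AD entries are taken as
    ref/alt counts.  The gene annotation is read from the INFO field named
    ``gene_field`` (empty string when absent).
    """
    import pysam  # optional dependency, imported lazily

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            gene = rec.info.get(gene_field, "")
            if isinstance(gene, tuple):
                gene = gene[0]
            for sample_name, sample in rec.samples.items():
                ad = sample.get("AD")
                if ad is None or ad[0] is None:
                    continue
                rows.append(
                    (sample_name, str(rec.chrom), int(rec.pos), str(gene), int(ad[0]), int(ad[1]))
                )
    df = pd.DataFrame(rows, columns=ALLELE_COLUMNS)
    return AlleleCountTable(df)
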