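"""Data model and readers/writers for bulk cohorts, clinical tables,
ligand-receptor databases and annotated single-cell count matrices.

Conventions
-----------
* Bulk expression lives on disk as a genes x patients table (TSV or CSV)
  with gene symbols in the first column and patient ids in the header.
* Clinical tables are CSV/TSV with columns ``patient_id, time, event,
  grade, stage``; ``time`` is overall survival in days.
* Single-cell matrices are MatrixMarket (``.mtx`` plus ``genes.tsv`` /
  ``barcodes.tsv`` sidecars) or dense TSV, oriented cells x genes in
  memory. Cell metadata maps barcode -> cell type and carries the
  patient id and tumor grade.
* Gene matching anywhere in the package is exact and case-sensitive;
  no alias resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

CPM_TOTAL = 1e6


class FormatError(ValueError):
    """An input file does not match the documented layout."""


class EmptyJoinError(ValueError):
    """Joining two inputs on their shared key left zero records."""


class DegenerateSampleError(ValueError):
    """A sample (patient column or cell) carries no counts at all."""


class LRPair(NamedTuple):
    """A directed ligand -> receptor gene couple.

    Direction matters: ``(A, B)`` and ``(B, A)`` are distinct entries.
    """

    ligand: str
    receptor: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.ligand}-{self.receptor}"


@dataclass
class CohortDataset:
    """One bulk cohort: expression matrix plus aligned clinical outcomes.

    ``expression`` is genes x patients. Columns of a CPM-normalized
    matrix each sum to 1e6. ``survival_time`` is in days; ``event`` is 1
    for an observed death and 0 for censoring. ``grade``/``stage`` may
    contain missing values.
    """

    cohort_id: str
    expression: pd.DataFrame
    survival_time: pd.Series
    event: pd.Series
    grade: pd.Series
    stage: pd.Series
    is_cpm: bool = False

    @property
    def patients(self) -> pd.Index:
        return self.expression.columns

    @property
    def n_patients(self) -> int:
        return self.expression.shape[1]

    def cpm(self) -> "CohortDataset":
        """Return a copy whose expression columns are CPM-normalized."""
        if self.is_cpm:
            return self
        return CohortDataset(
            cohort_id=self.cohort_id,
            expression=cpm_normalize(self.expression),
            survival_time=self.survival_time,
            event=self.event,
            grade=self.grade,
            stage=self.stage,
            is_cpm=True,
        )


@dataclass
class SingleCellDataset:
    """One patient's annotated single-cell count matrix.

    ``counts`` is a sparse cells x genes matrix of non-negative integer
    counts; every cell carries exactly one ``cell_type`` label; ``grade``
    is the patient-level pathological tumor grade.
    """

    patient_id: str
    counts: sp.csr_matrix
    genes: pd.Index
    barcodes: pd.Index
    cell_type: pd.Series
    grade: int

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.cell_type.unique())

    def to_anndata(self):  # pragma: no cover - optional convenience
        """Package the dataset as an AnnData object (requires anndata)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame({"cell_type": self.cell_type.values}, index=self.barcodes),
            var=pd.DataFrame(index=self.genes),
        )
        adata.uns["patient_id"] = self.patient_id
        adata.uns["grade"] = self.grade
        return adata


_CLINICAL_REQUIRED = ("patient_id", "time", "event")
_CLINICAL_OPTIONAL = ("grade", "stage")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def cpm_normalize(counts: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Scale every column (sample) to a library size of one million.

    Idempotent. Raises :class:`DegenerateSampleError` naming the first
    sample whose column sums to zero.
    """
    values = counts.values if isinstance(counts, pd.DataFrame) else np.asarray(counts, dtype=float)
    if (values < 0).any():
        raise FormatError("expression counts must be non-negative")
    colsums = values.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        name = counts.columns[zero[0]] if isinstance(counts, pd.DataFrame) else str(zero[0])
        raise DegenerateSampleError(f"sample {name!r} has zero total counts")
    scaled = values * (CPM_TOTAL / colsums)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(scaled, index=counts.index, columns=counts.columns)
    return scaled


def read_cohort(
    expression_path: str | Path,
    clinical_path: str | Path,
    cohort_id: str | None = None,
    already_cpm: bool = False,
) -> CohortDataset:
    """Read one cohort's expression matrix and clinical table.

    Patients are intersected between the two files (inner join on
    patient id); dropped patients and patients with missing survival
    time or event are logged. The expression matrix is returned as read
    (``already_cpm`` only flags it); run :meth:`CohortDataset.cpm` to
    normalize.
    """
    expression_path = Path(expression_path)
    clinical_path = Path(clinical_path)
    expr = pd.read_csv(expression_path, sep=_sep_for(expression_path), index_col=0)
    if expr.shape[1] == 0:
        raise FormatError(f"{expression_path}: no patient columns found")
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)
    if expr.index.has_duplicates:
        raise FormatError(f"{expression_path}: duplicate gene symbols")

    clin = pd.read_csv(clinical_path, sep=_sep_for(clinical_path))
    missing = [c for c in _CLINICAL_REQUIRED if c not in clin.columns]
    if missing:
        raise FormatError(f"{clinical_path}: missing required columns {missing}")
    clin = clin.copy()
    clin["patient_id"] = clin["patient_id"].astype(str)
    if clin["patient_id"].duplicated().any():
        raise FormatError(f"{clinical_path}: duplicate patient ids")
    clin = clin.set_index("patient_id")

    incomplete = clin["time"].isna() | clin["event"].isna()
    if incomplete.any():
        logger.info(
            "cohort %s: dropped %d patients with missing survival time or event",
            cohort_id, int(incomplete.sum()),
        )
        clin = clin.loc[~incomplete]

    shared = expr.columns.intersection(clin.index)
    if len(shared) == 0:
        raise EmptyJoinError("no overlapping patients between expression and clinical tables")
    n_dropped = (expr.shape[1] - len(shared)) + (clin.shape[0] - len(shared))
    if n_dropped:
        logger.info("cohort %s: dropped %d non-overlapping patients", cohort_id, n_dropped)
    expr = expr[shared]
    clin = clin.loc[shared]

    time = clin["time"].astype(float)
    if (time <= 0).any():
        raise FormatError("survival times must be positive")
    event = clin["event"].astype(int)
    if not event.isin((0, 1)).all():
        raise FormatError("event indicator must be 0 or 1")

    grade = clin["grade"] if "grade" in clin.columns else pd.Series(np.nan, index=clin.index)
    stage = clin["stage"] if "stage" in clin.columns else pd.Series(pd.NA, index=clin.index)
    return CohortDataset(
        cohort_id=cohort_id or expression_path.stem,
        expression=expr,
        survival_time=time,
        event=event,
        grade=grade,
        stage=stage,
        is_cpm=already_cpm,
    )


def write_cohort(
    dataset: CohortDataset, expression_path: str | Path, clinical_path: str | Path
) -> None:
    """Write a cohort back to disk in the layout :func:`read_cohort` reads."""
    expression_path = Path(expression_path)
    clinical_path = Path(clinical_path)
    dataset.expression.to_csv(
        expression_path, sep=_sep_for(expression_path), index_label="gene"
    )
    clin = pd.DataFrame(
        {
            "patient_id": dataset.patients,
            "time": dataset.survival_time.values,
            "event": dataset.event.values,
            "grade": dataset.grade.values,
            "stage": dataset.stage.values,
        }
    )
    clin.to_csv(clinical_path, sep=_sep_for(clinical_path), index=False)


def read_lr_database(path: str | Path) -> list[LRPair]:
    """Read a two-column ligand/receptor table into an ordered pair list.

    Duplicate rows are collapsed (keeping first occurrence) with a
    logged warning; direction is preserved, so (A, B) and (B, A) are two
    distinct pairs.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path))
    if table.shape[1] < 2:
        raise FormatError(f"{path}: need two columns (ligand, receptor)")
    if table.shape[0] == 0:
        raise FormatError(f"{path}: empty ligand-receptor table")
    ligands = table.iloc[:, 0].astype(str)
    receptors = table.iloc[:, 1].astype(str)
    if (ligands.str.len() == 0).any() or (receptors.str.len() == 0).any():
        raise FormatError(f"{path}: empty gene symbol in ligand-receptor table")
    pairs: list[LRPair] = []
    seen: set[LRPair] = set()
    n_dup = 0
    for lig, rec in zip(ligands, receptors):
        pair = LRPair(lig, rec)
        if pair in seen:
            n_dup += 1
            continue
        seen.add(pair)
        pairs.append(pair)
    if n_dup:
        logger.warning("%s: collapsed %d duplicate ligand-receptor rows", path, n_dup)
    return pairs


def write_lr_database(pairs: Iterable[LRPair], path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(list(pairs), columns=["ligand", "receptor"]).to_csv(
        path, sep=_sep_for(path), index=False
    )


def match_pairs(
    pairs: Sequence[LRPair], genes: Iterable[str]
) -> tuple[list[LRPair], int]:
    """Keep pairs whose genes both occur in ``genes`` (exact match).

    Returns the retained pairs and the count of excluded pairs.
    """
    gene_set = set(genes)
    kept = [p for p in pairs if p.ligand in gene_set and p.receptor in gene_set]
    n_excluded = len(pairs) - len(kept)
    if n_excluded:
        logger.info("excluded %d pairs with genes absent from the matrix", n_excluded)
    return kept, n_excluded


def read_single_cell(
    matrix_path: str | Path,
    metadata_path: str | Path,
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> SingleCellDataset:
    """Read one patient's single-cell counts with cell-type annotations.

    ``matrix_path`` is either a MatrixMarket file (sidecar ``genes.tsv``
    and ``barcodes.tsv`` next to it, or passed explicitly) or a dense
    TSV with barcodes in the first column and gene symbols in the
    header. ``metadata_path`` is a CSV/TSV with columns ``barcode,
    cell_type, patient_id, grade``. Cells without a metadata row are
    dropped with a logged count.
    """
    matrix_path = Path(matrix_path)
    metadata_path = Path(metadata_path)

    if matrix_path.suffix == ".mtx":
        mat = sp.csr_matrix(scipy.io.mmread(matrix_path))
        genes_path = Path(genes_path) if genes_path else matrix_path.with_name("genes.tsv")
        barcodes_path = (
            Path(barcodes_path) if barcodes_path else matrix_path.with_name("barcodes.tsv")
        )
        genes = pd.Index(pd.read_csv(genes_path, sep="\t", header=None).iloc[:, 0].astype(str))
        barcodes = pd.Index(
            pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].astype(str)
        )
        if mat.shape == (len(genes), len(barcodes)) and len(genes) != len(barcodes):
            mat = sp.csr_matrix(mat.T)  # genes x cells on disk; flip to cells x genes
        if mat.shape != (len(barcodes), len(genes)):
            raise FormatError(
                f"{matrix_path}: matrix shape {mat.shape} does not match "
                f"{len(barcodes)} barcodes x {len(genes)} genes"
            )
    else:
        dense = pd.read_csv(matrix_path, sep=_sep_for(matrix_path), index_col=0)
        genes = pd.Index(dense.columns.astype(str))
        barcodes = pd.Index(dense.index.astype(str))
        mat = sp.csr_matrix(dense.values)

    if mat.data.size and (np.mod(mat.data, 1) != 0).any():
        raise FormatError(f"{matrix_path}: counts must be integers")
    if mat.data.size and (mat.data < 0).any():
        raise FormatError(f"{matrix_path}: counts must be non-negative")
    if genes.has_duplicates:
        raise FormatError(f"{matrix_path}: duplicate gene symbols")

    meta = pd.read_csv(metadata_path, sep=_sep_for(metadata_path))
    for col in ("barcode", "cell_type"):
        if col not in meta.columns:
            raise FormatError(f"{metadata_path}: missing column {col!r}")
    meta = meta.copy()
    meta["barcode"] = meta["barcode"].astype(str)
    meta = meta.set_index("barcode")

    keep = barcodes.isin(meta.index)
    if not keep.any():
        raise EmptyJoinError("no cell barcodes matched the metadata table")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d unannotated cells", matrix_path, n_dropped)
    barcodes = barcodes[keep]
    mat = sp.csr_matrix(mat[np.flatnonzero(keep)])
    meta = meta.loc[barcodes]

    patient_id = str(meta["patient_id"].iloc[0]) if "patient_id" in meta.columns else matrix_path.stem
    grade = int(meta["grade"].iloc[0]) if "grade" in meta.columns else 0
    return SingleCellDataset(
        patient_id=patient_id,
        counts=mat.astype(np.int64),
        genes=genes,
        barcodes=barcodes,
        cell_type=pd.Series(meta["cell_type"].astype(str).values, index=barcodes),
        grade=grade,
    )


def write_single_cell(data: SingleCellDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write one patient's dataset as MTX + sidecars + metadata CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "genes": out_dir / "genes.tsv",
        "barcodes": out_dir / "barcodes.tsv",
        "metadata": out_dir / "metadata.csv",
    }
    scipy.io.mmwrite(paths["matrix"], sp.coo_matrix(data.counts), field="integer")
    pd.Series(data.genes).to_csv(paths["genes"], sep="\t", index=False, header=False)
    pd.Series(data.barcodes).to_csv(paths["barcodes"], sep="\t", index=False, header=False)
    pd.DataFrame(
        {
            "barcode": data.barcodes,
            "cell_type": data.cell_type.values,
            "patient_id": data.patient_id,
            "grade": data.grade,
        }
    ).to_csv(paths["metadata"], index=False)
    return paths
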