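"""Per-patient extraction of cell-type-pair communication edges.

For every ordered (sender, receiver) cell-type pair — autocrine pairs
included — and every ligand-receptor pair, an edge is emitted when the
ligand is detected in at least ``detection_threshold`` of the sender
cells and the receptor in at least that fraction of receiver cells. The
edge weight is the mean-expression product: (mean ligand expression
over ALL sender cells, zeros included) x (mean receptor expression over
all receiver cells). Cells are library-size normalized to 10,000 counts
per cell by default before taking means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import DegenerateSampleError, LRPair, SingleCellDataset, match_pairs

logger = logging.getLogger(__name__)

DEFAULT_DETECTION_THRESHOLD = 0.2
CP10K_TOTAL = 1e4

EDGE_COLUMNS = ["patient_id", "sender", "receiver", "ligand", "receptor", "weight"]


@dataclass
class CellTypeProfile:
    """Per-gene summary of one cell type in one patient."""

    patient_id: str
    cell_type: str
    mean_expression: pd.Series  # mean over the type's cells, zeros included
    detection_fraction: pd.Series  # fraction of cells with raw count > 0
    n_cells: int


@dataclass
class EdgeSet:
    """All communication edges detected for one patient.

    ``edges`` has columns patient_id, sender, receiver, ligand,
    receptor, weight — one row per distinct (sender, receiver, pair)
    triple. ``n_detected`` is the number of such triples;
    ``n_pairs_detected`` the number of distinct ligand-receptor pairs
    detected in any cell-type pair.
    """

    patient_id: str
    edges: pd.DataFrame
    n_detected: int
    n_pairs_detected: int
    n_pairs_skipped: int = 0  # pairs whose genes were absent from the matrix

    def pair_triples(self) -> set[tuple[str, str, LRPair]]:
        return {
            (row.sender, row.receiver, LRPair(row.ligand, row.receptor))
            for row in self.edges.itertuples()
        }


def normalize_cells(
    counts: sp.spmatrix | np.ndarray, cell_norm: str = "cp10k"
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Library-size normalize a cells x genes count matrix.

    ``cell_norm`` is ``cp10k`` (scale each cell to 10,000 total),
    ``cpm`` (to 1e6), or ``none`` (identity). Zero-count cells cannot be
    scaled and are dropped; the returned boolean mask marks kept cells.
    """
    mat = sp.csr_matrix(counts, dtype=float)
    totals = np.asarray(mat.sum(axis=1)).ravel()
    keep = totals > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d zero-count cells", n_dropped)
    mat = sp.csr_matrix(mat[np.flatnonzero(keep)])
    totals = totals[keep]
    if mat.shape[0] == 0:
        raise DegenerateSampleError("all cells have zero total counts")
    if cell_norm == "none":
        return mat, keep
    if cell_norm == "cp10k":
        target = CP10K_TOTAL
    elif cell_norm == "cpm":
        target = 1e6
    else:
        raise ValueError(f"unknown cell_norm {cell_norm!r}")
    scale = sp.diags(target / totals)
    return sp.csr_matrix(scale @ mat), keep


def profile_cell_types(
    data: SingleCellDataset, cell_norm: str = "cp10k"
) -> list[CellTypeProfile]:
    """Summarize each cell type: mean normalized expression per gene
    (zeros included) and the fraction of cells detecting each gene.

    Detection is evaluated on the raw counts (count > 0), so it does
    not depend on the normalization choice.
    """
    normalized, keep = normalize_cells(data.counts, cell_norm=cell_norm)
    labels = data.cell_type.to_numpy()[keep]
    raw = sp.csr_matrix(data.counts[np.flatnonzero(keep)])
    profiles: list[CellTypeProfile] = []
    for cell_type in sorted(pd.unique(labels)):
        idx = np.flatnonzero(labels == cell_type)
        sub = normalized[idx]
        mean = np.asarray(sub.mean(axis=0)).ravel()
        det = np.asarray((raw[idx] > 0).mean(axis=0)).ravel()
        profiles.append(
            CellTypeProfile(
                patient_id=data.patient_id,
                cell_type=str(cell_type),
                mean_expression=pd.Series(mean, index=data.genes),
                detection_fraction=pd.Series(det, index=data.genes),
                n_cells=len(idx),
            )
        )
    return profiles


def extract_edges(
    data: SingleCellDataset,
    pairs: list[LRPair],
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD,
    cell_norm: str = "cp10k",
) -> EdgeSet:
    """Extract all detected (sender, receiver, pair) edges for a patient.

    An edge exists when detection_fraction(ligand, sender) and
    detection_fraction(receptor, receiver) both reach the threshold;
    its weight is the product of the two cell-type mean expressions.
    Pairs whose genes are absent from the gene space are skipped and
    counted.
    """
    if not pairs:
        raise ValueError("empty ligand-receptor pair list")
    usable, n_skipped = match_pairs(pairs, data.genes)

    profiles = profile_cell_types(data, cell_norm=cell_norm)
    types = [p.cell_type for p in profiles]
    mean = np.vstack([p.mean_expression.to_numpy() for p in profiles])
    det = np.vstack([p.detection_fraction.to_numpy() for p in profiles])
    gene_pos = {g: i for i, g in enumerate(data.genes)}
    lig_idx = np.array([gene_pos[p.ligand] for p in usable], dtype=int)
    rec_idx = np.array([gene_pos[p.receptor] for p in usable], dtype=int)

    rows: list[tuple] = []
    if usable:
        lig_mean = mean[:, lig_idx]  # types x pairs
        rec_mean = mean[:, rec_idx]
        lig_ok = det[:, lig_idx] >= detection_threshold
        rec_ok = det[:, rec_idx] >= detection_threshold
        for si, sender in enumerate(types):
            for ri, receiver in enumerate(types):
                hit = np.flatnonzero(lig_ok[si] & rec_ok[ri])
                weights = lig_mean[si, hit] * rec_mean[ri, hit]
                for k, w in zip(hit, weights):
                    rows.append(
                        (
                            data.patient_id,
                            sender,
                            receiver,
                            usable[k].ligand,
                            usable[k].receptor,
                            float(w),
                        )
                    )
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    n_pairs_detected = (
        edges[["ligand", "receptor"]].drop_duplicates().shape[0] if len(edges) else 0
    )
    return EdgeSet(
        patient_id=data.patient_id,
        edges=edges,
        n_detected=len(edges),
        n_pairs_detected=n_pairs_detected,
        n_pairs_skipped=n_skipped,
    )


def extract_edges_all(
    datasets: list[SingleCellDataset],
    pairs: list[LRPair],
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD,
    cell_norm: str = "cp10k",
) -> list[EdgeSet]:
    """Run :func:`extract_edges` for every patient."""
    return [
        extract_edges(d, pairs, detection_threshold=detection_threshold, cell_norm=cell_norm)
        for d in datasets
    ]


def edges_table(edge_sets: list[EdgeSet]) -> pd.DataFrame:
    """Concatenate per-patient edge tables into one long table."""
    frames = [es.edges for es in edge_sets if len(es.edges)]
    if not frames:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def edge_sets_from_table(table: pd.DataFrame) -> list[EdgeSet]:
    """Rebuild per-patient edge sets from a long edge table (the TSV
    written by the CLI), so downstream stages can re-run from disk."""
    missing = [c for c in EDGE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"edge table missing columns {missing}")
    out = []
    for pid, sub in table.groupby("patient_id", sort=True):
        sub = sub.reset_index(drop=True)
        out.append(
            EdgeSet(
                patient_id=str(pid),
                edges=sub,
                n_detected=len(sub),
                n_pairs_detected=sub[["ligand", "receptor"]].drop_duplicates().shape[0],
            )
        )
    return out
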