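"""Adjusted enrichment of screened pairs per cell-type pair, patient
support counting, and the grade-dependent third-quartile weight screen.

The patient-wise adjusted enrichment of a screened pair set within one
(sender, receiver) cell-type pair is

    (m_p / n_p) * (N / M)

where m_p is the number of screened pairs detected there for patient p,
n_p the number of all database pairs detected there, M the screened-set
size and N the database size. It is the detection rate of screened
pairs relative to their database frequency: 1 means the screened set is
detected at exactly its background rate. The table value is the mean of
patient-wise values over patients with n_p > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .edges import EdgeSet
from .io import LRPair

logger = logging.getLogger(__name__)


@dataclass
class GradeScreenResult:
    """Outcome of the grade-restricted quartile screen.

    ``selected`` has columns sender, receiver, ligand, receptor, weight
    (mean across target-grade patients in which the edge was detected);
    every selected edge had a weight strictly above ``q3_threshold`` in
    at least one target-grade patient.
    """

    selected: pd.DataFrame
    q3_threshold: float
    target_grade: int
    n_target_patients: int


def _pair_key(df: pd.DataFrame) -> pd.Series:
    return pd.Series(list(zip(df["ligand"], df["receptor"])), index=df.index)


def _screened_keys(screened) -> set[tuple[str, str]]:
    return {(p.ligand, p.receptor) for p in screened}


def adjusted_enrichment(
    edge_sets: list[EdgeSet],
    screened,
    all_pairs: list[LRPair],
    per_cell_type_pair: bool = True,
) -> pd.DataFrame:
    """Adjusted enrichment of a screened pair set, per cell-type pair.

    Returns one row per observed (sender, receiver) with columns
    ``adjusted_enrichment`` (mean of patient-wise values), ``n_patients``
    (patients with n_p > 0 there) and ``per_patient`` (the patient-wise
    values, ordered by patient id). With ``per_cell_type_pair=False`` a
    single whole-patient row (sender = receiver = "*") is produced, with
    m_p and n_p counted over distinct pairs regardless of cell types.
    """
    screened = set(screened)
    if not screened or not all_pairs:
        raise ValueError("screened set and pair database must be non-empty")
    if not screened <= set(all_pairs):
        raise ValueError("screened pairs must be a subset of the database")
    m_size = len(screened)
    n_size = len(all_pairs)
    factor = n_size / m_size
    keys = _screened_keys(screened)

    per_patient: dict[tuple[str, str], dict[str, float]] = {}
    for es in edge_sets:
        edges = es.edges
        if not len(edges):
            continue
        is_screened = _pair_key(edges).isin(keys)
        if per_cell_type_pair:
            grouped = edges.assign(hit=is_screened).groupby(
                ["sender", "receiver"], sort=True
            )["hit"]
            for (sender, receiver), hits in grouped:
                n_p = len(hits)
                m_p = int(hits.sum())
                per_patient.setdefault((sender, receiver), {})[es.patient_id] = (
                    m_p / n_p
                ) * factor
        else:
            distinct = edges.assign(hit=is_screened)[["ligand", "receptor", "hit"]].drop_duplicates(
                ["ligand", "receptor"]
            )
            n_p = len(distinct)
            m_p = int(distinct["hit"].sum())
            per_patient.setdefault(("*", "*"), {})[es.patient_id] = (m_p / n_p) * factor

    rows = []
    for (sender, receiver), values in sorted(per_patient.items()):
        ordered = [values[pid] for pid in sorted(values)]
        rows.append(
            {
                "sender": sender,
                "receiver": receiver,
                "adjusted_enrichment": float(np.mean(ordered)),
                "n_patients": len(ordered),
                "per_patient": ordered,
            }
        )
    return pd.DataFrame(rows)


def enrichment_difference(
    table_poor: pd.DataFrame, table_good: pd.DataFrame
) -> pd.DataFrame:
    """Per-cell-type-pair difference: poor minus good adjusted enrichment.

    The two tables must cover the same (sender, receiver) pairs.
    """
    left = table_poor.set_index(["sender", "receiver"])["adjusted_enrichment"]
    right = table_good.set_index(["sender", "receiver"])["adjusted_enrichment"]
    if not left.index.equals(right.index):
        if set(left.index) != set(right.index):
            raise ValueError("cell-type-pair sets differ between the two tables")
        right = right.reindex(left.index)
    out = left.to_frame("poor")
    out["good"] = right
    out["difference"] = out["poor"] - out["good"]
    return out.reset_index()


def patient_support(
    edge_sets: list[EdgeSet],
    screened,
    cell_types: list[str] | None = None,
) -> pd.DataFrame:
    """Count, for each (sender, receiver, screened pair), the patients
    whose edge set contains that interaction.

    Rows are emitted for the full grid of cell-type pairs x screened
    pairs, including zero counts. ``cell_types`` defaults to every type
    appearing as sender or receiver in any edge set.
    """
    if not edge_sets:
        raise ValueError("need at least one patient")
    screened = sorted(set(screened))
    if cell_types is None:
        seen: set[str] = set()
        for es in edge_sets:
            seen.update(es.edges["sender"].unique())
            seen.update(es.edges["receiver"].unique())
        cell_types = sorted(seen)

    counts: dict[tuple[str, str, LRPair], int] = {}
    keys = _screened_keys(screened)
    for es in edge_sets:
        edges = es.edges
        if not len(edges):
            continue
        hits = edges[_pair_key(edges).isin(keys)]
        for row in hits.drop_duplicates(["sender", "receiver", "ligand", "receptor"]).itertuples():
            triple = (row.sender, row.receiver, LRPair(row.ligand, row.receptor))
            counts[triple] = counts.get(triple, 0) + 1

    rows = []
    for sender in cell_types:
        for receiver in cell_types:
            for pair in screened:
                rows.append(
                    {
                        "sender": sender,
                        "receiver": receiver,
                        "ligand": pair.ligand,
                        "receptor": pair.receptor,
                        "n_patients": counts.get((sender, receiver, pair), 0),
                    }
                )
    return pd.DataFrame(rows)


def grade_quartile_screen(
    edge_sets: list[EdgeSet],
    grades: dict[str, int],
    screened,
    target_grade: int = 4,
    quartile_scope: str = "global",
) -> GradeScreenResult:
    """Select screened-pair edges whose weight in target-grade patients
    exceeds the third quartile of ALL detected edge weights there.

    The quartile pool spans every detected edge occurrence (screened or
    not) across all target-grade patients and, with the default
    ``global`` scope, all cell-type pairs jointly; Q3 uses the
    linear-interpolation (type 7) quantile. Selection is strict (>).
    Selected triples are reported with their mean weight across the
    target-grade patients in which they were detected.
    """
    target_sets = [es for es in edge_sets if grades.get(es.patient_id) == target_grade]
    if not target_sets:
        raise ValueError(f"no patients at grade {target_grade}")
    pool_frames = [es.edges for es in target_sets if len(es.edges)]
    if not pool_frames:
        raise ValueError(f"no edges detected in grade-{target_grade} patients")
    pool = pd.concat(pool_frames, ignore_index=True)
    if quartile_scope not in ("global", "per_cell_type_pair"):
        raise ValueError("quartile_scope must be 'global' or 'per_cell_type_pair'")

    keys = _screened_keys(set(screened))
    candidates = pool[_pair_key(pool).isin(keys)]

    if quartile_scope == "global":
        q3 = float(np.quantile(pool["weight"].to_numpy(), 0.75))
        passing = candidates[candidates["weight"] > q3]
    else:
        q3_by = pool.groupby(["sender", "receiver"])["weight"].quantile(0.75)
        thresh = candidates.set_index(["sender", "receiver"]).index.map(q3_by)
        passing = candidates[candidates["weight"].to_numpy() > thresh.to_numpy()]
        q3 = float(np.quantile(pool["weight"].to_numpy(), 0.75))  # reported reference

    key_cols = ["sender", "receiver", "ligand", "receptor"]
    selected_keys = passing[key_cols].drop_duplicates()
    means = candidates.groupby(key_cols, sort=True)["weight"].mean().rename("weight")
    selected = (
        selected_keys.merge(means.reset_index(), on=key_cols, how="left")
        .sort_values(key_cols)
        .reset_index(drop=True)
    )
    return GradeScreenResult(
        selected=selected,
        q3_threshold=q3,
        target_grade=target_grade,
        n_target_patients=len(target_sets),
    )


def grade_weight_tables(
    edge_sets: list[EdgeSet], grades: dict[str, int], screened
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format weight tables for heatmap plotting.

    Returns (per-patient, per-grade-mean) tables of screened-pair edge
    weights, each keyed by (sender, receiver, ligand, receptor).
    """
    keys = _screened_keys(set(screened))
    frames = []
    for es in edge_sets:
        edges = es.edges
        if not len(edges):
            continue
        hits = edges[_pair_key(edges).isin(keys)].copy()
        hits["grade"] = grades.get(es.patient_id)
        frames.append(hits)
    if not frames:
        empty = pd.DataFrame(
            columns=["patient_id", "sender", "receiver", "ligand", "receptor", "weight", "grade"]
        )
        return empty, empty.drop(columns=["patient_id"])
    per_patient = pd.concat(frames, ignore_index=True)
    per_grade = (
        per_patient.groupby(["grade", "sender", "receiver", "ligand", "receptor"], sort=True)[
            "weight"
        ]
        .mean()
        .reset_index()
    )
    return per_patient, per_grade
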