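"""Synthetic bulk cohorts and single-cell datasets with planted truth.

The generator emulates the study design the pipeline targets at
miniature scale: several bulk RNA-seq cohorts with overall-survival
outcomes whose hazard depends on planted ligand-receptor pair scores,
and a handful of single-cell patients with cell-type-specific
ligand/receptor expression, heterogeneous cell-type compositions and
patient-level tumor grades. Every output is a pure function of
(config, seed), so recovery tests can compare pipeline output against
the planted truth exactly.

Bulk model
----------
Gene counts are negative-binomial with per-gene log-normal means and a
common dispersion. Each planted pair occupies a dedicated ligand and
receptor gene, so pair scores are independent across planted pairs and
effects do not confound one another. A patient's death hazard is

    baseline_hazard * exp(effect_log_hr * (#poor pairs high - #good pairs high))

where "high" means the patient's CPM score for that pair is at or above
the cohort median — the same stratum the screen later reconstructs, so
the planted high-vs-low hazard ratio per pair is exp(effect_log_hr) by
design. Survival times are exponential; censoring is independent
Uniform(0, c) with c solved numerically to hit the requested censoring
fraction.

Single-cell model
-----------------
Per patient, cell-type counts follow a Dirichlet-multinomial around
typical tumor-microenvironment proportions (epithelial tumor cells
dominant, fibroblasts and macrophages next). Gene counts are
negative-binomial around library-size-scaled log-normal gene weights.
A planted edge (sender, receiver, pair, intensity) multiplies the
ligand's mean in the sender type and the receptor's mean in the
receiver type by ``intensity``; grade-restricted planted edges are
active only in patients of that grade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CohortDataset, LRPair, SingleCellDataset, cpm_normalize

logger = logging.getLogger(__name__)

DEFAULT_SEED = 20210904
DEFAULT_CELL_TYPES = ("CAF", "DC", "EMT", "Endo", "ETC", "TAM", "TIL")
# typical tumor-microenvironment composition: tumor epithelium dominant,
# fibroblasts and macrophages next, dendritic cells rare
_BASE_PROPORTIONS = {
    "ETC": 0.30, "CAF": 0.20, "TAM": 0.15, "TIL": 0.12,
    "EMT": 0.10, "Endo": 0.08, "DC": 0.05,
}
_MIN_CELLS_PER_TYPE = 5


class ConfigError(ValueError):
    """A synthetic configuration violates its invariants."""


@dataclass(frozen=True)
class PlantedEdge:
    """One planted communication edge.

    ``pair_index`` refers to the generated ligand-receptor database
    (poor pairs occupy the first indices, good pairs the next block).
    ``grade_only`` restricts the edge to patients of that grade (None =
    active in every patient).
    """

    sender: str
    receiver: str
    pair_index: int
    intensity: float
    grade_only: int | None = None


@dataclass
class SyntheticConfig:
    """Full specification of one synthetic study."""

    n_cohorts: int = 3
    n_patients_per_cohort: int = 150
    n_genes: int = 2000
    n_lr_pairs: int = 500
    n_poor_planted: int = 20
    n_good_planted: int = 20
    effect_log_hr: float = 0.7
    censoring_rate: float = 0.2
    baseline_hazard: float = 1.0 / 1000.0  # per day; median survival ~693 days
    dispersion: float = 0.3
    n_sc_patients: int = 10
    cells_per_patient: int = 600
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    planted_edges: tuple[PlantedEdge, ...] | None = None  # None -> default layout
    grade_assignment: tuple[int, ...] | None = None  # per sc patient; None -> default
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.n_genes < 2 * self.n_lr_pairs:
            raise ConfigError("n_genes must be at least 2 * n_lr_pairs")
        if self.n_poor_planted + self.n_good_planted > self.n_lr_pairs:
            raise ConfigError("planted pairs exceed the pair database size")
        for name in ("n_cohorts", "n_patients_per_cohort", "n_genes", "n_lr_pairs",
                     "n_sc_patients", "cells_per_patient"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ConfigError("censoring_rate must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        if self.grade_assignment is not None and len(self.grade_assignment) != self.n_sc_patients:
            raise ConfigError("grade_assignment length must equal n_sc_patients")
        for edge in self.planted_edges or ():
            if edge.sender not in self.cell_types or edge.receiver not in self.cell_types:
                raise ConfigError(f"planted edge references unknown cell type: {edge}")
            if not 0 <= edge.pair_index < self.n_lr_pairs:
                raise ConfigError(f"planted edge references unknown pair: {edge}")

    def resolved_grades(self) -> tuple[int, ...]:
        if self.grade_assignment is not None:
            return tuple(self.grade_assignment)
        # grades 2-4 with grade 4 well represented
        base = [2, 2, 2, 3, 3, 3, 3, 4, 4, 4]
        reps = -(-self.n_sc_patients // len(base))
        return tuple((base * reps)[: self.n_sc_patients])

    def resolved_planted_edges(self) -> tuple[PlantedEdge, ...]:
        """Default layout: the first ten poor pairs signal ETC -> TAM in
        every patient; the next five only in grade-4 patients."""
        if self.planted_edges is not None:
            return tuple(self.planted_edges)
        n_always = min(10, self.n_poor_planted)
        n_grade4 = min(5, self.n_poor_planted - n_always)
        edges = [
            PlantedEdge("ETC", "TAM", i, intensity=5.0) for i in range(n_always)
        ] + [
            PlantedEdge("ETC", "TAM", n_always + i, intensity=5.0, grade_only=4)
            for i in range(n_grade4)
        ]
        return tuple(edges)


@dataclass
class SyntheticTruth:
    """What was planted, for recovery assertions."""

    poor_pairs: set[LRPair]
    good_pairs: set[LRPair]
    edge_truth: set[tuple[str, str, LRPair]]
    grade4_edge_truth: set[tuple[str, str, LRPair]]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def gene_universe(config: SyntheticConfig) -> tuple[list[str], list[LRPair]]:
    """Deterministic gene names and pair database.

    Pair i couples ligand gene ``L{i:04d}`` with receptor gene
    ``R{i:04d}``; remaining genes are background ``B{j:04d}``.
    """
    pairs = [LRPair(f"L{i:04d}", f"R{i:04d}") for i in range(config.n_lr_pairs)]
    genes = [p.ligand for p in pairs] + [p.receptor for p in pairs]
    genes += [f"B{j:04d}" for j in range(config.n_genes - len(genes))]
    return genes, pairs


def make_truth(config: SyntheticConfig) -> SyntheticTruth:
    _, pairs = gene_universe(config)
    poor = set(pairs[: config.n_poor_planted])
    good = set(pairs[config.n_poor_planted : config.n_poor_planted + config.n_good_planted])
    edge_truth = set()
    grade4 = set()
    for edge in config.resolved_planted_edges():
        triple = (edge.sender, edge.receiver, pairs[edge.pair_index])
        edge_truth.add(triple)
        if edge.grade_only == 4:
            grade4.add(triple)
    return SyntheticTruth(
        poor_pairs=poor, good_pairs=good, edge_truth=edge_truth, grade4_edge_truth=grade4
    )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws via the gamma-Poisson mixture."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def _censoring_horizon(times: np.ndarray, rate: float) -> float:
    """Solve for c so Uniform(0, c) censoring hits ``rate`` on average.

    P(C < T) = E[min(T, c)] / c, evaluated on the empirical sample and
    bisected; decreasing in c.
    """
    if rate <= 0:
        return float("inf")

    def frac(c: float) -> float:
        return float(np.minimum(times, c).mean()) / c

    lo, hi = 1e-9, float(times.max()) * 1e3
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) > rate:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def gen_bulk_cohorts(
    config: SyntheticConfig,
) -> tuple[list[CohortDataset], SyntheticTruth]:
    """Generate the bulk cohorts with planted survival effects."""
    truth = make_truth(config)
    genes, pairs = gene_universe(config)
    planted = pairs[: config.n_poor_planted + config.n_good_planted]
    signs = np.array(
        [1.0] * config.n_poor_planted + [-1.0] * config.n_good_planted
    )

    base_rng = _rng(config.seed, 0)
    # per-gene log-normal means, shared across cohorts
    gene_mean = np.exp(base_rng.normal(loc=3.0, scale=1.2, size=config.n_genes))

    cohorts: list[CohortDataset] = []
    for c in range(config.n_cohorts):
        rng = _rng(config.seed, 100 + c)
        n = config.n_patients_per_cohort
        counts = _nb_counts(
            rng, np.tile(gene_mean[:, None], (1, n)), config.dispersion
        ).astype(float)
        expr = pd.DataFrame(
            counts, index=genes, columns=[f"C{c}_P{i:04d}" for i in range(n)]
        )
        cpm = cpm_normalize(expr)

        # planted high/low strata drive the hazard
        z = np.zeros(n)
        for sign, pair in zip(signs, planted):
            score = cpm.loc[pair.ligand].to_numpy() + cpm.loc[pair.receptor].to_numpy()
            high = score >= np.median(score)
            z += sign * high
        hazard = config.baseline_hazard * np.exp(config.effect_log_hr * z)
        t_true = rng.exponential(1.0 / hazard)
        horizon = _censoring_horizon(t_true, config.censoring_rate)
        if np.isfinite(horizon):
            censor = rng.uniform(0.0, horizon, size=n)
            time = np.minimum(t_true, censor)
            event = (t_true <= censor).astype(int)
        else:
            time = t_true
            event = np.ones(n, dtype=int)
        time = np.maximum(time, 1e-6)

        cohorts.append(
            CohortDataset(
                cohort_id=f"cohort{c}",
                expression=cpm,
                survival_time=pd.Series(time, index=expr.columns, name="time"),
                event=pd.Series(event, index=expr.columns, name="event"),
                grade=pd.Series(rng.integers(2, 5, size=n), index=expr.columns, name="grade"),
                stage=pd.Series(
                    rng.choice(["I", "II", "III", "IV"], size=n),
                    index=expr.columns,
                    name="stage",
                ),
                is_cpm=True,
            )
        )
        logger.info(
            "cohort%d: %d patients, %.0f%% events", c, n, 100 * event.mean()
        )
    return cohorts, truth


def gen_single_cell(
    config: SyntheticConfig, truth: SyntheticTruth | None = None
) -> list[SingleCellDataset]:
    """Generate per-patient single-cell datasets with planted edges."""
    if truth is None:
        truth = make_truth(config)
    genes, pairs = gene_universe(config)
    gene_index = {g: i for i, g in enumerate(genes)}
    types = list(config.cell_types)
    base_alpha = np.array([_BASE_PROPORTIONS.get(t, 0.1) for t in types])
    base_alpha = base_alpha / base_alpha.sum()
    grades = config.resolved_grades()
    planted_edges = config.resolved_planted_edges()

    base_rng = _rng(config.seed, 1)
    # wide log-normal gene weights: some genes well expressed, many near
    # the detection limit
    base_weight = np.exp(base_rng.normal(loc=0.0, scale=1.0, size=config.n_genes))

    datasets: list[SingleCellDataset] = []
    for p in range(config.n_sc_patients):
        rng = _rng(config.seed, 200 + p)
        grade = grades[p]
        pid = f"SC{p:02d}"

        # heterogeneous composition: Dirichlet around the base mixture,
        # with a floor so every type is represented
        props = rng.dirichlet(base_alpha * 10.0)
        n_floor = _MIN_CELLS_PER_TYPE * len(types)
        if config.cells_per_patient <= n_floor:
            raise ConfigError("cells_per_patient too small for the cell-type floor")
        extra = rng.multinomial(config.cells_per_patient - n_floor, props)
        n_per_type = extra + _MIN_CELLS_PER_TYPE

        # per-type gene weights with planted multipliers
        type_weight = {t: base_weight.copy() for t in types}
        for edge in planted_edges:
            if edge.grade_only is not None and edge.grade_only != grade:
                continue
            pair = pairs[edge.pair_index]
            type_weight[edge.sender][gene_index[pair.ligand]] *= edge.intensity
            type_weight[edge.receiver][gene_index[pair.receptor]] *= edge.intensity

        blocks = []
        labels = []
        for t, n_cells in zip(types, n_per_type):
            w = type_weight[t]
            probs = w / w.sum()
            lib = np.exp(rng.normal(np.log(2000.0), 0.3, size=n_cells))
            mean = lib[:, None] * probs[None, :]
            blocks.append(_nb_counts(rng, mean, config.dispersion))
            labels.extend([t] * n_cells)
        counts = sp.csr_matrix(np.vstack(blocks).astype(np.int64))
        barcodes = pd.Index([f"{pid}_B{i:04d}" for i in range(counts.shape[0])])
        datasets.append(
            SingleCellDataset(
                patient_id=pid,
                counts=counts,
                genes=pd.Index(genes),
                barcodes=barcodes,
                cell_type=pd.Series(labels, index=barcodes),
                grade=int(grade),
            )
        )
    return datasets


def config_to_dict(config: SyntheticConfig) -> dict:
    """YAML/JSON-serializable form of a config."""
    out = asdict(config)
    if config.planted_edges is not None:
        out["planted_edges"] = [asdict(e) for e in config.planted_edges]
    out["cell_types"] = list(config.cell_types)
    if config.grade_assignment is not None:
        out["grade_assignment"] = list(config.grade_assignment)
    return out


def config_from_dict(data: dict) -> SyntheticConfig:
    data = dict(data)
    if data.get("planted_edges") is not None:
        data["planted_edges"] = tuple(
            PlantedEdge(**e) if isinstance(e, dict) else PlantedEdge(*e)
            for e in data["planted_edges"]
        )
    if data.get("cell_types") is not None:
        data["cell_types"] = tuple(data["cell_types"])
    if data.get("grade_assignment") is not None:
        data["grade_assignment"] = tuple(data["grade_assignment"])
    return SyntheticConfig(**data)
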