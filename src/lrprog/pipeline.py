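"""End-to-end orchestration: simulate -> screen -> edges -> enrichment
-> grade screen, with a JSON run manifest for reproducibility.

Every stage writes a self-describing TSV that the next stage (or a
re-run) can consume on its own; rerunning with the same config and
inputs reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .edges import edges_table, extract_edges_all
from .enrichment import (
    adjusted_enrichment,
    enrichment_difference,
    grade_quartile_screen,
    grade_weight_tables,
    patient_support,
)
from .io import LRPair, read_cohort, read_lr_database, read_single_cell
from .simulate import SyntheticConfig, gen_bulk_cohorts, gen_single_cell
from .survival import screen_pairs, screen_table

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineConfig:
    """Configuration for one full run.

    Either ``synthetic`` is set (data are generated in memory) or the
    path fields point at on-disk inputs. Thresholds default to the
    analysis conventions: q < 0.1 for the survival screen, detection
    fraction >= 0.2 for edges, grade 4 for the quartile screen.
    """

    out_dir: str = "lrprog_out"
    synthetic: SyntheticConfig | None = None
    cohorts: list[dict] = field(default_factory=list)  # {id, expression, clinical}
    single_cell: list[dict] = field(default_factory=list)  # {matrix, metadata}
    lr_db: str | None = None
    q_threshold: float = 0.1
    detection_threshold: float = 0.2
    target_grade: int = 4
    stratify_reference: str = "per_pair"
    cell_norm: str = "cp10k"
    quartile_scope: str = "global"
    already_cpm: bool = False
    seed: int = 20210904

    def __post_init__(self):
        if not 0 < self.q_threshold <= 1:
            raise ValueError("q_threshold must lie in (0, 1]")
        if not 0 <= self.detection_threshold <= 1:
            raise ValueError("detection_threshold must lie in [0, 1]")


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings: dict[str, float] = {}

    # ---- load or simulate inputs -------------------------------------
    t0 = time.time()
    if config.synthetic is not None:
        synth = config.synthetic
        if synth.seed != config.seed:
            synth = SyntheticConfig(**{**_synth_dict(synth), "seed": config.seed})
        cohorts, truth = gen_bulk_cohorts(synth)
        sc_data = gen_single_cell(synth, truth)
        from .simulate import gene_universe

        _, pairs = gene_universe(synth)
    else:
        if not config.cohorts or config.lr_db is None:
            raise ValueError("need cohort paths and an LR database (or a synthetic config)")
        cohorts = [
            read_cohort(
                spec["expression"],
                spec["clinical"],
                cohort_id=spec.get("id"),
                already_cpm=config.already_cpm,
            )
            for spec in config.cohorts
        ]
        pairs = read_lr_database(config.lr_db)
        sc_data = [
            read_single_cell(spec["matrix"], spec["metadata"])
            for spec in config.single_cell
        ]
        truth = None
    timings["load"] = time.time() - t0

    # ---- survival screen ---------------------------------------------
    t0 = time.time()
    results = screen_pairs(
        cohorts,
        pairs,
        q_threshold=config.q_threshold,
        stratify_reference=config.stratify_reference,
    )
    results_frame = screen_table(results)
    _write_tsv(results_frame, out_dir / "results.tsv")
    poor = [r.pair for r in results if r.prognostic_class == "poor"]
    good = [r.pair for r in results if r.prognostic_class == "good"]
    logger.info("screen: %d poor, %d good of %d pairs", len(poor), len(good), len(pairs))
    timings["screen"] = time.time() - t0

    manifest_outputs = ["results.tsv"]

    # ---- single-cell arm ---------------------------------------------
    if sc_data:
        t0 = time.time()
        edge_sets = extract_edges_all(
            sc_data,
            pairs,
            detection_threshold=config.detection_threshold,
            cell_norm=config.cell_norm,
        )
        _write_tsv(edges_table(edge_sets), out_dir / "edges.tsv")
        grades = {d.patient_id: d.grade for d in sc_data}
        timings["edges"] = time.time() - t0

        t0 = time.time()
        enrich_frames = []
        for klass, screened in (("poor", poor), ("good", good)):
            if not screened:
                continue
            table = adjusted_enrichment(edge_sets, screened, pairs)
            table = table.assign(prognostic_class=klass).drop(columns=["per_patient"])
            enrich_frames.append(table)
        if enrich_frames:
            enrichment_frame = pd.concat(enrich_frames, ignore_index=True)
        else:
            enrichment_frame = pd.DataFrame(
                columns=["sender", "receiver", "adjusted_enrichment", "n_patients", "prognostic_class"]
            )
        _write_tsv(enrichment_frame, out_dir / "enrichment.tsv")

        support_frame = (
            patient_support(edge_sets, poor)
            if poor
            else pd.DataFrame(columns=["sender", "receiver", "ligand", "receptor", "n_patients"])
        )
        _write_tsv(support_frame, out_dir / "support.tsv")
        timings["enrichment"] = time.time() - t0

        t0 = time.time()
        if poor and any(g == config.target_grade for g in grades.values()):
            screen_res = grade_quartile_screen(
                edge_sets,
                grades,
                poor,
                target_grade=config.target_grade,
                quartile_scope=config.quartile_scope,
            )
            grade_frame = screen_res.selected
            q3 = screen_res.q3_threshold
            per_patient_w, per_grade_w = grade_weight_tables(edge_sets, grades, poor)
            _write_tsv(per_patient_w, out_dir / "weights_per_patient.tsv")
            _write_tsv(per_grade_w, out_dir / "weights_per_grade.tsv")
            manifest_outputs += ["weights_per_patient.tsv", "weights_per_grade.tsv"]
        else:
            grade_frame = pd.DataFrame(
                columns=["sender", "receiver", "ligand", "receptor", "weight"]
            )
            q3 = float("nan")
        _write_tsv(grade_frame, out_dir / "grade_screen.tsv")
        timings["grade_screen"] = time.time() - t0
        manifest_outputs += ["edges.tsv", "enrichment.tsv", "support.tsv", "grade_screen.tsv"]
    else:
        q3 = float("nan")

    # ---- manifest -----------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "n_pairs": len(pairs),
        "n_poor": len(poor),
        "n_good": len(good),
        "grade_q3_threshold": q3,
        "outputs": {
            name: {
                "rows": _count_rows(out_dir / name),
                "sha256": _sha256(out_dir / name),
            }
            for name in sorted(manifest_outputs)
        },
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "total_s": round(time.time() - t_start, 3),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _count_rows(path: Path) -> int:
    with open(path) as fh:
        return max(sum(1 for _ in fh) - 1, 0)


def _synth_dict(synth: SyntheticConfig) -> dict:
    from .simulate import config_to_dict

    return config_to_dict(synth)


def _config_dict(config: PipelineConfig) -> dict:
    out = asdict(config)
    if config.synthetic is not None:
        out["synthetic"] = _synth_dict(config.synthetic)
    return out


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from YAML."""
    import yaml

    from .simulate import config_from_dict

    data = yaml.safe_load(Path(path).read_text()) or {}
    if data.get("synthetic") is not None:
        data["synthetic"] = config_from_dict(data["synthetic"])
    return PipelineConfig(**data)
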