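"""End-to-end orchestration: simulate/load -> preprocess -> ESOM -> U*/cluster -> score.

Every run writes its artifacts (tables as CSV, reports as JSON, maps as PNG)
into an output directory together with a manifest recording the seed, the
parameters and SHA-256 hashes of the outputs, so reruns with the same
configuration can be verified byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .cluster import ClusterAssignment, PerformanceReport, UStarClusterer
from .preprocess import PreprocessedMatrix, preprocess_cohort
from .simulate import ScenarioConfig, generate_cohort, read_cohort, write_cohort

logger = logging.getLogger("torusom")


class PipelineStageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


class RunConfig(BaseModel):
    """Full configuration of one analysis run (one input source only)."""

    input_csv: str | None = None
    scenario: ScenarioConfig | None = None
    grubbs_alpha: float = Field(default=0.05, gt=0, lt=1)
    remove_grubbs_outliers: bool = True
    covariate_correction: bool = True
    rows: int = 30
    cols: int = 48
    toroidal: bool = True
    epochs: int = 20
    lr_start: float = 0.5
    lr_end: float = 0.05
    radius_start: float = 12.0
    radius_end: float = 1.0
    radius_method: str = "distance_quantile"
    sphere_radius: float | None = None
    sphere_quantile: float = 0.2013
    threshold_quantile: float = Field(default=0.8, gt=0, lt=1)
    render: bool = False
    out_dir: str | None = None
    seed: int = 0

    @model_validator(mode="after")
    def _one_source(self):
        if (self.input_csv is None) == (self.scenario is None):
            raise ValueError("exactly one of input_csv or scenario must be given")
        return self


@dataclasses.dataclass
class RunResult:
    cohort: pd.DataFrame
    preprocessed: PreprocessedMatrix
    clusterer: UStarClusterer
    assignment: ClusterAssignment
    report: PerformanceReport
    manifest: dict[str, Any]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis and (optionally) write all artifacts."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, writer) -> None:
        if out_dir:
            path = out_dir / name
            writer(path)
            written.append(path)

    stage = "input"
    try:
        if config.scenario is not None:
            cohort = generate_cohort(config.scenario.model_copy(update={"seed": config.seed}))
        else:
            cohort = read_cohort(config.input_csv)
        _write("cohort.csv", lambda p: write_cohort(cohort, p))

        stage = "preprocessing"
        pre, grubbs_results = preprocess_cohort(
            cohort,
            grubbs_alpha=config.grubbs_alpha,
            remove_grubbs_outliers=config.remove_grubbs_outliers,
            covariate_correction=config.covariate_correction,
        )
        _write("preprocessed.csv", lambda p: pre.to_frame().to_csv(p, index=False))
        _write("preprocessing_report.json", lambda p: p.write_text(json.dumps({
            "grubbs": [dataclasses.asdict(r) for r in grubbs_results],
            "provenance": pre.provenance,
        }, indent=2)))

        stage = "structure_identification"
        clusterer = UStarClusterer(
            rows=config.rows, cols=config.cols, toroidal=config.toroidal,
            epochs=config.epochs, lr_start=config.lr_start, lr_end=config.lr_end,
            radius_start=config.radius_start, radius_end=config.radius_end,
            radius_method=config.radius_method, sphere_radius=config.sphere_radius,
            sphere_quantile=config.sphere_quantile,
            threshold_quantile=config.threshold_quantile,
            random_state=config.seed,
        ).fit(pre.values)
        _write("model.csv", clusterer.som_.save)
        _write("umatrix.csv", clusterer.u_matrix_.save)
        _write("pmatrix.csv", clusterer.p_matrix_.save)
        _write("ustar.csv", clusterer.u_star_matrix_.save)

        assignment = clusterer.assignment_
        sizes = pd.Series(assignment.subject_labels).value_counts()
        if assignment.n_clusters == 1 or (sizes.min() / sizes.sum()) < 0.01:
            logger.warning("no clear cluster structure: %d cluster(s), sizes %s",
                           assignment.n_clusters, sizes.to_dict())

        stage = "structure_interpretation"
        truth = pre.meta["group"].to_numpy()
        report = clusterer.score_agreement(truth)
        predicted = [report.cluster_to_class[int(c)] for c in assignment.subject_labels]
        _write("clusters.csv", lambda p: assignment.to_frame(
            pre.subjects, truth=truth, predicted=predicted).to_csv(p, index=False))
        _write("report.json", lambda p: p.write_text(json.dumps(report.to_dict(), indent=2)))

        if config.render and out_dir:
            stage = "render"
            from .render import TopographicRender, render_map
            bmus = clusterer.som_.bmu_coords(pre.values)
            render_map(clusterer.u_star_matrix_, out_dir / "map.png",
                       bmus=bmus, truth=truth,
                       style=TopographicRender(overlay="by-class"))
            written.append(out_dir / "map.png")
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with stage, keep partial outputs
        raise PipelineStageError(stage, exc) from exc

    manifest = {
        "package": "torusom",
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "n_subjects": len(pre.subjects),
        "n_markers": len(pre.markers),
        "n_clusters": assignment.n_clusters,
        "outputs": {p.name: _sha256(p) for p in written},
    }
    _write("manifest.json", lambda p: p.write_text(json.dumps(manifest, indent=2)))
    return RunResult(cohort, pre, clusterer, assignment, report, manifest)
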