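"""One-call orchestration: read → align → preprocess → distance → PCoA → export.

Given a :class:`~metord.config.PipelineConfig` this module runs the whole
analysis and writes six artifacts into the output directory:

* ``filtered_table.tsv``   — the preprocessed samples × features table
* ``filter_report.json``   — features removed by the blank filter
* ``distance_matrix.tsv``  — square pairwise dissimilarity matrix
* ``ordination.txt``       — eigenvalues / proportion explained / coordinates
* ``scatter.html``         — standalone interactive 3-D scatter
* ``run.log``              — parameters, stage dimensions, removal counts

Runs are deterministic: the same config and inputs produce byte-identical
numeric outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import io as mio
from .config import PipelineConfig
from .ordination import pairwise_distances, pcoa
from .preprocessing import run_preprocessing
from .scatter import render_scatter
from .tables import FeatureTable, SampleMetadata, align

__all__ = ["RunArtifacts", "run"]

logger = logging.getLogger(__name__)


@dataclass
class RunArtifacts:
    filtered_table: Path
    filter_report: Path
    distance_matrix: Path
    ordination: Path
    scatter_html: Path
    run_log: Path


def _read_table(config: PipelineConfig) -> FeatureTable:
    if config.dialect == "gnps":
        return mio.read_gnps_quant_table(config.input_path)
    orientation = (
        "features_in_rows" if config.dialect == "plain_features" else "samples_in_rows"
    )
    return mio.read_plain_table(config.input_path, orientation=orientation)


def run(config: PipelineConfig) -> RunArtifacts:
    """Execute the full pipeline described by ``config``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = ["# metord run", "", "## parameters"]
    for key, value in sorted(config.as_dict().items()):
        log_lines.append(f"{key} = {value!r}")

    def stage(name):
        logger.info("stage: %s", name)
        log_lines.append("")
        log_lines.append(f"## {name}")

    try:
        stage("read")
        table = _read_table(config)
        metadata = mio.read_metadata(config.metadata_path, config.id_column)
        log_lines.append(
            f"table: {table.n_samples} samples x {table.n_features} features"
        )
        log_lines.append(f"metadata: {len(metadata.sample_ids)} samples")

        stage("align")
        table, metadata, dropped_t, dropped_m = align(table, metadata)
        log_lines.append(f"aligned samples: {table.n_samples}")
        log_lines.append(f"dropped from table: {dropped_t}")
        log_lines.append(f"dropped from metadata: {dropped_m}")

        stage("preprocess")
        table, report = run_preprocessing(table, metadata, config)
        log_lines.append(
            f"blank filter removed {report.n_removed} of "
            f"{report.n_features_before} features "
            f"(retained {100 * report.retained_fraction:.1f}%)"
        )
        log_lines.append(
            f"normalization={config.normalization} scaling={config.scaling}"
        )
        log_lines.append(
            f"table: {table.n_samples} samples x {table.n_features} features"
        )

        if config.drop_blanks_before_ordination:
            stage("drop blanks")
            keep = [
                s for s in table.sample_ids
                if metadata.column(config.blank_column).loc[s] != config.blank_value
            ]
            table = table.select_samples(keep)
            metadata = metadata.select_samples(keep)
            log_lines.append(f"samples after dropping blanks: {table.n_samples}")

        stage("distances")
        dm = pairwise_distances(table, config.metric)
        log_lines.append(f"metric: {config.metric}, matrix {dm.n} x {dm.n}")

        stage("ordination")
        result = pcoa(dm, num_axes="all")
        shown = min(
            result.num_axes,
            result.num_axes if config.num_axes == "all" else int(config.num_axes),
        )
        log_lines.append(
            f"positive axes: {result.num_axes}; "
            f"negative eigenvalue mass: {result.negative_eigenvalue_mass:.6g}"
        )
        log_lines.append(
            "proportion explained (first axes): "
            + ", ".join(f"{p:.4f}" for p in result.proportion_explained[:shown])
        )

        stage("export")
        paths = RunArtifacts(
            filtered_table=out / "filtered_table.tsv",
            filter_report=out / "filter_report.json",
            distance_matrix=out / "distance_matrix.tsv",
            ordination=out / "ordination.txt",
            scatter_html=out / "scatter.html",
            run_log=out / "run.log",
        )
        mio.write_plain_table(table, paths.filtered_table)
        paths.filter_report.write_text(
            json.dumps(report.as_dict(), indent=1, sort_keys=True)
        )
        mio.write_distance_matrix(dm, paths.distance_matrix)
        mio.write_ordination(result, paths.ordination)
        color_by = config.color_by or config.blank_column
        render_scatter(
            result, metadata, color_by=color_by, shape_by=config.shape_by,
            path=paths.scatter_html,
        )
        for artifact in (
            paths.filtered_table, paths.filter_report, paths.distance_matrix,
            paths.ordination, paths.scatter_html,
        ):
            log_lines.append(f"wrote {artifact}")
    except Exception as exc:
        log_lines.append("")
        log_lines.append(f"FAILED: {exc}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise
    paths.run_log.write_text("\n".join(log_lines) + "\n")
    return paths
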