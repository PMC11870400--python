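"""Synthetic LC-MS/MS feature tables with known ground truth.

The generator emulates the structure of real untargeted metabolomics
quantification tables: a handful of solvent-blank runs, several biological
groups, a block of contaminant features that are bright in blanks and
attenuated in biological samples, and a sparse block of biological features
that are absent from blanks and log-normally distributed in samples, with
each feature acting as a marker for one group (its intensity multiplied by
``effect_size`` there).

Log-normal intensities are the standard model for LC-MS peak areas: skewed,
strictly positive, multiplicative noise. Sparsity is injected by zeroing a
fixed fraction of cells in the biological block, reproducing the
features-only-in-a-few-samples pattern that makes blank filtering and
abundance-based dissimilarities interesting in the first place.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_metadata, _FMT
from .tables import FeatureTable, SampleMetadata

__all__ = ["FixtureSpec", "GroundTruth", "generate", "write_gnps_dialect",
           "BLANK_COLUMN", "BLANK_VALUE", "GROUP_COLUMN"]

BLANK_COLUMN = "sample_type"
BLANK_VALUE = "blank"
GROUP_COLUMN = "group"

# log-intensity location/spread of feature base abundances (peak areas ~1e5)
_BASE_LOG_MEAN = np.log(1e5)
_BASE_LOG_SD = 1.0
_CONTAMINANT_ATTENUATION = 10.0  # contaminants are this much dimmer in samples
_BLANK_CARRYOVER = 1000.0  # biological signal in blanks is trace-level, not zero


@dataclass
class FixtureSpec:
    """Study design of one synthetic dataset.

    Defaults describe a small but realistic design: 4 blank runs, 3
    biological groups of 8 samples, 80 contaminant features, 240 biological
    features at 30% sparsity, 4-fold group marker effects, and log-normal
    noise with sigma 0.6.
    """

    n_blank: int = 4
    n_samples_per_group: int = 8
    n_groups: int = 3
    n_contaminant_features: int = 80
    n_biological_features: int = 240
    sparsity: float = 0.3
    effect_size: float = 4.0
    noise_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples_per_group", "n_groups",
                     "n_contaminant_features", "n_biological_features"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_blank < 0:
            raise ValueError("n_blank must be >= 0")
        if not 0 <= self.sparsity < 1:
            raise ValueError("sparsity must be in [0, 1)")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass
class GroundTruth:
    """Which features are contaminants, and which group each marker tags."""

    feature_kind: dict[str, str]          # feature id -> contaminant|biological
    marker_group: dict[str, str]          # biological feature id -> group name

    def as_dict(self) -> dict:
        return {"feature_kind": self.feature_kind,
                "marker_group": self.marker_group}


def generate(spec: FixtureSpec) -> tuple[FeatureTable, SampleMetadata, GroundTruth]:
    """Draw one synthetic feature table + metadata, reproducibly from seed."""
    rng = np.random.default_rng(spec.seed)
    groups = [f"group_{g + 1}" for g in range(spec.n_groups)]
    sample_ids = [f"blank_{b + 1}" for b in range(spec.n_blank)]
    sample_group = [BLANK_VALUE] * spec.n_blank
    for g, gname in enumerate(groups):
        for s in range(spec.n_samples_per_group):
            sample_ids.append(f"g{g + 1}_s{s + 1}")
            sample_group.append(gname)
    n_samples = len(sample_ids)
    is_blank = np.array([g == BLANK_VALUE for g in sample_group])

    n_feat = spec.n_contaminant_features + spec.n_biological_features
    feature_ids = [str(i + 1) for i in range(n_feat)]
    kinds = (["contaminant"] * spec.n_contaminant_features
             + ["biological"] * spec.n_biological_features)
    # round-robin marker assignment keeps groups balanced at any size
    marker = {
        feature_ids[spec.n_contaminant_features + j]: groups[j % spec.n_groups]
        for j in range(spec.n_biological_features)
    }

    base = rng.normal(_BASE_LOG_MEAN, _BASE_LOG_SD, size=n_feat)
    X = np.zeros((n_samples, n_feat))

    # contaminant block: bright in blanks, attenuated in biological samples
    nc = spec.n_contaminant_features
    noise = rng.normal(0.0, spec.noise_sd, size=(n_samples, nc))
    X[:, :nc] = np.exp(base[:nc] + noise)
    X[~is_blank, :nc] /= _CONTAMINANT_ATTENUATION

    # biological block: trace-level in blanks, group-structured in samples
    nb = spec.n_biological_features
    noise = rng.normal(0.0, spec.noise_sd, size=(n_samples, nb))
    bio = np.exp(base[nc:] + noise)
    for j in range(nb):
        fid = feature_ids[nc + j]
        boost = np.array([g == marker[fid] for g in sample_group])
        bio[boost, j] *= spec.effect_size
    if spec.sparsity > 0:
        bio[rng.random(bio.shape) < spec.sparsity] = 0.0
    bio[is_blank] /= _BLANK_CARRYOVER
    X[:, nc:] = bio

    data = pd.DataFrame(X, index=sample_ids, columns=feature_ids)
    annotations = pd.DataFrame(
        {
            "mz": rng.uniform(100.0, 1500.0, size=n_feat),
            "rt": rng.uniform(0.5, 20.0, size=n_feat),
        },
        index=feature_ids,
    )
    table = FeatureTable(data, annotations)
    metadata = SampleMetadata(
        pd.DataFrame(
            {BLANK_COLUMN: ["blank" if b else "sample" for b in is_blank],
             GROUP_COLUMN: sample_group},
            index=sample_ids,
        )
    )
    truth = GroundTruth(
        feature_kind=dict(zip(feature_ids, kinds)),
        marker_group=marker,
    )
    return table, metadata, truth


def write_gnps_dialect(
    table: FeatureTable,
    metadata: SampleMetadata,
    dir_path,
    ground_truth: GroundTruth | None = None,
) -> dict[str, Path]:
    """Write the fixture as a GNPS-style quant CSV + metadata TSV (+ truth).

    The quant table gets the feature-per-row layout with ``<sample>.mzML
    Peak area`` columns so the GNPS reader is exercised end-to-end.
    """
    if table.n_features == 0 or table.n_samples == 0:
        raise ValueError("refusing to write an empty feature table")
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    quant_path = dir_path / "quant_table.csv"
    meta_path = dir_path / "metadata.tsv"

    ann = table.feature_annotations
    mz = ann["mz"] if ann is not None and "mz" in ann else pd.Series(0.0, index=table.feature_ids)
    rt = ann["rt"] if ann is not None and "rt" in ann else pd.Series(0.0, index=table.feature_ids)

    header = ["row ID", "row m/z", "row retention time"] + [
        f"{s}.mzML Peak area" for s in table.sample_ids
    ]
    lines = [",".join(header)]
    V = table.values
    for j, fid in enumerate(table.feature_ids):
        cells = [fid, _FMT % mz.iloc[j], _FMT % rt.iloc[j]]
        cells += [_FMT % V[i, j] for i in range(table.n_samples)]
        lines.append(",".join(cells))
    quant_path.write_text("\n".join(lines) + "\n")

    write_metadata(metadata, meta_path, id_column="sample_id")
    paths = {"quant_table": quant_path, "metadata": meta_path}
    if ground_truth is not None:
        truth_path = dir_path / "ground_truth.json"
        truth_path.write_text(json.dumps(ground_truth.as_dict(), indent=1, sort_keys=True))
        paths["ground_truth"] = truth_path
    return paths
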