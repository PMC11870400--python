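"""Feature filtering, normalization, and scaling — in that fixed order.

Blank filtering removes background features (extraction solvents,
environmental contaminants, instrument noise) by comparing each feature's
intensity in biological samples against its mean intensity in blank runs: a
feature is retained only if it strictly exceeds ``fold_threshold`` times the
mean blank intensity in at least ``min_nonblank_fraction`` of the non-blank
samples. Filtering removes features, never samples — blanks stay in the
table so their separation remains visible in the ordination.

Normalization corrects per-sample intensity differences: TIC divides each
sample by its total ion current; PQN additionally divides by the per-sample
median fold change against a median reference spectrum, which corrects
dilution effects. Scaling then adjusts per-feature ranges: auto-scaling to
unit variance, or Pareto scaling by the square root of the standard
deviation (damping dominant features while preserving structure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .tables import FeatureTable, SampleMetadata

__all__ = [
    "BlankFilterParams",
    "FilterReport",
    "blank_filter",
    "normalize_tic",
    "normalize_pqn",
    "scale_auto",
    "scale_pareto",
    "normalize",
    "scale",
    "run_preprocessing",
    "NORMALIZATION_METHODS",
    "SCALING_METHODS",
]

logger = logging.getLogger(__name__)

NORMALIZATION_METHODS = ("tic", "pqn", "none")
SCALING_METHODS = ("auto", "pareto", "none")


@dataclass
class BlankFilterParams:
    """Parameters of the blank-intensity feature filter.

    fold_threshold
        A feature must strictly exceed ``fold_threshold`` × (mean blank
        intensity) to count as present in a sample. E.g. 0.3 keeps features
        higher than 30% of the average blank intensity.
    min_nonblank_fraction
        Fraction of non-blank samples that must satisfy the threshold for
        the feature to be retained (``>=`` comparison, no rounding).
    blank_column, blank_value
        Metadata column and cell value designating blank samples.
    """

    fold_threshold: float
    min_nonblank_fraction: float
    blank_column: str
    blank_value: str

    def __post_init__(self) -> None:
        if not self.fold_threshold > 0:
            raise ValueError("fold_threshold must be > 0")
        if not 0 < self.min_nonblank_fraction <= 1:
            raise ValueError("min_nonblank_fraction must be in (0, 1]")


@dataclass
class FilterReport:
    n_features_before: int
    n_features_after: int
    removed_feature_ids: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return self.n_features_before - self.n_features_after

    @property
    def retained_fraction(self) -> float:
        if self.n_features_before == 0:
            return 0.0
        return self.n_features_after / self.n_features_before

    def as_dict(self) -> dict:
        return {
            "n_features_before": self.n_features_before,
            "n_features_after": self.n_features_after,
            "n_removed": self.n_removed,
            "retained_fraction": self.retained_fraction,
            "removed_feature_ids": list(self.removed_feature_ids),
        }


def blank_filter(
    table: FeatureTable,
    metadata: SampleMetadata,
    params: BlankFilterParams,
) -> tuple[FeatureTable, FilterReport]:
    """Retain features that rise above blank background.

    For each feature compute its mean intensity over blank samples; the
    feature is retained iff the fraction of non-blank samples whose
    intensity *strictly* exceeds ``fold_threshold × blank mean`` is at least
    ``min_nonblank_fraction``. With an all-zero blank mean the threshold is
    zero, so any positive intensity qualifies. The sample set is unchanged:
    blanks are kept so ordination can still display them.
    """
    missing = [s for s in table.sample_ids if s not in set(metadata.sample_ids)]
    if missing:
        raise ValueError(
            f"samples missing from metadata (align first): {missing[:5]}"
        )
    flags = metadata.column(params.blank_column).reindex(table.sample_ids)
    is_blank = (flags == params.blank_value).to_numpy()
    n_blank = int(is_blank.sum())
    n_nonblank = int((~is_blank).sum())
    if n_blank == 0:
        raise ValueError(
            f"no samples have {params.blank_column!r} == "
            f"{params.blank_value!r}; skip the blank filter if the study "
            "has no blank runs"
        )
    if n_nonblank == 0:
        raise ValueError("all samples are blanks; nothing to filter against")

    X = table.values
    blank_mean = X[is_blank].mean(axis=0)
    exceeds = X[~is_blank] > params.fold_threshold * blank_mean
    frac = exceeds.sum(axis=0) / n_nonblank
    keep = frac >= params.min_nonblank_fraction

    kept_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    removed_ids = [f for f, k in zip(table.feature_ids, keep) if not k]
    report = FilterReport(
        n_features_before=table.n_features,
        n_features_after=len(kept_ids),
        removed_feature_ids=removed_ids,
    )
    logger.info(
        "blank filter removed %d of %d features (retained %.1f%%)",
        report.n_removed, report.n_features_before,
        100 * report.retained_fraction,
    )
    return table.select_features(kept_ids), report


def normalize_tic(table: FeatureTable) -> FeatureTable:
    """Divide each sample by its total ion current; rows then sum to 1."""
    X = table.values
    totals = X.sum(axis=1)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ValueError(
            f"sample {table.sample_ids[zero[0]]!r} has zero total intensity; "
            "TIC normalization is undefined"
        )
    return table.with_values(X / totals[:, None])


def normalize_pqn(table: FeatureTable) -> FeatureTable:
    """Probabilistic quotient normalization.

    TIC-normalize every sample, build the reference spectrum as the
    per-feature median across all samples, then divide each sample by the
    median of its feature-wise quotients against the reference (its dilution
    factor). Quotients use only features positive in both the sample and the
    reference.
    """
    if table.n_samples < 2:
        raise ValueError("PQN needs at least 2 samples to form a reference")
    tic = normalize_tic(table)
    X = tic.values
    ref = np.median(X, axis=0)
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        mask = (ref > 0) & (X[i] > 0)
        if not mask.any():
            raise ValueError(
                f"sample {table.sample_ids[i]!r} shares no positive feature "
                "with the PQN reference spectrum"
            )
        d = np.median(X[i, mask] / ref[mask])
        out[i] = X[i] / d
    return table.with_values(out)


def _scale(table: FeatureTable, denom_fn, what: str) -> FeatureTable:
    if table.n_samples < 2:
        raise ValueError(f"{what} scaling needs at least 2 samples")
    X = table.values
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant feature(s) set to zero during %s scaling",
            int(constant.sum()), what,
        )
    denom = np.where(constant, 1.0, denom_fn(sd))
    out = (X - mean) / denom
    out[:, constant] = 0.0
    return table.with_values(out)


def scale_auto(table: FeatureTable) -> FeatureTable:
    """Center each feature and divide by its standard deviation (ddof=1)."""
    return _scale(table, lambda sd: sd, "auto")


def scale_pareto(table: FeatureTable) -> FeatureTable:
    """Center each feature and divide by sqrt of its standard deviation."""
    return _scale(table, np.sqrt, "pareto")


def normalize(table: FeatureTable, method: str) -> FeatureTable:
    if method == "tic":
        return normalize_tic(table)
    if method == "pqn":
        return normalize_pqn(table)
    if method == "none":
        return table
    raise ValueError(
        f"unknown normalization {method!r}; choose from {NORMALIZATION_METHODS}"
    )


def scale(table: FeatureTable, method: str) -> FeatureTable:
    if method == "auto":
        return scale_auto(table)
    if method == "pareto":
        return scale_pareto(table)
    if method == "none":
        return table
    raise ValueError(
        f"unknown scaling {method!r}; choose from {SCALING_METHODS}"
    )


def run_preprocessing(
    table: FeatureTable,
    metadata: SampleMetadata,
    config,
) -> tuple[FeatureTable, FilterReport]:
    """Apply the full preprocessing chain: filter → normalize → scale.

    ``config`` is a :class:`~metord.config.PipelineConfig` (or anything with
    the same fields). Disabled stages are identities; a disabled filter
    yields a report with zero removals.
    """
    if config.normalization not in NORMALIZATION_METHODS:
        raise ValueError(
            f"unknown normalization {config.normalization!r}; choose from "
            f"{NORMALIZATION_METHODS}"
        )
    if config.scaling not in SCALING_METHODS:
        raise ValueError(
            f"unknown scaling {config.scaling!r}; choose from {SCALING_METHODS}"
        )
    if config.filter_enabled:
        params = BlankFilterParams(
            fold_threshold=config.fold_threshold,
            min_nonblank_fraction=config.min_nonblank_fraction,
            blank_column=config.blank_column,
            blank_value=config.blank_value,
        )
        table, report = blank_filter(table, metadata, params)
    else:
        report = FilterReport(
            n_features_before=table.n_features,
            n_features_after=table.n_features,
        )
    table = normalize(table, config.normalization)
    table = scale(table, config.scaling)
    return table, report
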