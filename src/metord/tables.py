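"""In-memory containers for feature tables and sample metadata.

A :class:`FeatureTable` is the canonical samples × features intensity matrix
of an untargeted LC-MS/MS experiment: rows are experimental samples, columns
are features (chromatographic peaks characterized by m/z and retention time),
and cells hold peak areas in arbitrary units. Missing cells are zeros —
feature tables are sparse by nature, since many features are detected in only
a small subset of samples.

:class:`SampleMetadata` carries the per-sample attributes (tissue type,
genotype, and crucially which samples are solvent/extraction blanks) that
drive blank filtering and plot styling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "SampleMetadata", "AlignResult", "align"]


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {kind} id: {x!r}")
        seen.add(x)


@dataclass
class FeatureTable:
    """Samples × features intensity matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Float matrix with sample ids as index and feature ids as columns.
    feature_annotations : pandas.DataFrame, optional
        Per-feature annotations indexed by feature id; conventionally holds
        ``mz`` (Da) and ``rt`` (retention time, units as found in the file).
    """

    data: pd.DataFrame
    feature_annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "feature")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("feature table contains non-finite values")
        if self.feature_annotations is not None:
            self.feature_annotations = self.feature_annotations.reindex(
                self.data.columns
            )

    # -- accessors -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        """Intensity matrix, shape (n_samples, n_features)."""
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    # -- transformations -------------------------------------------------
    def with_values(self, values: np.ndarray) -> "FeatureTable":
        """Same ids/annotations, new intensity matrix."""
        if values.shape != self.data.shape:
            raise ValueError(
                f"shape mismatch: {values.shape} vs {self.data.shape}"
            )
        return FeatureTable(
            pd.DataFrame(values, index=self.data.index, columns=self.data.columns),
            self.feature_annotations,
        )

    def select_samples(self, sample_ids) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return FeatureTable(self.data.loc[list(sample_ids)], self.feature_annotations)

    def select_features(self, feature_ids) -> "FeatureTable":
        missing = [f for f in feature_ids if f not in self.data.columns]
        if missing:
            raise KeyError(f"unknown feature ids: {missing}")
        ann = None
        if self.feature_annotations is not None:
            ann = self.feature_annotations.loc[list(feature_ids)]
        return FeatureTable(self.data[list(feature_ids)], ann)

    def equals(self, other: "FeatureTable", rtol: float = 1e-12) -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and np.allclose(self.values, other.values, rtol=rtol, atol=0.0)
        )


@dataclass
class SampleMetadata:
    """Per-sample attribute table; all attribute values are strings."""

    attributes: pd.DataFrame

    def __post_init__(self) -> None:
        self.attributes = self.attributes.astype(str)
        self.attributes.index = self.attributes.index.astype(str)
        _check_unique(self.attributes.index, "sample")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.attributes.index)

    @property
    def columns(self) -> list[str]:
        return list(self.attributes.columns)

    def column(self, name: str) -> pd.Series:
        if name not in self.attributes.columns:
            raise KeyError(
                f"metadata column {name!r} not found; available columns: "
                f"{list(self.attributes.columns)}"
            )
        return self.attributes[name]

    def select_samples(self, sample_ids) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in self.attributes.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return SampleMetadata(self.attributes.loc[list(sample_ids)])

    def equals(self, other: "SampleMetadata") -> bool:
        return self.attributes.equals(other.attributes)


class AlignResult(NamedTuple):
    table: FeatureTable
    metadata: SampleMetadata
    dropped_from_table: list[str]
    dropped_from_metadata: list[str]


def align(table: FeatureTable, metadata: SampleMetadata) -> AlignResult:
    """Restrict table and metadata to their shared samples.

    Both objects are subset to the intersection of sample ids, kept in the
    table's order; ids dropped from either side are reported so silent sample
    loss cannot go unnoticed.
    """
    meta_ids = set(metadata.sample_ids)
    shared = [s for s in table.sample_ids if s in meta_ids]
    if not shared:
        raise ValueError(
            "feature table and metadata share no sample ids; check the "
            "metadata id column and sample-name canonicalization"
        )
    shared_set = set(shared)
    dropped_t = [s for s in table.sample_ids if s not in shared_set]
    dropped_m = [s for s in metadata.sample_ids if s not in shared_set]
    return AlignResult(
        table.select_samples(shared),
        metadata.select_samples(shared),
        dropped_t,
        dropped_m,
    )
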