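"""Readers and writers for every tabular artifact the pipeline touches.

Supported dialects:

* GNPS/mzMine feature quantification CSV — one feature per row, header
  ``row ID, row m/z, row retention time`` followed by one peak-area column
  per sample (``<name>.mzML Peak area``).
* plain samples × features (or features × samples) TSV/CSV with a single id
  column;
* metadata TSV keyed by a sample-id column;
* square distance-matrix TSV with ids on both axes;
* the ecology-standard ordination text format (``Eigvals`` / ``Proportion
  explained`` / ``Site`` blocks).

All numeric output is written with 12 significant digits so that every
writer/reader pair round-trips numerically.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import FeatureTable, SampleMetadata

__all__ = [
    "FormatError",
    "read_gnps_quant_table",
    "read_plain_table",
    "write_plain_table",
    "read_metadata",
    "write_metadata",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_ordination",
    "write_ordination",
]

GNPS_REQUIRED = ("row ID", "row m/z", "row retention time")
_PEAK_AREA_SUFFIX = " Peak area"
_EXTENSION_RE = re.compile(r"\.(mzml|mzxml)$", re.IGNORECASE)

_FMT = "%.17g"  # shortest-exact float round-trip


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


def _sep_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def canonical_sample_name(column_header: str) -> str:
    """Strip one trailing ' Peak area' token and one mzML/mzXML extension.

    GNPS quant-table sample columns look like ``Blank_1.mzML Peak area``;
    the metadata file refers to the same sample as ``Blank_1``.
    """
    name = column_header
    if name.endswith(_PEAK_AREA_SUFFIX):
        name = name[: -len(_PEAK_AREA_SUFFIX)]
    return _EXTENSION_RE.sub("", name).strip()


def _check_nonnegative(values: np.ndarray, context: str) -> None:
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise FormatError(
            f"{context}: negative intensity {values[i, j]} at row {i}, "
            f"column {j}; raw feature tables must be non-negative"
        )


def read_gnps_quant_table(path, delimiter: str | None = None) -> FeatureTable:
    """Read a GNPS/mzMine feature quantification table.

    The file stores one feature per row; the returned table is transposed to
    the canonical samples × features orientation. Sample ids are the
    peak-area column headers with the `` Peak area`` suffix and one file
    extension stripped. ``row m/z`` / ``row retention time`` are kept as
    feature annotations. Empty cells become 0.
    """
    path = Path(path)
    sep = _sep_for(path, delimiter)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep), None)
    if header is None:
        raise FormatError(f"{path}: empty file")
    header = [h.strip() for h in header]
    for col in GNPS_REQUIRED:
        if col not in header:
            raise FormatError(f"{path}: missing required column {col!r}")
    sample_cols = [c for c in header if c and c not in GNPS_REQUIRED]
    if not sample_cols:
        raise FormatError(f"{path}: no sample intensity columns found")
    canonical = [canonical_sample_name(c) for c in sample_cols]
    seen: set[str] = set()
    for name in canonical:
        if name in seen:
            raise FormatError(f"{path}: duplicate sample column {name!r}")
        seen.add(name)

    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    row_ids = df["row ID"].astype(str).str.strip().tolist()
    dup = pd.Series(row_ids)[pd.Series(row_ids).duplicated()]
    if not dup.empty:
        raise FormatError(f"{path}: duplicate 'row ID' value {dup.iloc[0]!r}")

    intensities = np.zeros((len(row_ids), len(sample_cols)))
    for j, col in enumerate(sample_cols):
        raw = df[col].str.strip()
        num = pd.to_numeric(raw.replace("", "0"), errors="coerce")
        if num.isna().any():
            i = int(num.index[num.isna()][0])
            raise FormatError(
                f"{path}: non-numeric intensity {raw.iloc[i]!r} in column "
                f"{col!r}, feature row {row_ids[i]!r}"
            )
        intensities[:, j] = num.to_numpy()
    _check_nonnegative(intensities, str(path))

    annotations = pd.DataFrame(
        {
            "mz": pd.to_numeric(df["row m/z"], errors="coerce").to_numpy(),
            "rt": pd.to_numeric(df["row retention time"], errors="coerce").to_numpy(),
        },
        index=row_ids,
    )
    data = pd.DataFrame(intensities.T, index=canonical, columns=row_ids)
    return FeatureTable(data, annotations)


def read_plain_table(
    path,
    orientation: str = "samples_in_rows",
    delimiter: str | None = None,
) -> FeatureTable:
    """Read a plain table with one id column and a numeric body.

    ``orientation`` says what the file's rows are; the returned table is
    always samples × features.
    """
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise ValueError(
            "orientation must be 'samples_in_rows' or 'features_in_rows', "
            f"got {orientation!r}"
        )
    path = Path(path)
    sep = _sep_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty table")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell in table body: {exc}") from exc
    df = df.fillna(0.0)
    if orientation == "features_in_rows":
        df = df.T
    _check_nonnegative(df.to_numpy(), str(path))
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return FeatureTable(df)


def write_plain_table(table: FeatureTable, path, delimiter: str | None = None) -> None:
    """Write samples × features with a leading ``sample_id`` column."""
    path = Path(path)
    sep = _sep_for(path, delimiter)
    df = table.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep, float_format=_FMT)


def read_metadata(path, id_column: str, delimiter: str | None = None) -> SampleMetadata:
    """Read a metadata table; every non-id column is preserved as strings."""
    path = Path(path)
    sep = _sep_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if id_column not in df.columns:
        raise FormatError(
            f"{path}: id column {id_column!r} not found; available columns: "
            f"{list(df.columns)}"
        )
    ids = df[id_column].astype(str).str.strip()
    dups = ids[ids.duplicated()]
    if not dups.empty:
        raise FormatError(f"{path}: duplicate sample id {dups.iloc[0]!r}")
    attrs = df.drop(columns=[id_column])
    attrs.index = ids
    attrs.index.name = id_column
    return SampleMetadata(attrs)


def write_metadata(metadata: SampleMetadata, path, id_column: str = "sample_id",
                   delimiter: str | None = None) -> None:
    path = Path(path)
    sep = _sep_for(path, delimiter)
    df = metadata.attributes.copy()
    df.index.name = id_column
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# distance matrix and ordination formats
# ---------------------------------------------------------------------------

def write_distance_matrix(dm, path) -> None:
    """Write a square TSV with sample ids on both axes."""
    from .ordination import DistanceMatrix  # local import avoids a cycle

    if not isinstance(dm, DistanceMatrix):
        raise TypeError("expected a DistanceMatrix")
    if len(dm.ids) == 0:
        raise ValueError("refusing to write an empty distance matrix")
    path = Path(path)
    df = pd.DataFrame(dm.values, index=dm.ids, columns=dm.ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=_FMT)


def read_distance_matrix(path, metric_name: str = "unknown"):
    from .ordination import DistanceMatrix

    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise FormatError(f"{path}: row and column ids differ")
    return DistanceMatrix(
        ids=list(df.index.astype(str)),
        values=df.to_numpy(dtype=float),
        metric_name=metric_name,
    )


def write_ordination(result, path) -> None:
    """Write the block-structured ordination exchange format.

    Blocks: ``Eigvals``, ``Proportion explained``, ``Species`` (empty),
    ``Site`` (sample coordinates), ``Biplot`` (empty), ``Site constraints``
    (empty); tab-separated, blocks separated by blank lines. The empty blocks
    make the file readable by other ordination tools that expect the full
    layout.
    """
    from .ordination import OrdinationResult

    if not isinstance(result, OrdinationResult):
        raise TypeError("expected an OrdinationResult")
    k = result.num_axes
    if k == 0 or len(result.ids) == 0:
        raise ValueError("refusing to write an empty ordination result")
    path = Path(path)

    def fmt(x: float) -> str:
        return _FMT % x

    lines: list[str] = []
    lines.append(f"Eigvals\t{k}")
    lines.append("\t".join(fmt(v) for v in result.eigenvalues[:k]))
    lines.append("")
    lines.append(f"Proportion explained\t{k}")
    lines.append("\t".join(fmt(v) for v in result.proportion_explained))
    lines.append("")
    lines.append("Species\t0\t0")
    lines.append("")
    lines.append(f"Site\t{len(result.ids)}\t{k}")
    for sid, row in zip(result.ids, result.coordinates):
        lines.append(sid + "\t" + "\t".join(fmt(v) for v in row))
    lines.append("")
    lines.append("Biplot\t0\t0")
    lines.append("")
    lines.append("Site constraints\t0\t0")
    lines.append("")
    try:
        path.write_text("\n".join(lines))
    except OSError as exc:
        raise OSError(f"failed writing ordination file {path}: {exc}") from exc


def read_ordination(path):
    """Parse the ordination exchange format written by :func:`write_ordination`."""
    from .ordination import OrdinationResult

    path = Path(path)
    text = path.read_text()
    blocks: dict[str, list[list[str]]] = {}
    current: list[list[str]] | None = None
    for line in text.splitlines():
        if not line.strip():
            current = None
            continue
        cells = line.split("\t")
        header = cells[0]
        if current is None:
            blocks[header] = []
            current = blocks[header]
            continue
        current.append(cells)
    if "Eigvals" not in blocks or "Site" not in blocks:
        raise FormatError(f"{path}: not an ordination file")
    eigvals = np.array([float(v) for v in blocks["Eigvals"][0]])
    prop = np.array([float(v) for v in blocks["Proportion explained"][0]])
    ids = [row[0] for row in blocks["Site"]]
    coords = np.array([[float(v) for v in row[1:]] for row in blocks["Site"]])
    return OrdinationResult(
        ids=ids,
        eigenvalues=eigvals,
        coordinates=coords,
        proportion_explained=prop,
        negative_eigenvalue_mass=0.0,
    )
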