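"""Dissimilarity matrices, classical PCoA, and PCA.

Classical Principal Coordinate Analysis (metric multidimensional scaling)
embeds n samples described only by a pairwise dissimilarity matrix D into a
Euclidean space whose inter-point distances approximate D:

1. square the dissimilarities elementwise, A = -1/2 * D∘D;
2. Gower double-centering, B = J A J with J = I - 11ᵀ/n;
3. eigendecompose the symmetric B; sort eigenvalues descending;
4. coordinates on axis a are eigenvector_a * sqrt(λ_a) for λ_a > 0.

Non-Euclidean dissimilarities (Bray-Curtis among them) can yield negative
eigenvalues; those axes carry no real coordinates and are excluded from the
embedding and from the proportion-explained denominator, but their absolute
mass is kept as a distortion diagnostic. On a Euclidean distance matrix PCoA
is equivalent to PCA of the raw data — a classical result this module's test
suite checks numerically.

Pairwise dissimilarities are computed with the SciPy distance catalogue;
twenty metrics are registered. Binary metrics operate on presence/absence
obtained by thresholding intensities at strictly > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import distance as _ssd

from .tables import FeatureTable

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "METRICS",
    "BINARY_METRICS",
    "NONNEGATIVE_ONLY_METRICS",
    "pairwise_distances",
    "pcoa",
    "pca",
]

#: Metrics that operate on presence/absence (value > 0).
BINARY_METRICS = frozenset(
    {"jaccard", "dice", "russellrao", "rogerstanimoto", "sokalsneath",
     "yule", "matching", "hamming"}
)

#: Metrics defined for non-negative abundance data; scaled (signed) input
#: triggers a warning, not an error.
NONNEGATIVE_ONLY_METRICS = frozenset(
    {"braycurtis", "jaccard", "dice", "jensenshannon", "canberra"}
)

#: The registered dissimilarity measures: metric name -> pdist arguments.
METRICS: dict[str, dict] = {
    "braycurtis": {"metric": "braycurtis"},
    "euclidean": {"metric": "euclidean"},
    "sqeuclidean": {"metric": "sqeuclidean"},
    "cityblock": {"metric": "cityblock"},
    "chebyshev": {"metric": "chebyshev"},
    "canberra": {"metric": "canberra"},
    "cosine": {"metric": "cosine"},
    "correlation": {"metric": "correlation"},
    "minkowski": {"metric": "minkowski", "p": 3},
    "seuclidean": {"metric": "seuclidean"},
    "jensenshannon": {"metric": "jensenshannon"},
    "mahalanobis": {"metric": "mahalanobis"},
    "hamming": {"metric": "hamming"},
    "jaccard": {"metric": "jaccard"},
    "dice": {"metric": "dice"},
    "russellrao": {"metric": "russellrao"},
    "rogerstanimoto": {"metric": "rogerstanimoto"},
    "sokalsneath": {"metric": "sokalsneath"},
    "yule": {"metric": "yule"},
    "matching": {"metric": "hamming"},  # simple matching distance on presence
}


@dataclass
class DistanceMatrix:
    """Symmetric hollow matrix of pairwise sample dissimilarities."""

    ids: list[str]
    values: np.ndarray
    metric_name: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} ids"
            )
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in distance matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("distance matrix contains non-finite values")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix is not hollow (non-zero diagonal)")
        # exact symmetry/hollowness simplifies downstream math
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class OrdinationResult:
    """Sample embedding from PCoA or PCA.

    ``eigenvalues`` holds the full computed spectrum (descending, possibly
    with zero/negative entries for non-Euclidean dissimilarities);
    ``coordinates`` and ``proportion_explained`` cover only the retained
    positive axes (at most ``num_axes`` of them).
    """

    ids: list[str]
    eigenvalues: np.ndarray
    coordinates: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalue_mass: float = 0.0
    method: str = "pcoa"

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.proportion_explained = np.asarray(self.proportion_explained, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-9 * max(1.0, abs(self.eigenvalues[0]))):
            raise ValueError("eigenvalues must be sorted descending")
        if self.coordinates.shape != (len(self.ids), len(self.proportion_explained)):
            raise ValueError("coordinates shape does not match ids / axes")
        if (self.proportion_explained < -1e-12).any() or (
            self.proportion_explained > 1 + 1e-12
        ).any():
            raise ValueError("proportion explained entries must lie in [0, 1]")
        if self.proportion_explained.sum() > 1 + 1e-9:
            raise ValueError("proportion explained sums to more than 1")

    @property
    def num_axes(self) -> int:
        return self.coordinates.shape[1]


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each column's largest-|entry| element positive (deterministic)."""
    out = vectors.copy()
    for a in range(out.shape[1]):
        idx = int(np.argmax(np.abs(out[:, a])))
        if out[idx, a] < 0:
            out[:, a] = -out[:, a]
    return out


def pairwise_distances(table: FeatureTable, metric: str, **kwargs) -> DistanceMatrix:
    """Compute all pairwise sample dissimilarities under a registered metric.

    Binary metrics see ``value > 0`` presence patterns. Metrics defined for
    abundances only warn when the table contains negative values (possible
    after scaling). An undefined pair (e.g. Bray-Curtis between two all-zero
    samples) raises, naming the offending sample pair.
    """
    if metric not in METRICS:
        raise ValueError(
            f"unknown metric {metric!r}; valid metrics: "
            + ", ".join(sorted(METRICS))
        )
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples for pairwise distances")
    X = table.values
    if metric in NONNEGATIVE_ONLY_METRICS and (X < 0).any():
        warnings.warn(
            f"metric {metric!r} assumes non-negative intensities but the "
            "table contains negative values (scaled data?); results may be "
            "hard to interpret",
            UserWarning,
            stacklevel=2,
        )
    spec = dict(METRICS[metric])
    name = spec.pop("metric")
    spec.update(kwargs)
    if metric in BINARY_METRICS:
        X = X > 0
    if metric == "mahalanobis" and "VI" not in spec:
        # pseudo-inverse tolerates the p >= n tables typical of metabolomics
        spec["VI"] = np.linalg.pinv(np.cov(X.T.astype(float)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        condensed = _ssd.pdist(X, metric=name, **spec)
    square = _ssd.squareform(condensed)
    if not np.isfinite(square).all():
        i, j = np.argwhere(~np.isfinite(square))[0]
        raise ValueError(
            f"metric {metric!r} is undefined for sample pair "
            f"({table.sample_ids[i]!r}, {table.sample_ids[j]!r}); "
            "check for all-zero samples"
        )
    return DistanceMatrix(ids=table.sample_ids, values=square, metric_name=metric)


def pcoa(dm: DistanceMatrix, num_axes: int | str = "all") -> OrdinationResult:
    """Classical PCoA via Gower double-centering and eigendecomposition."""
    n = dm.n
    if n < 2:
        raise ValueError("need at least 2 samples for PCoA")
    if isinstance(num_axes, str) and num_axes != "all":
        raise ValueError("num_axes must be a positive integer or 'all'")
    D = dm.values
    A = -0.5 * D * D
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = J @ A @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    tol = 1e-12 * max(1.0, float(np.abs(eigvals).max(initial=0.0)))
    positive = eigvals > tol
    n_pos = int(positive.sum())
    k = n_pos if num_axes == "all" else min(int(num_axes), n_pos)
    if k == 0:
        raise ValueError("no positive eigenvalues; degenerate distance matrix")

    vecs = _fix_signs(eigvecs[:, :k])
    coords = vecs * np.sqrt(eigvals[:k])
    pos_sum = float(eigvals[positive].sum())
    neg_mass = float(np.abs(eigvals[eigvals < -tol]).sum())
    return OrdinationResult(
        ids=dm.ids,
        eigenvalues=eigvals,
        coordinates=coords,
        proportion_explained=eigvals[:k] / pos_sum,
        negative_eigenvalue_mass=neg_mass,
        method="pcoa",
    )


def pca(table: FeatureTable, num_axes: int | str = "all") -> OrdinationResult:
    """PCA of a samples × features table via SVD of the centered matrix.

    Sample scores are U·S; eigenvalues are the squared singular values, so
    the spectrum (and the scores) matches PCoA on Euclidean distances.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples for PCA")
    if isinstance(num_axes, str) and num_axes != "all":
        raise ValueError("num_axes must be a positive integer or 'all'")
    X = table.values
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    eigvals = S**2
    total = float(eigvals.sum())
    if total == 0.0:
        raise ValueError("all samples identical; PCA is undefined")
    tol = 1e-12 * float(eigvals.max())
    n_pos = int((eigvals > tol).sum())
    k = n_pos if num_axes == "all" else min(int(num_axes), n_pos)
    scores = _fix_signs(U[:, :k] * S[:k])
    return OrdinationResult(
        ids=table.sample_ids,
        eigenvalues=eigvals,
        coordinates=scores,
        proportion_explained=eigvals[:k] / total,
        negative_eigenvalue_mass=0.0,
        method="pca",
    )
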