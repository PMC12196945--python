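"""KNN-improved density-peak clustering with automatic cluster-count estimation.

Classic density-peak clustering (DPC) ranks points by a local density and by
the distance to the nearest denser point, then asks a human to pick cluster
centers off a decision graph.  The variant implemented here replaces the
global cutoff-distance density with a k-nearest-neighbor density, adds a
neighborhood-aware *repulsion factor*, and selects both the centers and the
number of clusters automatically:

* local density   ``rho_a = 1 - mean distance to the k nearest neighbors / sigma``
  where ``sigma`` is the dataset diameter (maximum pairwise distance), so
  ``rho`` always lies in [0, 1];
* repulsion factor ``delta_a`` = the minimum distance between the closed
  neighborhood of ``a`` (its k nearest neighbors plus itself) and any point of
  strictly higher density; for a global density peak, the maximum distance
  from the peak to any other point;
* centrality      ``gamma_a = (rho_a * delta_a) ** m``;
* candidate centers are the points whose density and repulsion both exceed
  their respective means; candidates are sorted by decreasing centrality and
  the estimated cluster count K is fixed by the boundary gap — the last
  adjacent centrality gap that exceeds the mean gap, which separates the
  center group from the trailing noise candidates;
* remaining points inherit, in order of decreasing density, the label of
  their nearest neighbor of strictly higher density.

All steps are deterministic; distance and density ties are broken by point
index.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "DPCParams",
    "DensityProfile",
    "ClusteringResult",
    "DegenerateDataError",
    "NoCandidateError",
    "pairwise_distances",
    "knn_indices",
    "local_density",
    "repulsion_factor",
    "centrality",
    "select_centers",
    "assign_labels",
    "fit",
    "read_features",
    "write_result",
]


class DegenerateDataError(ValueError):
    """All points coincide: the diameter is zero and densities are undefined."""


class NoCandidateError(ValueError):
    """No point exceeds both the mean density and the mean repulsion factor."""


@dataclass(frozen=True)
class DPCParams:
    """Tunable parameters of the clustering.

    k is the neighbor count used for the density estimate; m is the exponent
    applied to the density-repulsion product when ranking center candidates.
    """

    k: int = 8
    m: float = 2.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be a positive integer, got {self.k}")
        if self.m <= 0:
            raise ValueError(f"m must be positive, got {self.m}")


@dataclass(frozen=True)
class DensityProfile:
    """Per-point density state: (rho, delta, gamma) and the diameter sigma."""

    rho: np.ndarray
    delta: np.ndarray
    gamma: np.ndarray
    sigma: float


@dataclass(frozen=True)
class ClusteringResult:
    """Centers (ordered by decreasing centrality), cluster count and labels."""

    centers: np.ndarray
    n_clusters: int
    labels: np.ndarray
    profile: DensityProfile | None = field(default=None, compare=False)


def _validate_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError(f"feature matrix must be 2-D, got shape {X.shape}")
    if X.shape[0] < 2:
        raise ValueError("need at least two points")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite entries")
    return X


def pairwise_distances(X: np.ndarray) -> tuple[np.ndarray, float]:
    """Full Euclidean distance matrix and the dataset diameter sigma.

    sigma is the maximum pairwise distance and later normalizes the density
    estimate.  sigma == 0 flags fully degenerate (all-identical) data; the
    caller decides whether that is an error.
    """
    X = _validate_matrix(X)
    D = cdist(X, X, metric="euclidean")
    # enforce exact symmetry and a zero diagonal against roundoff
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D, float(D.max())


def knn_indices(D: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest neighbors of every point, self excluded.

    Returns an (n, k) array; distance ties are broken by ascending index
    (stable sort), which keeps the whole pipeline deterministic.  For large
    n the rows are pre-narrowed with argpartition before the stable sort.
    """
    n = D.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the point count n={n}")
    out = np.empty((n, k), dtype=np.intp)
    if n <= 512:
        order = np.argsort(D, axis=1, kind="stable")
        for a in range(n):
            row = order[a]
            out[a] = row[row != a][:k]
        return out
    part = np.argpartition(D, k + 1, axis=1)[:, : k + 2]
    for a in range(n):
        row = part[a]
        row = row[np.argsort(row, kind="stable")]  # index order for tie-breaks
        row = row[np.argsort(D[a, row], kind="stable")]
        out[a] = row[row != a][:k]
    return out


def local_density(
    D: np.ndarray,
    sigma: float,
    params: DPCParams = DPCParams(),
    nbrs: np.ndarray | None = None,
) -> np.ndarray:
    """KNN local density: rho_a = 1 - (mean distance to k nearest)/sigma.

    rho is 1 when all k neighbors coincide with the point and 0 when they all
    sit at the dataset diameter; it always lies in [0, 1].  ``nbrs`` lets the
    caller reuse a precomputed neighbor table.
    """
    if sigma <= 0:
        raise DegenerateDataError(
            "all points are identical (sigma = 0); densities are undefined"
        )
    if nbrs is None:
        nbrs = knn_indices(D, params.k)
    mean_knn_dist = np.take_along_axis(D, nbrs, axis=1).mean(axis=1)
    rho = 1.0 - mean_knn_dist / sigma
    # guard against roundoff leaking outside the closed unit interval
    return np.clip(rho, 0.0, 1.0)


def repulsion_factor(
    D: np.ndarray,
    rho: np.ndarray,
    params: DPCParams = DPCParams(),
    nbrs: np.ndarray | None = None,
) -> np.ndarray:
    """Neighborhood-to-denser-region distance, large for centers and outliers.

    For a point ``a`` that is not a global density peak,
    ``delta_a = min d(x_b, x_e)`` over ``x_b`` in the closed neighborhood
    KNN'(a) = KNN(a) ∪ {a} and ``x_e`` of strictly higher density.  Every
    point attaining the maximum density takes instead the distance to its
    farthest point.
    """
    n = D.shape[0]
    rho = np.asarray(rho, dtype=float)
    if nbrs is None:
        nbrs = knn_indices(D, params.k)
    knnp = np.concatenate(
        [nbrs, np.arange(n, dtype=np.intp)[:, None]], axis=1
    )
    delta = np.empty(n)
    rho_max = rho.max()

    # Sort points by decreasing density (ties by index).  Strictly denser
    # points form a prefix of this order, so a running column-minimum over the
    # reordered distance matrix gives min_{e in HD} d(b, e) for every b and
    # every prefix length in one pass.
    order = np.lexsort((np.arange(n), -rho))
    hd_count = n - np.searchsorted(np.sort(rho), rho, side="right")
    prefix_min = D[:, order]
    np.minimum.accumulate(prefix_min, axis=1, out=prefix_min)

    peak = rho >= rho_max
    delta[peak] = D[peak].max(axis=1)
    rest = ~peak
    if rest.any():
        idx = np.flatnonzero(rest)
        # hd_count >= 1 for non-peaks; prefix of length h covers exactly HD
        delta[idx] = prefix_min[knnp[idx], hd_count[idx, None] - 1].min(axis=1)
    return delta


def centrality(
    rho: np.ndarray, delta: np.ndarray, params: DPCParams = DPCParams()
) -> np.ndarray:
    """Centrality score gamma = (rho * delta) ** m used to rank candidates."""
    rho = np.asarray(rho, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if rho.shape != delta.shape:
        raise ValueError("rho and delta must have equal length")
    if (rho < 0).any() or (delta < 0).any():
        raise ValueError("rho and delta must be non-negative")
    return (rho * delta) ** params.m


def select_centers(
    rho: np.ndarray, delta: np.ndarray, gamma: np.ndarray
) -> tuple[np.ndarray, int]:
    """Adaptive center selection with the centrality-gap rule.

    Candidates are points with above-average density *and* above-average
    repulsion.  Sorted by decreasing centrality, the gaps between adjacent
    candidate centralities are compared with their mean: the boundary gap —
    the last gap exceeding the mean, i.e. the first above-average gap met
    when scanning up from the weakest candidate — fixes the cluster count K,
    and the top-K candidates become the centers.  This reading keeps the
    whole group of strong centers and discards the trailing low-centrality
    candidates; keying on the first above-average gap from the top instead
    would collapse K to 1 whenever the strongest center (whose repulsion is
    the dataset diameter) stands above the others.
    """
    cand_mask = (rho > rho.mean()) & (delta > delta.mean())
    cand = np.flatnonzero(cand_mask)
    if cand.size == 0:
        raise NoCandidateError(
            "no point exceeds both the mean density and the mean repulsion "
            "factor; the data may be too small or too uniform to cluster"
        )
    # decreasing gamma, ties by ascending index
    cand = cand[np.lexsort((cand, -gamma[cand]))]
    if cand.size == 1:
        return cand, 1
    gaps = gamma[cand][:-1] - gamma[cand][1:]
    above = np.flatnonzero(gaps > gaps.mean())
    if above.size == 0:
        warnings.warn(
            "no centrality gap exceeds the mean gap; keeping all "
            f"{cand.size} candidates as centers",
            stacklevel=2,
        )
        return cand, int(cand.size)
    K = int(above[-1]) + 1  # boundary gap g_K separates candidate K from K+1
    return cand[:K], K


def assign_labels(
    D: np.ndarray, rho: np.ndarray, centers: np.ndarray
) -> np.ndarray:
    """Propagate center labels down the density landscape.

    Points are visited in order of decreasing density; each non-center
    inherits the label of its nearest point of strictly higher density
    (distance ties broken by index).  A density peak that is not itself a
    center has no denser neighbor and is attached to its nearest center.
    """
    centers = np.asarray(centers, dtype=np.intp)
    if centers.size == 0:
        raise ValueError("centers must be non-empty")
    n = D.shape[0]
    labels = np.full(n, -1, dtype=np.intp)
    labels[centers] = np.arange(centers.size)
    order = np.lexsort((np.arange(n), -np.asarray(rho, dtype=float)))
    for a in order:
        if labels[a] >= 0:
            continue
        denser = np.flatnonzero(rho > rho[a])
        if denser.size:
            target = denser[np.argmin(D[a, denser])]
        else:  # non-center density peak (possible under ties)
            target = centers[np.argmin(D[a, centers])]
        labels[a] = labels[target]
    return labels


def fit(X: np.ndarray, params: DPCParams = DPCParams()) -> ClusteringResult:
    """Run the full pipeline: densities, repulsion, centers, labels.

    Deterministic: identical inputs always produce identical output.
    """
    D, sigma = pairwise_distances(X)
    nbrs = knn_indices(D, params.k)
    rho = local_density(D, sigma, params, nbrs=nbrs)
    delta = repulsion_factor(D, rho, params, nbrs=nbrs)
    gamma = centrality(rho, delta, params)
    centers, K = select_centers(rho, delta, gamma)
    labels = assign_labels(D, rho, centers)
    profile = DensityProfile(rho=rho, delta=delta, gamma=gamma, sigma=sigma)
    return ClusteringResult(
        centers=centers, n_clusters=K, labels=labels, profile=profile
    )


# ---------------------------------------------------------------------------
# I/O: feature matrices in CSV / HDF5, results as CSV + JSON summary


def read_features(
    path: str | Path, label_column: str | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Read an n x d feature matrix from CSV (header row) or HDF5.

    For HDF5 the dataset is looked up under 'features' (labels under
    'labels' if present).  Returns (X, labels-or-None); labels are only ever
    used for evaluation, never by the clustering itself.
    """
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        import h5py

        with h5py.File(path, "r") as f:
            X = np.asarray(f["features"])
            y = np.asarray(f["labels"]) if "labels" in f else None
        return X, y
    df = pd.read_csv(path)
    y = None
    if label_column is not None:
        y = df.pop(label_column).to_numpy()
    elif "label" in df.columns:
        y = df.pop("label").to_numpy()
    return df.to_numpy(dtype=float), y


def write_result(
    result: ClusteringResult,
    csv_path: str | Path,
    json_path: str | Path | None = None,
    params: DPCParams | None = None,
) -> None:
    """Write per-point diagnostics as CSV and an optional JSON summary."""
    n = result.labels.size
    prof = result.profile
    df = pd.DataFrame(
        {
            "point_index": np.arange(n),
            "rho": prof.rho if prof is not None else np.full(n, np.nan),
            "delta": prof.delta if prof is not None else np.full(n, np.nan),
            "gamma": prof.gamma if prof is not None else np.full(n, np.nan),
            "label": result.labels,
            "is_center": np.isin(np.arange(n), result.centers),
        }
    )
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        summary = {
            "K": int(result.n_clusters),
            "center_indices": [int(c) for c in result.centers],
            "params": {"k": params.k, "m": params.m} if params else None,
        }
        Path(json_path).write_text(json.dumps(summary, indent=2))
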