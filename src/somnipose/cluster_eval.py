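"""External clustering validity metrics: NMI and ARI.

Both metrics compare a clustering ``V`` against a reference partition ``U``
through their contingency table and are invariant to how either partition
labels its clusters.

* NMI(U, V) = 2 I(U, V) / (H(U) + H(V)), with mutual information and entropy
  in nats (the base cancels in the ratio); ranges over [0, 1], equal to 1
  exactly when the partitions coincide up to relabeling.
* ARI is the chance-corrected pair-counting Rand index,

      ARI = [sum_ij C(n_ij,2) - E] / [(sum_i C(a_i,2) + sum_j C(b_j,2))/2 - E]

  with E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2); it is 1 for identical
  partitions, has expectation 0 under independent random labelings, and can
  be negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ContingencyTable", "contingency", "nmi", "ari"]


@dataclass(frozen=True)
class ContingencyTable:
    """Joint counts n_ij of (reference cluster i, predicted cluster j)."""

    table: np.ndarray
    row_sums: np.ndarray
    col_sums: np.ndarray
    n: int


def _as_codes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).ravel()
    _, codes = np.unique(labels, return_inverse=True)
    return codes


def contingency(u: np.ndarray, v: np.ndarray) -> ContingencyTable:
    """Contingency table of two equal-length label vectors.

    Labels may be arbitrary integers (or any hashable values); only the
    induced partitions matter.
    """
    u = np.asarray(u).ravel()
    v = np.asarray(v).ravel()
    if u.shape != v.shape:
        raise ValueError(
            f"partitions must have equal length, got {u.size} and {v.size}"
        )
    ui = _as_codes(u)
    vi = _as_codes(v)
    table = np.zeros((ui.max() + 1, vi.max() + 1), dtype=np.int64)
    np.add.at(table, (ui, vi), 1)
    return ContingencyTable(
        table=table,
        row_sums=table.sum(axis=1),
        col_sums=table.sum(axis=0),
        n=int(u.size),
    )


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def nmi(u: np.ndarray, v: np.ndarray) -> float:
    """Normalized mutual information, 2 I/(H(U)+H(V)), in [0, 1]."""
    ct = contingency(u, v)
    hu = _entropy(ct.row_sums, ct.n)
    hv = _entropy(ct.col_sums, ct.n)
    if hu + hv == 0.0:
        # both partitions are a single cluster: identical, hence agreement 1
        warnings.warn(
            "both partitions have zero entropy (single cluster); NMI "
            "defined as 1.0",
            stacklevel=2,
        )
        return 1.0
    nz = ct.table > 0
    pij = ct.table[nz] / ct.n
    pi = ct.row_sums[np.nonzero(nz)[0]] / ct.n
    pj = ct.col_sums[np.nonzero(nz)[1]] / ct.n
    mi = float((pij * np.log(pij / (pi * pj))).sum())
    val = 2.0 * mi / (hu + hv)
    return float(min(max(val, 0.0), 1.0))


def _comb2(x: np.ndarray | int) -> np.ndarray | float:
    x = np.asarray(x, dtype=float)
    return x * (x - 1.0) / 2.0


def ari(u: np.ndarray, v: np.ndarray) -> float:
    """Adjusted Rand index; 1 for identical partitions, ~0 for random ones."""
    ct = contingency(u, v)
    if ct.n < 2:
        raise ValueError("ARI requires at least two points")
    sum_ij = float(_comb2(ct.table).sum())
    sum_a = float(_comb2(ct.row_sums).sum())
    sum_b = float(_comb2(ct.col_sums).sum())
    total = float(_comb2(ct.n))
    expected = sum_a * sum_b / total
    denom = 0.5 * (sum_a + sum_b) - expected
    if denom == 0.0:
        # both partitions all-singletons or both one-cluster: agreement is
        # total iff the tables coincide
        if sum_ij == sum_a == sum_b:
            return 1.0
        warnings.warn(
            "ARI denominator is zero for non-identical degenerate "
            "partitions; returning 0.0",
            stacklevel=2,
        )
        return 0.0
    return float((sum_ij - expected) / denom)
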