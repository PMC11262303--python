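"""Thresholding and weighted graph topology: transitivity and efficiency.

Connectivity matrices are thresholded with an absolute cutoff — the median
of connectivity strength pooled across all recordings of a band — keeping
weights at or above the cutoff unchanged and zeroing the rest (no
binarization).

Weighted transitivity

    T = sum_i 2 t_i / sum_i k_i (k_i - 1),
    t_i = 1/2 sum_{j,h} (w_ij w_ih w_jh)^(1/3)

is the collectively normalized clustering coefficient: total weighted
triangle intensity over total connected triples (k_i = number of nonzero
links at node i). Weighted global efficiency

    E = 1/N sum_i [ sum_{j != i} d_ij^{-1} / (N - 1) ]

averages inverse shortest weighted path lengths, with the weight-to-length
map f(w) = 1/w (the convention for correlation-weighted graphs; -log w is
available) and unreachable pairs contributing zero, so E is defined for
disconnected graphs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from sklearn.base import BaseEstimator

from .bands import BandSpec, get_band
from .connectivity import ConnectivityMatrix


def _check_metric_input(m: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    w = m.weights if isinstance(m, ConnectivityMatrix) else np.asarray(m, float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if np.abs(np.diag(w)).max(initial=0.0) != 0.0:
        raise ValueError("diagonal must be zero")
    if w.min(initial=0.0) < 0:
        raise ValueError(
            "negative weights are undefined for these metrics; threshold first"
        )
    return w


def pooled_median_threshold(
    matrices: list[ConnectivityMatrix], band: str | BandSpec | None = None
) -> float:
    """Median of all upper-triangle weights pooled across matrices.

    Midpoint interpolation for even pool sizes (numpy's default median).
    All matrices must share the band and region set.
    """
    if not matrices:
        raise ValueError("empty matrix pool")
    band = get_band(band) if band is not None else matrices[0].band
    labels = matrices[0].region_labels
    for m in matrices:
        if m.band != band:
            raise ValueError("pooled matrices must share the band")
        if m.region_labels != labels:
            raise ValueError("pooled matrices must share the region set")
    pooled = np.concatenate([m.upper_triangle() for m in matrices])
    return float(np.median(pooled))


def apply_threshold(A: ConnectivityMatrix, cutoff: float) -> ConnectivityMatrix:
    """Zero entries strictly below ``cutoff``; keep entries >= cutoff as-is."""
    if np.isnan(cutoff):
        raise ValueError("cutoff must be a number (may be -inf)")
    w = np.where(A.weights >= cutoff, A.weights, 0.0)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(
        weights=w,
        band=A.band,
        subject=A.subject,
        condition=A.condition,
        region_labels=list(A.region_labels),
    )


class MedianThresholder(BaseEstimator):
    """Learn one pooled-median cutoff per band and apply it.

    ``fit`` pools the upper-triangle weights of all supplied matrices
    (for one band) and stores the median as ``cutoff_``; ``transform``
    zeroes sub-cutoff entries of a matrix. Pooling every condition —
    including the two resting recordings — is the default; pass
    ``exclude_conditions`` to restrict the pool.
    """

    def __init__(self, exclude_conditions: tuple[str, ...] = ()):
        self.exclude_conditions = exclude_conditions

    def fit(self, matrices: list[ConnectivityMatrix]) -> "MedianThresholder":
        pool = [
            m for m in matrices if m.condition not in set(self.exclude_conditions)
        ]
        self.cutoff_ = pooled_median_threshold(pool)
        self.n_pooled_ = len(pool)
        return self

    def transform(self, A: ConnectivityMatrix) -> ConnectivityMatrix:
        return apply_threshold(A, self.cutoff_)


def weighted_transitivity(A: ConnectivityMatrix | np.ndarray) -> float:
    """Weighted transitivity T; 0 when no node has degree >= 2."""
    w = _check_metric_input(A)
    c = np.cbrt(w)
    # t_i = 1/2 * (C^3)_ii ; the matrix power enumerates ordered (j, h).
    t = 0.5 * np.einsum("ij,jh,hi->i", c, c, c)
    k = (w > 0).sum(axis=1)
    denom = float((k * (k - 1)).sum())
    if denom == 0.0:
        return 0.0
    return float(2.0 * t.sum() / denom)


def weighted_global_efficiency(
    A: ConnectivityMatrix | np.ndarray, length_map: str = "inverse"
) -> float:
    """Weighted global efficiency E under f(w) = 1/w (or -log w).

    Unreachable pairs contribute inverse distance 0; graphs with fewer
    than two nodes have E = 0.
    """
    w = _check_metric_input(A)
    n = w.shape[0]
    if n < 2:
        return 0.0
    if length_map == "inverse":
        lengths = np.divide(1.0, w, out=np.zeros_like(w), where=w > 0)
    elif length_map == "neglog":
        if w.max(initial=0.0) > 1.0:
            raise ValueError("-log length map requires weights <= 1")
        lengths = np.where(w > 0, -np.log(np.clip(w, 1e-300, None)), 0.0)
    else:
        raise ValueError(f"unknown length map {length_map!r}")
    d = shortest_path(csr_matrix(lengths), method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


@dataclass
class NetworkMeasures:
    """Both topology measures for one subject x condition x band."""

    subject: str
    condition: str
    band: BandSpec
    T: float
    E: float


def measures_from_matrices(
    matrices: list[ConnectivityMatrix],
    thresholder: MedianThresholder | None = None,
    length_map: str = "inverse",
) -> pd.DataFrame:
    """Threshold a band's matrices and tabulate T and E in long format.

    Returns a MeasureTable-shaped DataFrame with columns
    subject, condition, band, measure, value.
    """
    if thresholder is None:
        thresholder = MedianThresholder().fit(matrices)
    rows = []
    for m in matrices:
        thr = thresholder.transform(m)
        rows.append((m.subject, m.condition, m.band.name, "T", weighted_transitivity(thr)))
        rows.append(
            (m.subject, m.condition, m.band.name, "E",
             weighted_global_efficiency(thr, length_map=length_map))
        )
    return pd.DataFrame(
        rows, columns=["subject", "condition", "band", "measure", "value"]
    )
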