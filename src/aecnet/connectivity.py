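"""Orthogonalized amplitude-envelope correlation (AEC) connectivity.

Signal leakage — the spurious zero-lag correlation that instantaneous
linear mixing induces between reconstructed regional signals — is removed
pairwise: the component of the analytic signal y(t) collinear with the
instantaneous phase of x(t) is discarded, keeping only

    y_perp_x(t) = Im( conj(x(t)) / |x(t)| * y(t) ).

AEC is then the Pearson correlation between the amplitude envelopes. The
orthogonalization is asymmetric, so both directions are computed and the
undirected weight is their arithmetic mean — the established convention
for this estimator.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .bands import BandSpec, get_band
from .envelope import (
    AnalyticSeries,
    analytic_signal,
    bandpass,
    edge_trim,
    envelope_of,
    EnvelopeSeries,
)
from .timeseries import RegionTimeSeries

logger = logging.getLogger(__name__)


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted adjacency matrix for one subject x condition x band.

    Invariants: symmetric, zero diagonal, entries in [-1, 1].
    """

    weights: np.ndarray
    band: BandSpec
    subject: str = ""
    condition: str = ""
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.abs(np.diag(w)).max(initial=0.0) != 0.0:
            raise ValueError("diagonal must be exactly zero")
        if np.nanmax(np.abs(w), initial=0.0) > 1.0 + 1e-12:
            raise ValueError("weights must lie in [-1, 1]")
        self.weights = w
        if not self.region_labels:
            self.region_labels = [f"region{i:03d}" for i in range(w.shape[0])]
        if len(self.region_labels) != w.shape[0]:
            raise ValueError("label count does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Off-diagonal upper-triangle weights as a flat vector."""
        iu = np.triu_indices(self.n_regions, k=1)
        return self.weights[iu]


def orthogonalize(y: AnalyticSeries, x: AnalyticSeries) -> np.ndarray:
    """Component of y orthogonal to the instantaneous phase of x.

    Returns the real series Im(conj(x)/|x| * y). Samples where |x| is
    numerically zero (below 1e-12 of its maximum) return 0 instead of
    blowing up.
    """
    if y.values.shape != x.values.shape:
        raise ValueError("series length mismatch")
    if y.band != x.band or y.fs != x.fs:
        raise ValueError("band/sampling-rate mismatch")
    mag = np.abs(x.values)
    eps = 1e-12 * mag.max(initial=0.0)
    safe = mag > eps
    out = np.zeros_like(mag)
    np.divide(
        np.imag(np.conj(x.values) * y.values), mag, out=out, where=safe
    )
    return out


def aec(a_i: EnvelopeSeries | np.ndarray, a_j: EnvelopeSeries | np.ndarray) -> float:
    """Pearson correlation between two amplitude envelopes.

    Returns 0 with a warning if either envelope is constant (the
    correlation is undefined there).
    """
    u = np.asarray(a_i.values if isinstance(a_i, EnvelopeSeries) else a_i, float)
    v = np.asarray(a_j.values if isinstance(a_j, EnvelopeSeries) else a_j, float)
    if u.shape != v.shape:
        raise ValueError("envelope length mismatch")
    if u.size < 3:
        raise ValueError("need at least 3 samples")
    u = u - u.mean()
    v = v - v.mean()
    nu, nv = np.sqrt(u @ u), np.sqrt(v @ v)
    if nu == 0.0 or nv == 0.0:
        warnings.warn("constant envelope: AEC undefined, returning 0")
        return 0.0
    return float(np.clip((u @ v) / (nu * nv), -1.0, 1.0))


class AECConnectivity(BaseEstimator):
    """Transformer: region time series -> AEC connectivity matrix.

    Parameters
    ----------
    band : str or BandSpec
        Frequency band to analyse.
    orthogonalize : bool, default True
        Remove zero-lag leakage pairwise before correlating envelopes.
        With False the plain AEC is computed.
    trim : int or None
        Samples discarded at each edge before correlating; defaults to
        one filter length.
    n_windows : int, default 1
        Optional windowed estimation: the trimmed recording is split into
        this many equal windows and the per-window AECs averaged. The
        default (1) is a single static estimate over the full recording.
    """

    def __init__(
        self,
        band: str | BandSpec = "alpha",
        orthogonalize: bool = True,
        trim: int | None = None,
        n_windows: int = 1,
    ):
        self.band = band
        self.orthogonalize = orthogonalize
        self.trim = trim
        self.n_windows = n_windows

    def transform(self, ts: RegionTimeSeries) -> ConnectivityMatrix:
        band = get_band(self.band)
        if ts.n_regions < 2:
            raise ValueError("need at least 2 regions")
        trim = self.trim if self.trim is not None else edge_trim(ts.fs, band)
        filtered = bandpass(ts.data, ts.fs, band)
        if filtered.shape[1] - 2 * trim < 3 * self.n_windows:
            raise ValueError("recording too short after edge trimming")

        analytic = [
            analytic_signal(filtered[i], ts.fs, band) for i in range(ts.n_regions)
        ]
        n = ts.n_regions
        w = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                try:
                    w[i, j] = w[j, i] = self._pair(analytic[i], analytic[j], trim)
                except Exception as exc:  # pragma: no cover - defensive
                    logger.warning(
                        "AEC failed for pair (%s, %s): %s; storing 0",
                        ts.labels[i], ts.labels[j], exc,
                    )
        return ConnectivityMatrix(
            weights=w,
            band=band,
            subject=ts.subject,
            condition=ts.condition,
            region_labels=list(ts.labels),
        )

    def _pair(self, zi: AnalyticSeries, zj: AnalyticSeries, trim: int) -> float:
        values = []
        for sl in self._windows(zi.values.size, trim):
            if self.orthogonalize:
                env_i = np.abs(zi.values[sl])
                env_j = np.abs(zj.values[sl])
                ji = self._env_of_real(orthogonalize(zj, zi)[sl], zi, zj)
                ij = self._env_of_real(orthogonalize(zi, zj)[sl], zi, zi)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    values.append(0.5 * (aec(ji, env_i) + aec(ij, env_j)))
            else:
                values.append(aec(np.abs(zi.values[sl]), np.abs(zj.values[sl])))
        return float(np.mean(values))

    @staticmethod
    def _env_of_real(
        x: np.ndarray, ref: AnalyticSeries, source: AnalyticSeries
    ) -> np.ndarray:
        """Amplitude envelope of an orthogonalized (real) series.

        A residual that is negligible relative to the orthogonalized
        signal's own amplitude (collinear channels leave only rounding
        noise) is treated as exactly zero.
        """
        scale = np.abs(source.values).max(initial=0.0)
        if np.ptp(x) == 0 or np.abs(x).max(initial=0.0) <= 1e-10 * scale:
            return np.zeros_like(x)
        return np.abs(analytic_signal(x, ref.fs, ref.band).values)

    def _windows(self, n: int, trim: int) -> list[slice]:
        lo, hi = trim, n - trim
        if self.n_windows <= 1:
            return [slice(lo, hi)]
        edges = np.linspace(lo, hi, self.n_windows + 1).astype(int)
        return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def orthogonalized_aec_matrix(
    ts: RegionTimeSeries, band: str | BandSpec, **kwargs
) -> ConnectivityMatrix:
    """One orthogonalized-AEC adjacency matrix for a recording."""
    return AECConnectivity(band=band, orthogonalize=True, **kwargs).transform(ts)


def plain_aec_matrix(
    ts: RegionTimeSeries, band: str | BandSpec, **kwargs
) -> ConnectivityMatrix:
    """Plain (non-orthogonalized) AEC adjacency matrix."""
    return AECConnectivity(band=band, orthogonalize=False, **kwargs).transform(ts)


def write_matrix(path: str | Path, m: ConnectivityMatrix) -> None:
    """Write a matrix as a delimited square table with a label header."""
    df = pd.DataFrame(m.weights, index=m.region_labels, columns=m.region_labels)
    df.to_csv(path, float_format="%.17g")


def read_matrix(
    path: str | Path,
    band: str | BandSpec,
    subject: str = "",
    condition: str = "",
) -> ConnectivityMatrix:
    """Read a matrix written by :func:`write_matrix`; rejects asymmetry."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels disagree")
    w = df.to_numpy(dtype=float)
    if not np.isfinite(w).all():
        raise ValueError(f"{path}: non-finite weights")
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError(f"{path}: matrix payload is not symmetric")
    return ConnectivityMatrix(
        weights=0.5 * (w + w.T),
        band=get_band(band),
        subject=subject,
        condition=condition,
        region_labels=[str(c) for c in df.columns],
    )
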