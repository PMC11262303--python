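"""Region-level time-series container and hierarchical-store I/O.

A :class:`RegionTimeSeries` is the pipeline's entry point: one matrix of
``n_regions x n_samples`` real samples for a single subject and condition,
with the sampling rate and the ordered region labels attached. Collections
of recordings are persisted to an HDF5 store with one group per
``subject/condition`` holding ``data``, ``fs`` and ``labels`` datasets.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np


def region_labels(printed: bool = False) -> list[str]:
    """The 61 emotion-network region labels.

    The published region table contains two visible duplicates
    (``R Hippocampus`` and ``L Ant OFC`` each appear twice) while their
    contralateral counterparts (``L Hippocampus``, ``R Ant OFC``) are
    absent. The canonical list (default) restores the missing
    counterparts so that all 61 labels are unique; ``printed=True``
    returns the list verbatim as published, duplicates included.
    """
    name = "region_labels_printed.txt" if printed else "region_labels.txt"
    text = resources.files("aecnet.data").joinpath(name).read_text()
    return [line for line in text.splitlines() if line.strip()]


@dataclass
class RegionTimeSeries:
    """Multichannel recording for one subject x condition.

    Attributes
    ----------
    data : ndarray, shape (n_regions, n_samples)
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Unique region labels, one per row of ``data``.
    subject, condition : str
    """

    data: np.ndarray
    fs: float
    labels: list[str] = field(default_factory=list)
    subject: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (regions x samples)")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.labels:
            self.labels = [f"region{i:03d}" for i in range(self.n_regions)]
        if len(self.labels) != self.n_regions:
            raise ValueError("label count does not match region count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("region labels must be unique")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def write_recordings(path: str | Path, recordings: list[RegionTimeSeries]) -> None:
    """Write recordings to an HDF5 store, one group per subject/condition."""
    with h5py.File(path, "w") as f:
        for rec in recordings:
            grp = f.require_group(rec.subject).create_group(rec.condition)
            grp.create_dataset("data", data=rec.data)
            grp.create_dataset("fs", data=float(rec.fs))
            grp.create_dataset(
                "labels", data=np.array(rec.labels, dtype=h5py.string_dtype())
            )


def read_recordings(path: str | Path) -> Iterator[RegionTimeSeries]:
    """Iterate recordings from a store written by :func:`write_recordings`."""
    with h5py.File(path, "r") as f:
        for subject in sorted(f):
            for condition in sorted(f[subject]):
                grp = f[subject][condition]
                yield RegionTimeSeries(
                    data=grp["data"][()],
                    fs=float(grp["fs"][()]),
                    labels=[s.decode() for s in grp["labels"][()]],
                    subject=subject,
                    condition=condition,
                )
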