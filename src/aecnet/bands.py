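"""Canonical frequency-band definitions.

The five bands follow the convention widespread in MEG/EEG connectivity
work (and used by the Brainstorm software): delta 2-4 Hz, theta 5-7 Hz,
alpha 8-12 Hz, beta 15-29 Hz, gamma 30-59 Hz.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with inclusive edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band edges: {self.low}-{self.high} Hz")

    @property
    def span(self) -> float:
        return self.high - self.low

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    def validate_for(self, fs: float) -> None:
        """Check the band sits below the Nyquist frequency of ``fs``."""
        if self.high >= fs / 2:
            raise ValueError(
                f"band {self.name} ({self.low}-{self.high} Hz) reaches or "
                f"exceeds Nyquist ({fs / 2} Hz)"
            )


#: The canonical band table. Edges are exact as conventionally printed.
CANONICAL_BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 2.0, 4.0),
    "theta": BandSpec("theta", 5.0, 7.0),
    "alpha": BandSpec("alpha", 8.0, 12.0),
    "beta": BandSpec("beta", 15.0, 29.0),
    "gamma": BandSpec("gamma", 30.0, 59.0),
}

BAND_ORDER = ("delta", "theta", "alpha", "beta", "gamma")


def get_band(name: str | BandSpec) -> BandSpec:
    """Resolve a band name (or pass a BandSpec through)."""
    if isinstance(name, BandSpec):
        return name
    try:
        return CANONICAL_BANDS[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; expected one of {sorted(CANONICAL_BANDS)}"
        ) from None
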