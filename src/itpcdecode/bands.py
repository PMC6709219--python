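"""Canonical oscillatory frequency bands.

The analysis operates on five fixed bands spanning alpha through high
gamma; every band-limited container carries a :class:`BandSpec` so that
downstream stages (ITPC, decoding, cluster tables) can report which band
they describe.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BandSpec", "CANONICAL_BANDS", "band"]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(
                f"band edges must satisfy 0 < low < high, got ({self.low}, {self.high})"
            )

    @property
    def width(self) -> float:
        return self.high - self.low

    def contains(self, freq: float) -> bool:
        return self.low <= freq <= self.high


#: The five canonical bands used throughout the pipeline (Hz).
CANONICAL_BANDS: dict[str, BandSpec] = {
    "alpha": BandSpec("alpha", 8.0, 12.0),
    "beta": BandSpec("beta", 13.0, 30.0),
    "gamma_low": BandSpec("gamma_low", 30.0, 45.0),
    "gamma_medium": BandSpec("gamma_medium", 55.0, 70.0),
    "gamma_high": BandSpec("gamma_high", 70.0, 90.0),
}


def band(name_or_spec: str | BandSpec) -> BandSpec:
    """Resolve a band name or pass a :class:`BandSpec` through."""
    if isinstance(name_or_spec, BandSpec):
        return name_or_spec
    try:
        return CANONICAL_BANDS[name_or_spec]
    except KeyError:
        raise KeyError(
            f"unknown band {name_or_spec!r}; known bands: {sorted(CANONICAL_BANDS)}"
        ) from None
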