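"""Canonical EEG frequency-band definitions.

Five classical bands cover the 0.5-30 Hz range analysed throughout the
package: delta (0.5-4 Hz), theta (4-8 Hz), alpha (8-13 Hz), beta1
(13-20 Hz) and beta2 (20-30 Hz). Greek spellings are accepted as aliases
everywhere a band name is taken.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo, hi] in Hz with 0 < lo < hi <= 30."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi <= 30):
            raise ValueError(
                f"band {self.name!r}: require 0 < lo < hi <= 30, got "
                f"lo={self.lo}, hi={self.hi}"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)

    @property
    def width(self) -> float:
        return self.hi - self.lo


#: Greek / unicode aliases accepted for band names.
BAND_ALIASES = {
    "δ": "delta",
    "θ": "theta",
    "α": "alpha",
    "β1": "beta1",
    "β2": "beta2",
}

DEFAULT_BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 0.5, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta1": BandDefinition("beta1", 13.0, 20.0),
    "beta2": BandDefinition("beta2", 20.0, 30.0),
}

BAND_ORDER = tuple(DEFAULT_BANDS)

#: Layer bands of the multilayer / improved-multilayer networks.
MULTILAYER_BANDS = ("alpha", "beta1", "beta2")


def canonical_band_name(name: str) -> str:
    """Resolve a band name or Greek alias to its canonical ascii name."""
    name = BAND_ALIASES.get(name, name)
    if name not in DEFAULT_BANDS:
        valid = sorted(DEFAULT_BANDS) + sorted(BAND_ALIASES)
        raise KeyError(f"unknown band {name!r}; valid names: {valid}")
    return name


def get_band(name: str) -> BandDefinition:
    return DEFAULT_BANDS[canonical_band_name(name)]
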