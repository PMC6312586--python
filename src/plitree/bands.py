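"""Canonical frequency-band definitions.

The five defaults are the standard clinical MEG/EEG bands used throughout the
pipeline: delta 0.5-4, theta 4-8, alpha 8-13, beta 13-30 and gamma 30-48 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_low, f_high] in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self):
        if not (0 < self.f_low < self.f_high):
            raise InvalidParameterError(
                f"band {self.name!r}: need 0 < f_low < f_high, "
                f"got ({self.f_low}, {self.f_high})"
            )

    @property
    def centre(self) -> float:
        return 0.5 * (self.f_low + self.f_high)

    @property
    def width(self) -> float:
        return self.f_high - self.f_low


DELTA = BandDefinition("delta", 0.5, 4.0)
THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 13.0)
BETA = BandDefinition("beta", 13.0, 30.0)
GAMMA = BandDefinition("gamma", 30.0, 48.0)

DEFAULT_BANDS: tuple[BandDefinition, ...] = (DELTA, THETA, ALPHA, BETA, GAMMA)

_BY_NAME = {b.name: b for b in DEFAULT_BANDS}


def band_by_name(name: str) -> BandDefinition:
    """Look up one of the five default bands by its lower-case name."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown band {name!r}; known bands: {sorted(_BY_NAME)}"
        ) from None
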