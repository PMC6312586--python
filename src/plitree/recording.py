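"""In-memory containers for multichannel time series and derived phase data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError


@dataclass
class Recording:
    """A (channels x samples) source-space time series.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal values, arbitrary amplitude units.
    fs : float
        Sampling rate in Hz.
    labels : sequence of str
        One region name per channel (AAL convention for 90-ROI data).
    """

    data: np.ndarray
    fs: float
    labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidInputError(
                f"recording data must be 2-D (channels x samples), got {self.data.ndim}-D"
            )
        if self.data.shape[1] < 1:
            raise InvalidInputError("recording must contain at least one sample")
        if self.fs <= 0:
            raise InvalidInputError(f"sampling rate must be positive, got {self.fs}")
        if not self.labels:
            self.labels = tuple(f"ch{i}" for i in range(self.data.shape[0]))
        self.labels = tuple(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise InvalidInputError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Epoch:
    """One fixed-length window cut from a Recording (default 8 s)."""

    data: np.ndarray
    fs: float
    index: int
    labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidInputError("epoch data must be 2-D (channels x samples)")
        if not self.labels:
            self.labels = tuple(f"ch{i}" for i in range(self.data.shape[0]))
        self.labels = tuple(self.labels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class PhaseSeries:
    """Instantaneous phases (channels x samples), wrapped to [-pi, pi]."""

    phases: np.ndarray
    fs: float
    labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 2:
            raise InvalidInputError("phases must be 2-D (channels x samples)")
        if not self.labels:
            self.labels = tuple(f"ch{i}" for i in range(self.phases.shape[0]))
        self.labels = tuple(self.labels)

    @property
    def n_channels(self) -> int:
        return self.phases.shape[0]

    @property
    def n_samples(self) -> int:
        return self.phases.shape[1]
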