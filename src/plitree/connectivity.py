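"""Phase Lag Index (PLI) connectivity.

The PLI between two phase series is

    PLI = | < sign( sin( dPhi(t_k) ) ) >_k |

where dPhi is the instantaneous phase difference (wrapped to [-pi, pi]) and
< > averages over samples.  The sign statistic discards phase differences of
exactly 0 or pi, so common zero-lag components (volume conduction) do not
contribute: PLI = 0 for identical signals and PLI = 1 for a constant nonzero
lag.  sign(0) is taken as 0 (the signum convention), which makes identical
channels give exactly 0 rather than an arbitrary +-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import BandDefinition
from .errors import InvalidInputError
from .recording import PhaseSeries

try:  # optional JIT acceleration of the all-pairs kernel
    import numba

    @numba.njit(cache=True)
    def _pli_kernel(s: np.ndarray, c: np.ndarray) -> np.ndarray:  # pragma: no cover
        n_ch, n_s = s.shape
        out = np.zeros((n_ch, n_ch))
        for i in range(n_ch - 1):
            for j in range(i + 1, n_ch):
                acc = 0
                for t in range(n_s):
                    x = s[i, t] * c[j, t] - c[i, t] * s[j, t]
                    if x > 0:
                        acc += 1
                    elif x < 0:
                        acc -= 1
                out[i, j] = abs(acc) / n_s
                out[j, i] = out[i, j]
        return out

except ImportError:  # pragma: no cover
    _pli_kernel = None

AVERAGED = "averaged"


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative N x N PLI adjacency over regions."""

    values: np.ndarray
    band: BandDefinition | None = None
    epoch_index: int | str | None = None
    labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise InvalidInputError(
                f"connectivity matrix must be square, got shape {self.values.shape}"
            )
        if not self.labels:
            self.labels = tuple(f"ch{i}" for i in range(self.values.shape[0]))
        self.labels = tuple(self.labels)
        if len(self.labels) != self.values.shape[0]:
            raise InvalidInputError("label count does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def pli_pair(phase_i: np.ndarray, phase_j: np.ndarray) -> float:
    """PLI between two phase vectors.

    sin is 2*pi-periodic, so the sign of sin(dPhi) is unaffected by which
    wrapping convention is applied to the raw difference; no explicit wrap
    is needed.
    """
    phase_i = np.asarray(phase_i, dtype=float).ravel()
    phase_j = np.asarray(phase_j, dtype=float).ravel()
    if phase_i.shape != phase_j.shape:
        raise InvalidInputError(
            f"phase vectors have different lengths: {phase_i.size} vs {phase_j.size}"
        )
    if phase_i.size == 0:
        raise InvalidInputError("phase vectors must contain at least one sample")
    return float(np.abs(np.mean(np.sign(np.sin(phase_i - phase_j)))))


def pli_matrix(
    phases: PhaseSeries | np.ndarray,
    band: BandDefinition | None = None,
    epoch_index: int | str | None = None,
) -> ConnectivityMatrix:
    """All-pairs PLI for a (channels x samples) phase array.

    Uses sin(a - b) = sin(a)cos(b) - cos(a)sin(b) to evaluate the sign
    statistic for whole rows at once; identical channels still yield an
    exact 0 because the product form cancels exactly.
    """
    if isinstance(phases, PhaseSeries):
        labels = phases.labels
        ph = phases.phases
    else:
        ph = np.asarray(phases, dtype=float)
        labels = ()
    if ph.ndim != 2:
        raise InvalidInputError("phases must be 2-D (channels x samples)")
    n_ch, n_s = ph.shape
    if n_ch < 2:
        raise InvalidInputError(f"need at least 2 channels, got {n_ch}")
    if n_s < 1:
        raise InvalidInputError("need at least one sample")
    s = np.sin(ph)
    c = np.cos(ph)
    if _pli_kernel is not None:
        out = _pli_kernel(np.ascontiguousarray(s), np.ascontiguousarray(c))
    else:
        out = np.zeros((n_ch, n_ch))
        for i in range(n_ch - 1):
            cross = s[i] * c[i + 1 :] - c[i] * s[i + 1 :]
            out[i, i + 1 :] = np.abs(np.mean(np.sign(cross), axis=1))
        out += out.T
    return ConnectivityMatrix(
        values=out, band=band, epoch_index=epoch_index, labels=labels
    )


def average_matrices(mats: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise arithmetic mean of per-epoch matrices, marked 'averaged'."""
    if not mats:
        raise InvalidInputError("cannot average an empty list of matrices")
    first = mats[0]
    for m in mats[1:]:
        if m.values.shape != first.values.shape:
            raise InvalidInputError("matrices to average have mismatched shapes")
        if (m.band is None) != (first.band is None) or (
            m.band is not None and m.band.name != first.band.name
        ):
            raise InvalidInputError("cannot average matrices from different bands")
    mean = np.mean([m.values for m in mats], axis=0)
    return ConnectivityMatrix(
        values=mean, band=first.band, epoch_index=AVERAGED, labels=first.labels
    )
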