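"""Band-limiting, epoch segmentation, resampling and instantaneous phase.

Filtering is a 4th-order Butterworth band-pass applied forward-backward
(zero phase) by default.  One-pass causal filtering distorts instantaneous
phase estimates, which is exactly what the downstream Phase Lag Index is
computed from, so zero-phase is the default; a one-pass option is kept for
comparison.  Instantaneous phase is the argument of the analytic signal
(Hilbert transform), computed per channel on each epoch.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from .bands import BandDefinition
from .errors import InsufficientDataError, InvalidParameterError
from .recording import Epoch, PhaseSeries, Recording


def butter_sos(band: BandDefinition, fs: float, order: int = 4) -> np.ndarray:
    """Second-order sections of the band-pass filter used by :func:`bandpass`."""
    if band.f_high >= fs / 2:
        raise InvalidParameterError(
            f"band edge {band.f_high} Hz at or above Nyquist ({fs / 2} Hz)"
        )
    return signal.butter(
        order, [band.f_low, band.f_high], btype="bandpass", fs=fs, output="sos"
    )


def bandpass(
    rec: Recording,
    band: BandDefinition,
    order: int = 4,
    zero_phase: bool = True,
) -> Recording:
    """Band-pass filter every channel of a recording.

    Zero-phase (forward-backward) filtering squares the Butterworth magnitude
    response, so the effective magnitude order is twice ``order`` while the
    phase response is identically zero.
    """
    sos = butter_sos(band, rec.fs, order=order)
    if zero_phase:
        filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    else:
        filtered = signal.sosfilt(sos, rec.data, axis=1)
    return Recording(data=filtered, fs=rec.fs, labels=rec.labels)


def segment_epochs(
    rec: Recording,
    epoch_seconds: float = 8.0,
    n_epochs: int = 10,
    artifact_mask: np.ndarray | None = None,
) -> list[Epoch]:
    """Cut the first ``n_epochs`` clean, non-overlapping windows.

    Windows are scanned in temporal order; a window is clean when no sample
    inside it is flagged by ``artifact_mask`` (True = artifact).  After a
    clean window is taken the scan resumes at its end, so with no mask the
    selected epochs tile the start of the recording exactly.

    Raises
    ------
    InsufficientDataError
        If fewer than ``n_epochs`` clean windows exist; the error reports the
        count that was found.
    """
    if epoch_seconds <= 0 or n_epochs < 1:
        raise InvalidParameterError("epoch_seconds and n_epochs must be positive")
    win = int(round(epoch_seconds * rec.fs))
    if win < 1:
        raise InvalidParameterError("epoch shorter than one sample")
    mask = None
    if artifact_mask is not None:
        mask = np.asarray(artifact_mask, dtype=bool)
        if mask.shape != (rec.n_samples,):
            raise InvalidParameterError(
                f"artifact mask length {mask.shape} does not match "
                f"{rec.n_samples} samples"
            )
    epochs: list[Epoch] = []
    start = 0
    while start + win <= rec.n_samples and len(epochs) < n_epochs:
        if mask is not None:
            bad = np.flatnonzero(mask[start : start + win])
            if bad.size:
                # jump past the last artefactual sample in this window
                start += int(bad[-1]) + 1
                continue
        epochs.append(
            Epoch(
                data=rec.data[:, start : start + win].copy(),
                fs=rec.fs,
                index=len(epochs),
                labels=rec.labels,
            )
        )
        start += win
    if len(epochs) < n_epochs:
        raise InsufficientDataError(
            f"only {len(epochs)} clean epochs of {epoch_seconds} s available, "
            f"{n_epochs} requested",
            found=len(epochs),
            requested=n_epochs,
        )
    return epochs


def resample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased polyphase resampling to ``target_fs`` Hz.

    The rate ratio is approximated by a rational number; for the typical
    1024 -> 512 Hz case the ratio is exact.
    """
    if target_fs <= 0:
        raise InvalidParameterError(f"target_fs must be positive, got {target_fs}")
    if target_fs == rec.fs:
        return Recording(data=rec.data.copy(), fs=rec.fs, labels=rec.labels)
    ratio = Fraction(target_fs / rec.fs).limit_denominator(1 << 16)
    out = signal.resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=1)
    return Recording(data=out, fs=target_fs, labels=rec.labels)


def instantaneous_phase(ep: Epoch) -> PhaseSeries:
    """Instantaneous phase of each channel via the analytic signal.

    No edge samples are trimmed by default: the sign statistic downstream is
    robust to mild edge distortion of the Hilbert transform, and the
    connectivity definition averages over all samples of the epoch.
    """
    analytic = signal.hilbert(ep.data, axis=1)
    return PhaseSeries(phases=np.angle(analytic), fs=ep.fs, labels=ep.labels)
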