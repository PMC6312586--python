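"""Synthetic source-space recordings with known phase-coupling structure.

The generator emulates resting-state ROI time series as they would arrive
from a beamformer: 90 regions at 512 Hz, ten 8-second epochs per subject.
Each planted coupling is driven by a latent narrowband oscillator whose
unwrapped phase theta(t) accumulates increments 2*pi*(f_c + eps_t)/fs with
Gaussian frequency noise eps_t.  The source region carries cos(theta), the
target carries amplitude * cos(theta + lag + eta(t)), where the phase jitter
eta is a stationary Ornstein-Uhlenbeck process with marginal sd
``jitter_sd`` (wrapped implicitly by the cosine).  The jitter is temporally
correlated (default tau = 0.3 s) on purpose: white per-sample phase jitter
sits almost entirely outside the analysis bands and would be removed by the
band-pass filter, leaving the Phase Lag Index insensitive to it.  All
regions additionally receive independent broadband Gaussian noise.

Two cohorts (default 26 vs 29 subjects) share identical baseline couplings
and differ only in the jitter of the couplings around one planted hub
region (default Hippocampus_R, 10 partners, theta band): group A couples
tightly (jitter 0.1 rad), group B loosely (1.5 rad).  All hub couplings
share one lag value, drawn once from [0.1*pi, 0.9*pi]: partner-partner phase
differences then sit near zero and are discarded by the PLI's zero-lag
blindness, so the planted structure is a PLI hub, not a clique.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .atlas import RIGHT_HIPPOCAMPUS_INDEX, default_labels
from .bands import THETA, BandDefinition
from .errors import InvalidParameterError
from .recording import Recording

#: correlation time (s) of the Ornstein-Uhlenbeck phase jitter
JITTER_TAU = 0.3
#: sd (Hz) of the per-sample frequency noise of latent oscillators
OSC_FREQ_JITTER_SD = 0.3


@dataclass(frozen=True)
class CouplingSpec:
    """One directed phase coupling between two regions in one band."""

    source_node: int
    target_node: int
    band: BandDefinition
    lag: float
    jitter_sd: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self):
        if self.source_node == self.target_node:
            raise InvalidParameterError("coupling source and target must differ")
        if not (0.0 < self.lag < np.pi):
            raise InvalidParameterError(
                f"lag must lie strictly in (0, pi); got {self.lag} "
                "(zero/pi lags are invisible to the PLI by construction)"
            )
        if self.jitter_sd < 0:
            raise InvalidParameterError("jitter_sd must be >= 0")
        if self.amplitude <= 0:
            raise InvalidParameterError("amplitude must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a two-cohort synthetic dataset."""

    n_group_a: int = 26
    n_group_b: int = 29
    n_rois: int = 90
    fs: float = 512.0
    epoch_seconds: float = 8.0
    n_epochs: int = 10
    baseline_couplings: tuple[CouplingSpec, ...] = field(default_factory=tuple)
    planted_hub: int = RIGHT_HIPPOCAMPUS_INDEX
    hub_partners: int = 10
    hub_band: BandDefinition = THETA
    hub_jitter_a: float = 0.1
    hub_jitter_b: float = 1.5
    hub_amplitude: float = 0.35
    noise_sd: float = 0.5
    background_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise InvalidParameterError("group sizes must be >= 2")
        if not (0 <= self.planted_hub < self.n_rois):
            raise InvalidParameterError("planted_hub must be a valid region index")
        if self.hub_partners >= self.n_rois:
            raise InvalidParameterError(
                f"hub_partners ({self.hub_partners}) must be < n_rois ({self.n_rois})"
            )
        if self.hub_jitter_a > self.hub_jitter_b:
            raise InvalidParameterError(
                "hub_jitter_a must be <= hub_jitter_b (group A is the tightly "
                "coupled cohort)"
            )
        if self.fs <= 0 or self.epoch_seconds <= 0 or self.n_epochs < 1:
            raise InvalidParameterError("fs, epoch_seconds, n_epochs must be positive")
        if self.noise_sd < 0 or self.background_sd < 0:
            raise InvalidParameterError("noise_sd and background_sd must be >= 0")
        if self.hub_amplitude <= 0:
            raise InvalidParameterError("hub_amplitude must be > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.n_epochs * self.epoch_seconds * self.fs))


def generate_phase_process(
    f_center: float,
    duration: float,
    fs: float,
    freq_jitter_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    phi0: float = 0.0,
) -> np.ndarray:
    """Unwrapped phase of a noisy oscillator.

    Increments are 2*pi*(f_center + eps_t)/fs with eps_t iid N(0,
    freq_jitter_sd^2), i.e. the phase performs a drifting random walk around
    a linear ramp of slope 2*pi*f_center/fs per sample.
    """
    if fs <= 0 or duration < 0:
        raise InvalidParameterError("fs must be positive and duration nonnegative")
    if fs <= 2 * f_center:
        raise InvalidParameterError(
            f"fs = {fs} must exceed twice the oscillator frequency {f_center}"
        )
    n = int(round(duration * fs))
    if n == 0:
        return np.empty(0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = f_center + (
        rng.normal(0.0, freq_jitter_sd, size=n) if freq_jitter_sd > 0 else 0.0
    )
    return phi0 + np.cumsum(2.0 * np.pi * freqs / fs)


def _ou_series(
    n: int, sd: float, fs: float, rng: np.random.Generator, tau: float = JITTER_TAU
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck (AR(1)) series with marginal sd ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    rho = float(np.exp(-1.0 / (tau * fs)))
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), size=n)
    x0 = rng.normal(0.0, sd)
    out, _ = lfilter([1.0], [1.0, -rho], innov, zi=np.array([rho * x0]))
    return out


def _pink_noise(
    n: int,
    sd: float,
    fs: float,
    rng: np.random.Generator,
    exponent: float = 1.0,
    f_min: float = 0.5,
) -> np.ndarray:
    """1/f^exponent background noise, spectrum flattened below ``f_min`` Hz.

    This is the ongoing broadband rhythm every region carries: its phase in
    any narrow analysis band dwells and drifts the way resting-state
    oscillations do, which sets a realistic fluctuation floor for the PLI.
    """
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    white = rng.normal(size=n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.zeros_like(freqs)
    nz = freqs > 0
    scale[nz] = np.maximum(freqs[nz], f_min) ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * scale, n=n)
    return x * (sd / x.std())


def _structural_rng(spec: CohortSpec) -> np.random.Generator:
    """RNG for dataset-level structure shared by every subject in both groups."""
    return np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5A11]))


def hub_partner_nodes(spec: CohortSpec) -> np.ndarray:
    """The hub's partner set: fixed by spec.seed, identical for all subjects."""
    rng = _structural_rng(spec)
    candidates = np.setdiff1d(np.arange(spec.n_rois), [spec.planted_hub])
    return np.sort(rng.choice(candidates, size=spec.hub_partners, replace=False))


def hub_couplings(spec: CohortSpec, group_jitter: float) -> tuple[CouplingSpec, ...]:
    """Hub-to-partner couplings with one shared lag, drawn from spec.seed."""
    rng = _structural_rng(spec)
    candidates = np.setdiff1d(np.arange(spec.n_rois), [spec.planted_hub])
    partners = np.sort(rng.choice(candidates, size=spec.hub_partners, replace=False))
    lag = rng.uniform(0.1 * np.pi, 0.9 * np.pi)
    return tuple(
        CouplingSpec(
            source_node=spec.planted_hub,
            target_node=int(p),
            band=spec.hub_band,
            lag=float(lag),
            jitter_sd=group_jitter,
            amplitude=spec.hub_amplitude,
        )
        for p in partners
    )


def _oscillator_frequency(spec: CohortSpec, source: int, band: BandDefinition) -> float:
    """Carrier frequency of the (source, band) oscillator, fixed across subjects.

    Drawn from the central half of the band so that distinct oscillators are
    spectrally separated and stay away from the filter skirts.
    """
    band_key = zlib.crc32(band.name.encode()) & 0x7FFFFFFF  # stable across runs
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 0xF0, source, band_key])
    )
    lo = band.f_low + 0.25 * band.width
    hi = band.f_high - 0.25 * band.width
    return float(rng.uniform(lo, hi))


def generate_subject(
    spec: CohortSpec,
    group_jitter: float,
    subject_seed: int | np.random.SeedSequence,
) -> tuple[Recording, pd.DataFrame]:
    """One subject's recording plus its ground-truth coupling table.

    The coupling structure (partner set, lags, oscillator frequencies) is a
    deterministic function of ``spec.seed``; the signal realisation (noise,
    oscillator phases, jitter paths) is driven by ``subject_seed``.
    """
    couplings = tuple(spec.baseline_couplings)
    if spec.hub_partners > 0:
        couplings = couplings + hub_couplings(spec, group_jitter)
    keys = [(c.source_node, c.target_node, c.band.name) for c in couplings]
    if len(keys) != len(set(keys)):
        raise InvalidParameterError("duplicate (source, target, band) couplings")
    for c in couplings:
        if not (0 <= c.source_node < spec.n_rois and 0 <= c.target_node < spec.n_rois):
            raise InvalidParameterError("coupling node index out of range")

    rng = (
        np.random.default_rng(subject_seed)
        if not isinstance(subject_seed, np.random.Generator)
        else subject_seed
    )
    n = spec.n_samples
    duration = n / spec.fs
    data = (
        rng.normal(0.0, spec.noise_sd, size=(spec.n_rois, n))
        if spec.noise_sd > 0
        else np.zeros((spec.n_rois, n))
    )
    if spec.background_sd > 0:
        for ch in range(spec.n_rois):
            data[ch] += _pink_noise(n, spec.background_sd, spec.fs, rng)

    # one latent oscillator per (source, band); realisation is per subject
    oscillators: dict[tuple[int, str], np.ndarray] = {}
    records = []
    for c in couplings:
        key = (c.source_node, c.band.name)
        if key not in oscillators:
            f_c = _oscillator_frequency(spec, c.source_node, c.band)
            theta = generate_phase_process(
                f_c,
                duration,
                spec.fs,
                freq_jitter_sd=OSC_FREQ_JITTER_SD,
                seed=rng,
                phi0=rng.uniform(0.0, 2.0 * np.pi),
            )
            oscillators[key] = theta
            data[c.source_node] += np.cos(theta)
        theta = oscillators[key]
        eta = _ou_series(n, c.jitter_sd, spec.fs, rng)
        data[c.target_node] += c.amplitude * np.cos(theta + c.lag + eta)
        records.append(
            {
                "source": c.source_node,
                "target": c.target_node,
                "band": c.band.name,
                "lag": c.lag,
                "jitter_sd": c.jitter_sd,
                "amplitude": c.amplitude,
            }
        )

    rec = Recording(data=data, fs=spec.fs, labels=default_labels(spec.n_rois))
    truth = pd.DataFrame(
        records, columns=["source", "target", "band", "lag", "jitter_sd", "amplitude"]
    )
    return rec, truth


def generate_cohorts(
    spec: CohortSpec,
) -> tuple[list[Recording], list[Recording], dict]:
    """Both cohorts plus a ground-truth manifest.

    Group A subjects use ``hub_jitter_a`` on the hub couplings, group B
    ``hub_jitter_b``.  Per-subject seeds are spawned from ``spec.seed`` so
    identical specs give bit-identical datasets.
    """
    ss = np.random.SeedSequence([spec.seed, 0xC047])
    children = ss.spawn(spec.n_group_a + spec.n_group_b)
    group_a: list[Recording] = []
    group_b: list[Recording] = []
    truth_frames = []
    for k in range(spec.n_group_a):
        rec, truth = generate_subject(spec, spec.hub_jitter_a, children[k])
        truth = truth.assign(group="A", subject=k)
        group_a.append(rec)
        truth_frames.append(truth)
    for k in range(spec.n_group_b):
        rec, truth = generate_subject(
            spec, spec.hub_jitter_b, children[spec.n_group_a + k]
        )
        truth = truth.assign(group="B", subject=k)
        group_b.append(rec)
        truth_frames.append(truth)

    labels = default_labels(spec.n_rois)
    partners = hub_partner_nodes(spec)
    manifest = {
        "n_group_a": spec.n_group_a,
        "n_group_b": spec.n_group_b,
        "n_rois": spec.n_rois,
        "fs": spec.fs,
        "epoch_seconds": spec.epoch_seconds,
        "n_epochs": spec.n_epochs,
        "seed": spec.seed,
        "planted_hub": int(spec.planted_hub),
        "planted_hub_label": labels[spec.planted_hub],
        "hub_partners": [int(p) for p in partners],
        "hub_band": spec.hub_band.name,
        "hub_jitter_a": spec.hub_jitter_a,
        "hub_jitter_b": spec.hub_jitter_b,
        "noise_sd": spec.noise_sd,
        "couplings": pd.concat(truth_frames, ignore_index=True).to_dict("records"),
        "expected_difference": (
            "MST degree of the planted hub in the hub band is higher in group A "
            "than in group B"
            if spec.hub_jitter_a < spec.hub_jitter_b
            else "groups are exchangeable (no planted difference)"
        ),
    }
    return group_a, group_b, manifest


def null_spec(spec: CohortSpec) -> CohortSpec:
    """The same study conditions with no planted group difference."""
    return replace(spec, hub_jitter_b=spec.hub_jitter_a)
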