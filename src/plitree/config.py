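"""Pipeline configuration.

Defaults reproduce the reference analysis settings: five clinical bands,
512 Hz, ten 8-second epochs, 10,000 label permutations, alpha = 0.05,
per-epoch minimum spanning trees with metrics averaged across epochs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .bands import DEFAULT_BANDS, BandDefinition, band_by_name
from .errors import ConfigurationError

MST_MODES = ("per-epoch", "averaged-matrix")
TH_MODES = ("default", "literal")
FDR_FAMILIES = ("per-band-metric", "pooled")


@dataclass(frozen=True)
class PipelineConfig:
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    fs_target: float = 512.0
    epoch_seconds: float = 8.0
    n_epochs: int = 10
    n_perm: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    mst_mode: str = "per-epoch"
    th_mode: str = "default"
    fdr_family: str = "per-band-metric"
    #: broadband pre-filter applied before the per-band filters; None disables
    pre_band: tuple[float, float] | None = (0.5, 48.0)
    #: zero-phase (forward-backward) band-pass filtering
    zero_phase: bool = True

    def __post_init__(self):
        if not self.bands:
            raise ConfigurationError("at least one band is required")
        if self.mst_mode not in MST_MODES:
            raise ConfigurationError(
                f"mst_mode must be one of {MST_MODES}, got {self.mst_mode!r}"
            )
        if self.th_mode not in TH_MODES:
            raise ConfigurationError(
                f"th_mode must be one of {TH_MODES}, got {self.th_mode!r}"
            )
        if self.fdr_family not in FDR_FAMILIES:
            raise ConfigurationError(
                f"fdr_family must be one of {FDR_FAMILIES}, got {self.fdr_family!r}"
            )
        if not (0 < self.alpha < 1):
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_perm < 1 or self.n_epochs < 1:
            raise ConfigurationError("n_perm and n_epochs must be positive")
        for b in self.bands:
            if b.f_high >= self.fs_target / 2:
                raise ConfigurationError(
                    f"band {b.name!r} upper edge {b.f_high} Hz at or above "
                    f"Nyquist for fs_target = {self.fs_target} Hz"
                )

    def to_dict(self) -> dict:
        return {
            "bands": [[b.name, b.f_low, b.f_high] for b in self.bands],
            "fs_target": self.fs_target,
            "epoch_seconds": self.epoch_seconds,
            "n_epochs": self.n_epochs,
            "n_perm": self.n_perm,
            "alpha": self.alpha,
            "seed": self.seed,
            "mst_mode": self.mst_mode,
            "th_mode": self.th_mode,
            "fdr_family": self.fdr_family,
            "pre_band": list(self.pre_band) if self.pre_band else None,
            "zero_phase": self.zero_phase,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        bands = d.pop("bands", None)
        if bands is not None:
            parsed = []
            for item in bands:
                if isinstance(item, str):
                    parsed.append(band_by_name(item))
                else:
                    name, lo, hi = item
                    parsed.append(BandDefinition(str(name), float(lo), float(hi)))
            d["bands"] = tuple(parsed)
        pre = d.get("pre_band")
        if pre is not None:
            d["pre_band"] = (float(pre[0]), float(pre[1]))
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
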