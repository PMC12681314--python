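"""Run configuration: every tunable of the pipeline with documented defaults.

The default acquisition mirrors the sequence this package models — TR 2.5 ms,
128 points per spoke, 280 mm FOV, three simultaneous slices, 25 spokes per
frame (62.5 ms temporal resolution) — at a desk-scale image grid (64 x 64,
8 synthetic coils, 40 frames) so every stage runs in seconds to minutes on
one CPU.  Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .recon import LAMBDA_DEFAULT, ReconConfig


class ConfigError(ValueError):
    """Invalid or unknown configuration values."""


@dataclass
class RunConfig:
    # geometry / sequence
    grid_size: int = 64
    n_slices: int = 3
    n_coils: int = 8
    scheme: str = "SMS_GA"
    n_frames: int = 40
    spokes_per_frame: int = 25
    points_per_spoke: int = 128
    tr_ms: float = 2.5
    fov_mm: float = 280.0
    # phantom / noise
    motion_amplitude_px: float = 6.0
    motion_period_frames: float = 20.0
    noise_level: float = 0.05  # noise SD as a fraction of the RMS k-space magnitude
    seed: int = 0
    # preprocessing
    n_virtual: int | None = None  # None = no compression
    espirit_kernel: int = 6
    espirit_sv_threshold: float = 0.01
    espirit_eig_threshold: float = 0.85
    # solver
    lam: float = LAMBDA_DEFAULT
    max_iterations: int = 50
    inner_cg_iterations: int = 10
    rho_init: float = 0.1
    residual_balance_mu: float = 10.0
    residual_balance_tau: float = 2.0
    tolerance: float = 1e-5
    cg_sense_iterations: int = 15
    median_width: int = 3

    def __post_init__(self) -> None:
        if self.grid_size < 32:
            raise ConfigError(f"grid_size must be >= 32, got {self.grid_size}")
        if self.n_slices < 1 or self.n_coils < 2:
            raise ConfigError("need n_slices >= 1 and n_coils >= 2")
        if self.scheme not in ("GA", "SMS_GA"):
            raise ConfigError(f"scheme must be GA or SMS_GA, got {self.scheme!r}")
        if self.n_frames < 2 or self.spokes_per_frame < 1:
            raise ConfigError("need n_frames >= 2 and spokes_per_frame >= 1")
        if self.n_virtual is not None and not 1 <= self.n_virtual <= self.n_coils:
            raise ConfigError(f"n_virtual must be in [1, {self.n_coils}]")
        if self.lam < 0 or self.noise_level < 0:
            raise ConfigError("lam and noise_level must be non-negative")

    @property
    def n_spokes(self) -> int:
        return self.n_frames * self.spokes_per_frame

    @property
    def pixel_size_mm(self) -> float:
        """Nominal in-plane resolution: FOV / readout points."""
        return self.fov_mm / self.points_per_spoke

    def recon_config(self) -> ReconConfig:
        return ReconConfig(
            max_iterations=self.max_iterations,
            inner_cg_iterations=self.inner_cg_iterations,
            rho_init=self.rho_init,
            residual_balance_mu=self.residual_balance_mu,
            residual_balance_tau=self.residual_balance_tau,
            tolerance=self.tolerance,
            seed=self.seed,
        )

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    # -- YAML round-trip -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)
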