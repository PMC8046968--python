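"""Run configuration: defaults, YAML loading, stable hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

#: Provenance of the upstream filament tracing (recorded, not used).
DEFAULT_TRACING_PROVENANCE = {
    "template_diameter_nm": 10.0,
    "template_length_nm": 80.0,
    "search_cone_length_nm": 50.0,
    "search_cone_angle_deg": 37.0,
    "direction_coefficient": 0.3,
}


@dataclass
class RunConfig:
    """Parameters shared across the pipeline stages."""

    bin_width: float = 2.0
    hist_max: float = 200.0
    contact_cutoff: float = 20.0
    n_simulations: int = 200
    resample_step: float = 5.0
    min_fibril_length: float = 100.0
    fibril_radius: float = 5.0
    temperature: float = 295.0
    max_tangent_separation: float = 200.0
    rotations: str = "full"  # "full" | "in_plane"
    max_retries: int = 1000
    rng_seed: int = 0
    provenance: dict = field(default_factory=lambda: dict(DEFAULT_TRACING_PROVENANCE))

    def __post_init__(self) -> None:
        for name in (
            "bin_width", "hist_max", "contact_cutoff", "resample_step",
            "min_fibril_length", "fibril_radius", "temperature",
            "max_tangent_separation",
        ):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.n_simulations < 1:
            raise ConfigurationError("n_simulations must be >= 1")
        if not self.contact_cutoff < self.hist_max:
            raise ConfigurationError(
                f"contact_cutoff {self.contact_cutoff} must be below the "
                f"histogram range {self.hist_max}"
            )
        if self.rotations not in ("full", "in_plane"):
            raise ConfigurationError("rotations must be 'full' or 'in_plane'")

    @property
    def bin_edges(self):
        import numpy as np

        n = int(round(self.hist_max / self.bin_width))
        return np.linspace(0.0, n * self.bin_width, n + 1)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Stable SHA-256 over the canonical JSON form (first 12 hex chars)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
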