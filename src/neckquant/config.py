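"""Run configuration shared by the CLI and the library pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field

from .errors import InputError, SpecError


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and conventions for a pipeline run.

    Ordering invariant: air_threshold < hu_low < hu_high < tissue_threshold,
    so the airway, fat, and body-contour definitions can never overlap.
    """

    hu_low: float = -150.0
    hu_high: float = -30.0
    air_threshold: float = -500.0
    tissue_threshold: float = -20.0
    slab_thickness_mm: float = 5.0
    quantile_convention: str = "linear"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not (self.air_threshold < self.hu_low < self.hu_high < self.tissue_threshold):
            raise InputError(
                "thresholds must satisfy air < hu_low < hu_high < tissue; got "
                f"{self.air_threshold} / {self.hu_low} / {self.hu_high} / "
                f"{self.tissue_threshold}"
            )
        if self.slab_thickness_mm <= 0:
            raise InputError("slab_thickness_mm must be > 0")
        if self.quantile_convention != "linear":
            raise InputError(f"unknown quantile convention {self.quantile_convention!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise SpecError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            try:
                payload = json.load(fh)
            except json.JSONDecodeError as exc:
                raise SpecError(f"malformed config JSON: {exc}") from exc
        return cls.from_dict(payload)

    def config_hash(self) -> str:
        """Stable short hash identifying the configuration of a run."""
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
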