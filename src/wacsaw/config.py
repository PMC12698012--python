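"""Pipeline hyperparameters and their file round trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .errors import InputError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Every knob of the classifier in one declarative object.

    Defaults follow the published procedure wherever it states a value:
    order-1 distance over 5-minute windows, thresholds recomputed per 2-day
    block, the 3 s concatenation rule, merging at alpha = 1e-25 with the
    30 s filtration exemption, 1000 resampled subsegments scored at order
    k = 20 after trimming to the middle 95%, and the 0.015/0.1
    transport-energy cut-offs.  The CPT quantile and the xi grid are this
    implementation's documented choices.
    """

    window_seconds: int = 300
    order_p: float = 1.0
    cpt_block_seconds: int = 172800
    cpt_quantile: float = 0.95
    min_segment_seconds: int = 3
    levene_alpha: float = 1e-25
    levene_long_seconds: float = 30.0
    subsegment_count: int = 1000
    min_subsegment_samples: int = 100
    energy_order_k: float = 20.0
    trim_fraction: float = 0.05
    low_cut: float = 0.015
    high_cut: float = 0.1
    xi_max: float = 500.0
    xi_points: int = 256
    rng_seed: int = 20240101

    def __post_init__(self) -> None:
        if not 0 < self.cpt_quantile < 1:
            raise InputError("cpt_quantile must lie in (0, 1)")
        if self.window_seconds <= 0 or self.cpt_block_seconds <= 0:
            raise InputError("window and block lengths must be positive")
        if not 0 <= self.trim_fraction < 1:
            raise InputError("trim_fraction must lie in [0, 1)")
        if not 0 < self.low_cut <= self.high_cut:
            raise InputError("need 0 < low_cut <= high_cut")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)
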