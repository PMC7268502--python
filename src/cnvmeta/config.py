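"""Run configuration: every tunable of the pipeline with its default.

A config can be loaded from a YAML mapping; unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .harmonize import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_CLAMP,
    DEFAULT_T2_INTERVAL,
    EqualizerParams,
)


@dataclass(frozen=True)
class ConsensusConfig:
    """Tunables of harmonisation and consensus calling.

    histogram_bin_width
        Resolution (CN units) of the frequency histograms used for bias
        and threshold estimation.
    clamp_limit
        Largest applied bias correction, in CN units.
    t2_search_interval
        CN interval searched for the T2 local minimum.
    equalizer
        Base divisor and exponent coefficient of the null-ratio equaliser.
    """

    histogram_bin_width: float = DEFAULT_BIN_WIDTH
    clamp_limit: float = DEFAULT_CLAMP
    t2_search_interval: tuple[float, float] = DEFAULT_T2_INTERVAL
    equalizer: EqualizerParams = field(default_factory=EqualizerParams)

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "ConsensusConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = dict(data)
        if "t2_search_interval" in kwargs:
            lo, hi = kwargs["t2_search_interval"]
            kwargs["t2_search_interval"] = (float(lo), float(hi))
        if "equalizer" in kwargs and not isinstance(kwargs["equalizer"], EqualizerParams):
            kwargs["equalizer"] = EqualizerParams(**kwargs["equalizer"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConsensusConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["t2_search_interval"] = list(self.t2_search_interval)
        return d
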