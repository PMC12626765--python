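"""Analysis configuration: thresholds, seeds, harmonization policy.

Defaults mirror the screening protocol: instrument p < 1e-5 (metabolite
exposures; use 5e-8 for large adiposity GWAS), clumping r² < 0.001 within
10 Mb, F > 10 retention, all sensitivity verdicts at two-sided α = 0.05, a
multiplicative random-effects IVW as the primary estimator, and no multiple
testing correction across traits (an optional Benjamini–Hochberg mode
exists but is off by default, for fidelity to the screen being modelled).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .exceptions import ConfigError
from .harmonize import HarmonizationPolicy


@dataclass
class MRConfig:
    """Thresholds and settings shared by the battery and the cascade."""

    p_instrument: float = 1e-5
    p_reverse: float = 1e-5
    clump_r2: float = 0.001
    clump_window_bp: int = 10_000_000
    f_min: float = 10.0
    alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    ivw_model: str = "multiplicative_random"
    mode_phi: float = 1.0
    multiple_testing: str | None = None  # None or "bh"
    policy: HarmonizationPolicy = field(default_factory=HarmonizationPolicy)

    def __post_init__(self):
        for name in ("p_instrument", "p_reverse", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if not 0.0 <= self.clump_r2 <= 1.0:
            raise ConfigError(f"clump_r2 must be in [0, 1], got {self.clump_r2}")
        if self.clump_window_bp < 0:
            raise ConfigError("clump_window_bp must be >= 0")
        if self.n_boot < 0:
            raise ConfigError("n_boot must be >= 0")
        if self.ivw_model not in ("multiplicative_random", "fixed"):
            raise ConfigError(f"unknown ivw_model {self.ivw_model!r}")
        if self.multiple_testing not in (None, "bh"):
            raise ConfigError(f"unknown multiple_testing {self.multiple_testing!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "MRConfig":
        d = dict(d)
        policy = d.pop("policy", None)
        known = {f for f in cls.__dataclass_fields__ if f != "policy"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        kwargs = {k: v for k, v in d.items()}
        if policy is not None:
            kwargs["policy"] = HarmonizationPolicy(**policy)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "MRConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
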