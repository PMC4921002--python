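"""Run configuration: every tunable threshold of the calling procedure.

Defaults follow the published operating point: MAF routing threshold
0.05, cluster-size window b1 = 3, b2 = 10, no-call posterior threshold
0.85, reference screening at MAF > 0.15 with >= 10 % cluster
proportions, HWE alpha 1e-4.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

from .core import ValidationError


@dataclass
class MDConfig:
    maf_threshold: float = 0.05  # g1 boundary (inclusive)
    b1: int = 3  # minimum cluster size for g2 (inclusive)
    b2: int = 10  # maximum cluster size for g2 (exclusive)
    pr_threshold: float = 0.85  # no-call posterior threshold (inclusive)
    ref_maf: float = 0.15  # Step I MAF screen (exclusive)
    ref_min_prop: float = 0.10  # Step II cluster-proportion screen (inclusive)
    max_candidates: int = 200  # Step I search-window cap
    hwe_alpha: float = 1e-4
    hwe_exact: bool = False  # reserved: chi-square is the default test
    em_tol: float = 1e-8
    em_max_iter: int = 500
    dp_n_iter: int = 2000
    dp_burn_in: int = 500
    dp_thin: int = 5
    dp_r: float = 0.01  # Normal-Wishart relative precision of mu
    dp_nu: float = 4.0  # Wishart degrees of freedom
    fallback_policy: str = "search-after"  # or "plain-dp"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.maf_threshold <= 0.5):
            raise ValidationError("maf_threshold must be in [0, 0.5]")
        if not (0 <= self.pr_threshold <= 1):
            raise ValidationError("pr_threshold must be in [0, 1]")
        if self.b1 < 0 or self.b2 <= self.b1:
            raise ValidationError("need 0 <= b1 < b2")
        if self.fallback_policy not in ("search-after", "plain-dp"):
            raise ValidationError(f"unknown fallback_policy {self.fallback_policy!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> MDConfig:
    """Load a YAML (or flat key: value) config file; unknown keys rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError("config file must contain a mapping")
    known = set(MDConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return MDConfig(**data)


def save_config(cfg: MDConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
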