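"""Simulation configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import yaml

from tgcevo.arms import ARM_LENGTHS_MB


class ConfigError(ValueError):
    """Raised for invalid configuration values; message names the field."""


@dataclass
class SimConfig:
    """Parameters of the synthetic tumour generator.

    Defaults mimic the target setting: a tetraploid founder lineage,
    mostly post-duplication point mutations at low density (~0.1/Mb),
    net-loss copy-number evolution, and deep amplicon sequencing
    (median depth well above 250).
    """

    # genome / tree
    arm_table: dict = field(default_factory=lambda: dict(ARM_LENGTHS_MB))
    n_clones: int = 6
    cna_per_edge: float = 2.0
    loss_gain_ratio: float = 0.75
    loh_bias: float = 0.3          # prob. a loss targets an arm one step from LOH
    max_copies: int = 4            # per-haplotype cap for gains
    n_12p_gain: int = 2            # extra 12p copies gained by the invasive founder

    # mutations
    snv_rate: float = 0.1          # SNVs per Mb of genome
    frac_pre_wgd: float = 0.05
    n_svs: int = 2
    signature_mix: Sequence[float] = (0.7, 0.3, 0.0, 0.0)

    # samples
    n_samples: int = 8
    purity_range: tuple = (0.7, 1.0)
    gcnis_admixture: float = 0.0   # fraction of a progressed clone mixed into GCNIS samples
    sample_histologies: Optional[Sequence[str]] = None
    sampled_clones: Optional[Sequence[str]] = None
    replicates: int = 1

    # sequencing
    depth_median: int = 500
    depth_sigma: float = 0.3
    min_depth: int = 20
    overdispersion: float = 0.0    # beta-binomial rho; 0 = binomial
    dropout_rate: float = 0.0
    amplicons_per_arm: int = 3
    snps_per_amplicon: int = 2

    seed: int = 0

    def validate(self) -> "SimConfig":
        def _frac(name):
            v = getattr(self, name)
            if not (0.0 <= float(v) <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")

        if not self.arm_table:
            raise ConfigError("arm_table must be non-empty")
        for arm, length in self.arm_table.items():
            if length <= 0:
                raise ConfigError(f"arm_table length for {arm} must be > 0, got {length}")
        if self.n_clones < 2:
            raise ConfigError(f"n_clones must be >= 2, got {self.n_clones}")
        if self.cna_per_edge < 0:
            raise ConfigError(f"cna_per_edge must be >= 0, got {self.cna_per_edge}")
        for name in ("loss_gain_ratio", "loh_bias", "frac_pre_wgd",
                     "gcnis_admixture", "dropout_rate", "overdispersion"):
            _frac(name)
        if self.snv_rate < 0:
            raise ConfigError(f"snv_rate must be >= 0, got {self.snv_rate}")
        if self.n_svs < 0:
            raise ConfigError(f"n_svs must be >= 0, got {self.n_svs}")
        if self.max_copies < 2:
            raise ConfigError(f"max_copies must be >= 2, got {self.max_copies}")
        if self.n_samples < 1:
            raise ConfigError(f"n_samples must be >= 1, got {self.n_samples}")
        lo, hi = self.purity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError(f"purity_range must be an interval within [0, 1], got {self.purity_range}")
        if self.depth_median < 1:
            raise ConfigError(f"depth_median must be >= 1, got {self.depth_median}")
        if self.depth_sigma < 0:
            raise ConfigError(f"depth_sigma must be >= 0, got {self.depth_sigma}")
        if self.min_depth < 1:
            raise ConfigError(f"min_depth must be >= 1, got {self.min_depth}")
        if self.amplicons_per_arm < 1:
            raise ConfigError(f"amplicons_per_arm must be >= 1, got {self.amplicons_per_arm}")
        if self.snps_per_amplicon < 1:
            raise ConfigError(f"snps_per_amplicon must be >= 1, got {self.snps_per_amplicon}")
        if self.replicates < 1:
            raise ConfigError(f"replicates must be >= 1, got {self.replicates}")
        if any(w < 0 for w in self.signature_mix) or sum(self.signature_mix) <= 0:
            raise ConfigError("signature_mix must be non-negative with positive sum")
        return self

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = list(v)
            d[f.name] = v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration field(s): {sorted(unknown)}")
        cfg = cls(**d)
        if isinstance(cfg.purity_range, list):
            cfg.purity_range = tuple(cfg.purity_range)
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping of fields")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
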