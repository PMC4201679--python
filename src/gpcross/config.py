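"""Run configuration: a flat, schema-checked mapping of study parameters.

Defaults reproduce the study design constants: 20/51/511 cohorts in 8
half-sib families, 4-fold cross-validation under both scenarios, QC at
call rate 0.95 / MAF 0.01, mixture proportions 0.889/0.1/0.01/0.001 and
the 50,000/20,000/20 MCMC schedule.  Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # population
    n_f0: int = 20
    n_f1: int = 51
    n_sires_f1: int = 8
    n_f2: int = 511
    n_snps: int = 5000
    n_chromosomes: int = 10
    map_length_cm: float = 100.0
    divergence: float = 0.3
    n_qtl: int = 200
    n_hatches: int = 4
    missing_rate: float = 0.0
    traits: tuple = ("BW6", "BW12", "EP", "BMP", "LMP")
    # QC
    min_call_rate: float = 0.95
    min_maf: float = 0.01
    # models and validation
    models: tuple = ("blup", "gblup", "lasso", "mix4")
    scenarios: tuple = ("family", "random")
    k_folds: int = 4
    pi: tuple = (0.889, 0.1, 0.01, 0.001)
    g_ridge: float = 1e-6
    include_full_data: bool = False
    # MCMC schedule
    mcmc_cycles: int = 50_000
    mcmc_burn_in: int = 20_000
    mcmc_thin: int = 20
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        self.traits = tuple(self.traits)
        self.models = tuple(self.models)
        self.scenarios = tuple(self.scenarios)
        self.pi = tuple(float(p) for p in self.pi)
        if abs(sum(self.pi) - 1.0) > 1e-12:
            raise ValueError("mixture proportions must sum to 1")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must be in [0, 1)")
        if self.mcmc_burn_in >= self.mcmc_cycles:
            raise ValueError("burn-in must be shorter than the chain")
        if min(self.n_f0, self.n_f1, self.n_f2, self.n_snps, self.k_folds) < 1:
            raise ValueError("counts must be positive")
        bad = set(self.scenarios) - {"family", "random"}
        if bad:
            raise ValueError(f"unknown scenario(s) {bad}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("configuration file must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("traits", "models", "scenarios", "pi"):
            d[key] = list(d[key])
        return d

    def stage_hash(self, *keys: str) -> str:
        """Stable hash of the configuration fields a stage depends on."""
        sub = {k: self.to_dict()[k] for k in sorted(keys)}
        return hashlib.sha256(json.dumps(sub, sort_keys=True).encode()).hexdigest()[:16]
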