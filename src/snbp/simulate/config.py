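"""Simulation configuration with validation and YAML loading.

All distributional choices in the generators are stand-ins: the analyses
we emulate never published a generative model, so these parameters define
convenient ground truth for testing, not biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from snbp.errors import ConfigError

CHROMOSOME_CLASSES = ("A", "X", "Y")


@dataclass
class EventRates:
    """Per-branch, per-unit-length Poisson rates for one event kind."""

    gain: float = 0.0
    loss: float = 0.0
    amplification: float = 0.0

    def validate(self) -> None:
        for name in ("gain", "loss", "amplification"):
            if getattr(self, name) < 0:
                raise ConfigError(f"event rate {name} must be >= 0")


@dataclass
class CodonParams:
    omega: float = 0.5
    kappa: float = 2.0
    n_codons: int = 100

    def validate(self) -> None:
        if self.omega <= 0:
            raise ConfigError("omega must be > 0")
        if self.kappa <= 0:
            raise ConfigError("kappa must be > 0")
        if self.n_codons < 1:
            raise ConfigError("n_codons must be >= 1")


@dataclass
class MKParams:
    alpha_true: float = 0.0
    mean_ds: float = 10.0
    mean_ps: float = 10.0
    neutral_ratio: float = 0.3  # expected Pn/Ps (= Dn/Ds at alpha=0)
    rare_fraction: float = 0.0
    rare_freq_max: float = 0.05
    n_genes: int = 100

    def validate(self) -> None:
        if self.alpha_true >= 1:
            raise ConfigError("alpha_true must be < 1")
        if self.mean_ds <= 0 or self.mean_ps <= 0:
            raise ConfigError("mean_ds and mean_ps must be > 0")
        if self.neutral_ratio <= 0:
            raise ConfigError("neutral_ratio must be > 0")
        if not (0.0 <= self.rare_fraction < 1.0):
            raise ConfigError("rare_fraction must be in [0, 1)")
        if not (0.0 < self.rare_freq_max < 1.0):
            raise ConfigError("rare_freq_max must be in (0, 1)")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")


@dataclass
class CoverageParams:
    haploid_depth: float = 30.0
    dispersion: float = 0.2  # overdispersion: var = mu + dispersion * mu^2; 0 = Poisson
    window: int = 10_000
    contig_lengths: dict[str, int] = field(default_factory=dict)
    contig_classes: dict[str, str] = field(default_factory=dict)  # contig -> A/X/Y

    def validate(self) -> None:
        if self.haploid_depth <= 0:
            raise ConfigError("haploid_depth must be > 0")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.window < 100:
            raise ConfigError("window must be >= 100")
        for contig, length in self.contig_lengths.items():
            if length < self.window:
                raise ConfigError(
                    f"contig {contig!r} shorter ({length}) than window ({self.window})"
                )
        for contig, cls in self.contig_classes.items():
            if cls not in CHROMOSOME_CLASSES:
                raise ConfigError(f"contig {contig!r} has unknown class {cls!r}")


@dataclass
class SimulationConfig:
    seed: int = 0
    tree_spec: str | tuple[int, float] = "(A:0.1,B:0.1);"
    rates: dict[str, EventRates] = field(
        default_factory=lambda: {c: EventRates() for c in CHROMOSOME_CLASSES}
    )
    sex_bias: float = 0.5  # P(amplification lands on a sex chromosome)
    n_root_genes: int = 5
    pseudogene_fraction: float = 0.5  # losses leaving a pseudogene vs clean absence
    codon: CodonParams = field(default_factory=CodonParams)
    mk: MKParams = field(default_factory=MKParams)
    coverage: CoverageParams = field(default_factory=CoverageParams)

    def validate(self) -> "SimulationConfig":
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        for cls in self.rates:
            if cls not in CHROMOSOME_CLASSES:
                raise ConfigError(f"unknown chromosome class {cls!r} in rates")
            self.rates[cls].validate()
        for cls in CHROMOSOME_CLASSES:
            self.rates.setdefault(cls, EventRates())
        if not (0.0 <= self.sex_bias <= 1.0):
            raise ConfigError("sex_bias must be in [0, 1]")
        if not (0.0 <= self.pseudogene_fraction <= 1.0):
            raise ConfigError("pseudogene_fraction must be in [0, 1]")
        if self.n_root_genes < 0:
            raise ConfigError("n_root_genes must be >= 0")
        self.codon.validate()
        self.mk.validate()
        self.coverage.validate()
        return self

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        kwargs = dict(data)
        if "rates" in kwargs:
            kwargs["rates"] = {
                c: EventRates(**r) for c, r in kwargs["rates"].items()
            }
        if "tree_spec" in kwargs and isinstance(kwargs["tree_spec"], list):
            kwargs["tree_spec"] = tuple(kwargs["tree_spec"])
        for name, sub in (
            ("codon", CodonParams),
            ("mk", MKParams),
            ("coverage", CoverageParams),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = sub(**kwargs[name])
        try:
            cfg = cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(f"bad configuration: {exc}") from None
        return cfg.validate()

    def to_dict(self) -> dict:
        return asdict(self)
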