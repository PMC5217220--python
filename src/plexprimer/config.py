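"""Design configuration: every tunable of the pipeline, with a flat-file loader.

Defaults mirror a validated microfluidic multiplex design: primer length
17-26 bp, amplicon 247-300 bp, Tm window centered near 60 °C.  The config
file is a flat YAML mapping whose keys equal the dataclass field names
(thermodynamic and structural thresholds included), e.g.::

    tm_min: 57.0
    tm_max: 63.0
    amp_max: 300
    adapter_fwd: ACACTGACGACATGGTTCTACA
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import yaml

from .thermo import StructureParams, ThermoConditions


@dataclass(frozen=True)
class DesignConfig:
    # primer acceptance windows
    tm_min: float = 57.0
    tm_max: float = 63.0
    gc_min: float = 0.30
    gc_max: float = 0.70
    len_min: int = 17
    len_max: int = 26
    # amplicon size bounds; amp_max is the "maximum allowable amplicon size"
    amp_min: int = 247
    amp_max: int = 300
    # variant avoidance: reject primers over SNPs at/above this minor-allele frequency
    snp_freq_cutoff: float = 0.01
    # genome index
    kmer_size: int = 15
    quality_threshold: float = 2.0
    three_prime_penalty: float = 100.0
    # solution conditions / structure screens
    monovalent: float = 0.05
    oligo_conc: float = 2.5e-7
    hairpin_min_stem: int = 4
    hairpin_min_loop: int = 3
    dimer_min_run: int = 8
    dimer_min_run_3p: int = 5
    self_anneal_word: int = 7
    # pooling
    pool_strategy: str = "most"  # seed pools with the most- or least-connected pair
    pool_tm_spread: float = 2.0
    pool_size_frac: float = 0.20  # rule 4: |lenA-lenB| <= frac * max_amp
    cross_anneal_check: bool = True
    dynamic_degrees: bool = False
    # iterative loosening
    tm_step: float = 1.0
    amp_step: int = 25
    max_iterations: int = 3
    # output / ordering
    adapter_fwd: str = ""
    adapter_rev: str = ""
    # in-silico PCR
    max_mismatches: int = 0
    max_product: int | None = None  # default: 4 * amp_max
    # candidate flank: how far outside the target a primer may bind (None: amp_max)
    flank: int | None = None

    def __post_init__(self) -> None:
        if self.tm_min >= self.tm_max:
            raise ValueError("empty Tm window")
        if not (0.0 <= self.gc_min < self.gc_max <= 1.0):
            raise ValueError("invalid GC window")
        if not (8 <= self.len_min <= self.len_max <= 40):
            raise ValueError("invalid primer length range")
        if self.len_min < self.kmer_size:
            raise ValueError("len_min must be >= kmer_size for quality scoring")
        if self.amp_min > self.amp_max:
            raise ValueError("empty amplicon size range")
        if not 0.0 <= self.snp_freq_cutoff <= 0.5:
            raise ValueError("snp_freq_cutoff must be in [0, 0.5]")
        if not 8 <= self.kmer_size <= 16:
            raise ValueError("kmer_size outside 8-16")
        if self.pool_strategy not in ("most", "least"):
            raise ValueError("pool_strategy must be 'most' or 'least'")
        if self.max_mismatches not in (0, 1, 2):
            raise ValueError("max_mismatches must be 0, 1 or 2")
        if self.max_iterations < 0 or self.tm_step < 0 or self.amp_step < 0:
            raise ValueError("loosening schedule values must be non-negative")

    @property
    def thermo(self) -> ThermoConditions:
        return ThermoConditions(monovalent=self.monovalent, oligo_conc=self.oligo_conc)

    @property
    def structure(self) -> StructureParams:
        return StructureParams(
            hairpin_min_stem=self.hairpin_min_stem,
            hairpin_min_loop=self.hairpin_min_loop,
            dimer_min_run=self.dimer_min_run,
            dimer_min_run_3p=self.dimer_min_run_3p,
            self_anneal_word=self.self_anneal_word,
        )

    @property
    def effective_flank(self) -> int:
        return self.amp_max if self.flank is None else self.flank

    @property
    def effective_max_product(self) -> int:
        return 4 * self.amp_max if self.max_product is None else self.max_product

    def loosened(self, iteration: int) -> "DesignConfig":
        """Parameters after *iteration* widening steps (iteration 0 = stringent)."""
        if iteration == 0:
            return self
        return replace(
            self,
            tm_min=self.tm_min - iteration * self.tm_step,
            tm_max=self.tm_max + iteration * self.tm_step,
            amp_max=self.amp_max + iteration * self.amp_step,
        )


_FIELDS = {f.name for f in dataclasses.fields(DesignConfig)}


def config_from_dict(d: dict) -> DesignConfig:
    unknown = set(d) - _FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return DesignConfig(**d)


def load_config(path) -> DesignConfig:
    """Load a flat YAML key-value config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return config_from_dict(data)
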