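"""Simulation and pipeline configuration.

One :class:`SimulationConfig` object, fully determined by its ``seed``,
drives every synthetic input the pipeline consumes: the allotetraploid
reference (A and C subgenomes), the inbred accession panel, short reads,
gene models with GO annotations, and two-channel GoldenGate intensities.
The defaults encode the study design this package emulates: ten fully
inbred accessions of an A+C allotetraploid, 100 bp reads, ~3% per-base
homoeolog divergence, one simple SNP per 10 kb, and a small fraction of
tri-allelic sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Raised for an invalid simulation or pipeline configuration."""


# Per-accession mean fold-coverages of the resequencing panel this package
# emulates (ten inbred rapeseed accessions, 5.3-37.5x). Useful for examples
# exploring uneven coverage; the pipeline default is a flat 12x so that the
# minimum-depth genotype filter is rarely the binding constraint.
STUDY_DEPTHS = [37.5, 22.2, 9.0, 7.2, 6.5, 6.6, 5.3, 6.0, 7.6, 6.7]


@dataclass
class GoldenGateConfig:
    """Design of the simulated two-channel genotyping experiment."""

    n_dh: int = 50            # doubled-haploid population size
    n_f2: int = 80            # F2 population size
    n_assays: int = 96        # multiplex level of the oligo pool
    hemi_fraction: float = 3 / 96  # assays planted as hemi-SNPs
    mu_on: float = 4000.0     # mean channel intensity, allele present
    mu_off: float = 300.0     # mean channel intensity, allele absent
    sd: float = 200.0         # Gaussian channel noise (truncated at 0)
    n_replicates: int = 3     # one sample run in triplicate
    dh_parents: tuple[int, int] = (0, 1)   # accession indices
    f2_parents: tuple[int, int] = (2, 3)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_accessions: int = 10
    # (subgenome, length); the i-th "A" entry is homoeologous to the i-th
    # "C" entry (equal lengths required), leftovers are unpaired.
    chrom_plan: list[tuple[str, int]] = field(
        default_factory=lambda: [("A", 150_000), ("C", 150_000),
                                 ("A", 150_000), ("C", 150_000)]
    )
    homoeolog_divergence: float = 0.03
    # (unit length bp, copy number) per repeat family
    repeat_families: list[tuple[int, int]] = field(
        default_factory=lambda: [(200, 20), (500, 8)]
    )
    snp_rate: float = 1e-4
    triallelic_fraction: float = 3e-4
    # probability over minor-allele accession counts 1..n_accessions//2
    minor_count_spectrum: list[float] = field(
        default_factory=lambda: [0.2, 0.2, 0.2, 0.2, 0.2]
    )
    read_length: int = 100
    per_accession_depth: list[float] = field(default_factory=lambda: [12.0] * 10)
    base_error_rate: float = 0.002
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (300, 900)  # CDS bp, multiple of 3
    goldengate: GoldenGateConfig = field(default_factory=GoldenGateConfig)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("homoeolog_divergence", "snp_rate", "triallelic_fraction",
                     "base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not self.chrom_plan:
            raise ConfigError("chrom_plan must be nonempty")
        for sub, length in self.chrom_plan:
            if sub not in ("A", "C"):
                raise ConfigError(f"subgenome must be 'A' or 'C', got {sub!r}")
            if length < 10 * self.read_length:
                raise ConfigError(
                    f"chromosome length {length} shorter than 10x read length"
                )
        if len(self.per_accession_depth) != self.n_accessions:
            raise ConfigError("per_accession_depth length must equal n_accessions")
        if any(d <= 0 for d in self.per_accession_depth):
            raise ConfigError("per-accession depth must be positive")
        if self.read_length not in (75, 100):
            raise ConfigError("read_length must be 75 or 100")
        spectrum = self.minor_count_spectrum
        if len(spectrum) != self.n_accessions // 2 or abs(sum(spectrum) - 1) > 1e-9:
            raise ConfigError(
                "minor_count_spectrum must be a distribution over counts "
                f"1..{self.n_accessions // 2}"
            )

    @property
    def accession_names(self) -> list[str]:
        return [f"acc{i:02d}" for i in range(self.n_accessions)]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "goldengate" in d and isinstance(d["goldengate"], dict):
            gg = dict(d["goldengate"])
            for key in ("dh_parents", "f2_parents"):
                if key in gg:
                    gg[key] = tuple(gg[key])
            d["goldengate"] = GoldenGateConfig(**gg)
        for key in ("chrom_plan", "repeat_families"):
            if key in d:
                d[key] = [tuple(x) for x in d[key]]
        if "gene_length_range" in d:
            d["gene_length_range"] = tuple(d["gene_length_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
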