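"""Simulation configuration and ground-truth bookkeeping.

The generator emulates the structure of an iPSC Cell Painting cohort: donors
laid out on imaging plates (one plate per donor, several wells each), traits
dominated by plate batch effects with a smaller donor-shared component, a
colony/isolate context split by neighbor count, rare protein-altering
variants collapsible per gene, and common variants with small effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Mapping, Sequence

VARIANCE_COMPONENTS = ("plate", "well", "donor", "residual")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class PlantedEffect:
    """A genetic effect planted on one trait.

    ``beta`` is on the cell-level trait scale (total cell variance is 1 by
    construction), multiplied by dosage (variant targets) or carrier status
    (gene targets).
    """

    target_type: Literal["gene", "variant"]
    target_id: str
    trait: int
    beta: float


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Cohort-shape defaults follow the study design this package models
    (297 donors across 7 plates, 8 wells per line, 2.52% isolate cells);
    per-well cell counts and trait/variant/gene counts are desk-scale.
    """

    n_donors: int = 297
    n_plates: int = 7
    wells_per_donor: int = 8
    cells_per_well_mean: int = 150
    n_traits: int = 40
    n_common_variants: int = 500
    n_genes: int = 120
    rare_variants_per_gene: tuple[int, int] = (2, 8)
    maf_range_common: tuple[float, float] = (0.05, 0.5)
    maf_range_rare: tuple[float, float] = (0.001, 0.01)
    variance_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"plate": 0.60, "well": 0.05, "donor": 0.17, "residual": 0.18}
    )
    planted_effects: Sequence[PlantedEffect] = ()
    isolate_fraction: float = 0.0252
    missing_cell_fraction: float = 0.01
    missing_trait_fraction: float = 0.08
    dosage_missing_fraction: float = 0.0
    # planted QC-failure classes for genotype-filter bookkeeping tests:
    # keys among {"low_maf", "high_missing", "hwe_violation"} -> counts
    planted_qc_failures: Mapping[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_donors": self.n_donors,
            "n_plates": self.n_plates,
            "wells_per_donor": self.wells_per_donor,
            "cells_per_well_mean": self.cells_per_well_mean,
            "n_traits": self.n_traits,
            "n_genes": self.n_genes,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        if self.n_common_variants < 0:
            raise ConfigurationError("n_common_variants must be non-negative")
        if self.n_common_variants == 0 and self.n_genes == 0:
            raise ConfigurationError("need at least one variant")
        lo, hi = self.rare_variants_per_gene
        if not (0 < lo <= hi):
            raise ConfigurationError("rare_variants_per_gene must be a positive range")
        total = sum(self.variance_fractions.get(c, 0.0) for c in VARIANCE_COMPONENTS)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"variance fractions must sum to 1 (got {total!r})"
            )
        for name, frac in self.variance_fractions.items():
            if name not in VARIANCE_COMPONENTS:
                raise ConfigurationError(f"unknown variance component {name!r}")
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"variance fraction {name}={frac} outside [0,1]")
        if not 0.0 < self.isolate_fraction < 1.0:
            raise ConfigurationError("isolate_fraction must be in (0,1)")
        for name in ("maf_range_common", "maf_range_rare"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 0.5):
                raise ConfigurationError(f"{name} must satisfy 0 <= lo <= hi <= 0.5")

    def trait_names(self) -> list[str]:
        width = len(str(self.n_traits - 1))
        return [f"trait_{i:0{width}d}" for i in range(self.n_traits)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_effects"] = [asdict(e) for e in self.planted_effects]
        d["variance_fractions"] = dict(self.variance_fractions)
        d["planted_qc_failures"] = dict(self.planted_qc_failures)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "planted_effects" in d:
            d["planted_effects"] = tuple(
                e if isinstance(e, PlantedEffect) else PlantedEffect(**e)
                for e in d["planted_effects"]
            )
        for key in ("rare_variants_per_gene", "maf_range_common", "maf_range_rare"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Registry of what the generator actually planted.

    ``carriers`` maps gene -> sorted donor indices carrying >=1 qualifying
    rare allele; ``planted_fail_ids`` maps QC-failure class -> variant ids.
    """

    effects: list[PlantedEffect] = field(default_factory=list)
    variance_fractions: dict[str, float] = field(default_factory=dict)
    carriers: dict[str, list[int]] = field(default_factory=dict)
    planted_fail_ids: dict[str, list[str]] = field(default_factory=dict)

    def validate_against(self, genes: Sequence[str], variant_ids: Sequence[str], n_traits: int) -> None:
        genes = set(genes)
        variant_ids = set(variant_ids)
        for eff in self.effects:
            if eff.target_type == "gene" and eff.target_id not in genes:
                raise ConfigurationError(f"planted effect targets unknown gene {eff.target_id!r}")
            if eff.target_type == "variant" and eff.target_id not in variant_ids:
                raise ConfigurationError(f"planted effect targets unknown variant {eff.target_id!r}")
            if not 0 <= eff.trait < n_traits:
                raise ConfigurationError(f"planted effect targets nonexistent trait {eff.trait}")
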