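"""End-to-end orchestration: simulate -> profiles -> varcomp -> genotypes ->
association (rare burden + common scan, per context) -> power projection.

Every stage writes its outputs under the run directory and is logged with
in/out counts; a RunManifest records the configuration hash and per-file
checksums so identical configurations are verifiably reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from cmqtl import association, genotypes as gt, io, power, profiles, varcomp
from cmqtl.config import SimulationConfig
from cmqtl.simulate import simulate_donor_metadata, simulate_genotypes, simulate_profiles

logger = logging.getLogger(__name__)

CONTEXTS = ("colony", "isolate")


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, defaulting to the study's values."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    contexts: Sequence[str] = CONTEXTS
    max_missing_fraction: float = 0.05  # cell QC
    trait_blocklist: tuple[str, ...] = ()
    composite_r_threshold: float = 0.9
    maf_min_common: float = 0.05
    variant_miss_max: float = 0.05
    hwe_p_min: float = 1e-5
    maf_max_rare: float = 0.01
    rare_call_rate_min: float = 0.95
    min_carrier_fraction: float = 0.02
    alpha: float = 0.05
    genome_wide_alpha: float = 5e-8
    suggestive_p_burden: float = 1e-6  # raw, per the burden Manhattan convention
    suggestive_alpha_common: float = 1e-5  # divided by n traits
    n_pcs: int = 20
    run_varcomp: bool = True
    varcomp_max_traits: int | None = 5  # decomposition is the slow stage
    power_n_grid: tuple[int, ...] = (297, 500, 1000, 2000)
    power_k: int = 4
    seed: int = 0
    out_dir: str = "cmqtl_run"

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and not isinstance(d["sim"], SimulationConfig):
            d["sim"] = SimulationConfig.from_dict(d["sim"])
        for key in ("trait_blocklist", "power_n_grid", "contexts"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        d.pop("out_dir")  # where results land does not change what they are
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    checksums: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, dict] = field(default_factory=dict)
    version: str = ""
    started: float = 0.0
    finished: float = 0.0

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineResult:
    manifest: RunManifest
    donor_traits: dict[str, pd.DataFrame]
    burden_scans: dict[str, association.ScanSummary]
    common_scans: dict[str, association.ScanSummary]
    varcomp_tables: dict[str, pd.DataFrame]
    mixture: power.EffectSizeMixture | None
    projection: pd.DataFrame | None
    composite: profiles.CompositeTraitSet | None = None


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    import cmqtl

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(), seed=config.seed,
        version=cmqtl.__version__, started=time.time(),
    )
    written: list[Path] = []

    def save(frame: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        io.write_table(frame, path, index=index)
        written.append(path)

    stage = "simulate"
    try:
        sim = config.sim
        geno, truth = simulate_genotypes(sim)
        metadata = simulate_donor_metadata(sim)
        cells, truth = simulate_profiles(sim, geno, truth)
        io.write_vcf(geno, out / "genotypes.vcf")
        written.append(out / "genotypes.vcf")
        io.write_annotation(geno, out / "annotation.tsv")
        written.append(out / "annotation.tsv")
        save(metadata, "donor_metadata.tsv", index=True)
        manifest.stage_counts[stage] = {
            "cells": len(cells), "traits": sim.n_traits,
            "variants": geno.n_variants, "donors": geno.n_donors,
        }

        stage = "genotype_qc"
        common, qc_report = gt.qc_common_variants(
            geno, maf_min=config.maf_min_common,
            miss_max=config.variant_miss_max, hwe_p_min=config.hwe_p_min,
        )
        pruned_ids = gt.ld_prune(common, mode="bp")
        grm = gt.compute_grm(common.subset_variants(pruned_ids))
        k = min(config.n_pcs, len(grm) - 1)
        pcs = gt.pca_from_grm(grm, k=k).components
        save(pcs, "ancestry_pcs.tsv", index=True)
        burden = gt.collapse_rare_burden(
            geno, maf_max=config.maf_max_rare,
            call_rate_min=config.rare_call_rate_min,
            min_carrier_fraction=config.min_carrier_fraction,
        )
        save(burden.indicators, "gene_burden.tsv", index=True)
        manifest.stage_counts[stage] = dict(qc_report.counts, pruned=len(pruned_ids),
                                            burden_genes=len(burden.genes))

        stage = "profiles"
        cells_qc = profiles.qc_cells(cells, config.max_missing_fraction)
        cells_qc = profiles.qc_traits(cells_qc, blocklist=config.trait_blocklist)
        colony, isolate = profiles.split_context(cells_qc)
        context_tables = {"colony": colony, "isolate": isolate}
        well_int: dict[str, pd.DataFrame] = {}
        donor_raw: dict[str, pd.DataFrame] = {}
        for ctx in config.contexts:
            wells = profiles.aggregate_wells(context_tables[ctx])
            wells = profiles.inverse_normal_transform(wells)
            well_int[ctx] = wells
            donor_raw[ctx] = profiles.pseudo_bulk(wells)
        corr = [profiles.donor_level_correlation(donor_raw[c]) for c in config.contexts]
        composite = profiles.select_composite_traits(corr, config.composite_r_threshold)
        donor_traits = {
            c: donor_raw[c][composite.retained] for c in config.contexts
        }
        for ctx in config.contexts:
            save(donor_traits[ctx], f"donor_traits_{ctx}.tsv", index=True)
        (out / "composite_traits.json").write_text(
            json.dumps({"retained": composite.retained, "log": composite.log}, indent=2)
        )
        written.append(out / "composite_traits.json")
        manifest.stage_counts[stage] = {
            "cells_retained": len(cells_qc),
            "colony_cells": len(colony), "isolate_cells": len(isolate),
            "composite_traits": len(composite.retained),
        }

        stage = "varcomp"
        varcomp_tables: dict[str, pd.DataFrame] = {}
        if config.run_varcomp:
            for ctx in config.contexts:
                traits = composite.retained[: config.varcomp_max_traits]
                table = varcomp.decompose_traits(
                    well_int[ctx], metadata, pcs=pcs, traits=traits, context=ctx,
                    n_traits_for_correction=len(composite.retained),
                )
                varcomp_tables[ctx] = table
                save(table, f"varcomp_{ctx}.tsv")
        manifest.stage_counts[stage] = {c: len(t) for c, t in varcomp_tables.items()}

        stage = "association"
        plates = _donor_plates(cells_qc)
        burden_scans: dict[str, association.ScanSummary] = {}
        common_scans: dict[str, association.ScanSummary] = {}
        n_traits = len(composite.retained)
        burden_thr = association.bonferroni_threshold(
            config.alpha, max(1, n_traits * len(burden.genes))
        )
        common_thr = config.genome_wide_alpha / max(1, n_traits)
        for ctx in config.contexts:
            traits_ctx = donor_traits[ctx]
            neighbor_means = (
                profiles.donor_neighbor_means(well_int[ctx]) if ctx == "colony" else None
            )
            covars = association.build_covariates(
                metadata.loc[traits_ctx.index], pcs=pcs, plates=plates,
                neighbor_means=neighbor_means, context=ctx,
            )
            tests = association.burden_regression(
                traits_ctx, burden, covars, context=ctx
            )
            burden_scans[ctx] = association.summarize_scan(
                tests, burden_thr, config.suggestive_p_burden
            )
            save(tests, f"burden_{ctx}.tsv")
            ctests = association.common_variant_scan(traits_ctx, common, covars, context=ctx)
            common_scans[ctx] = association.summarize_scan(
                ctests, common_thr, config.suggestive_alpha_common / max(1, n_traits)
            )
            save(ctests, f"common_{ctx}.tsv")
        manifest.stage_counts[stage] = {
            "burden_tests": sum(len(s.tests) for s in burden_scans.values()),
            "common_tests": sum(len(s.tests) for s in common_scans.values()),
            "burden_threshold": burden_thr,
            "common_threshold": common_thr,
        }

        stage = "power"
        z = pd.concat(
            [s.tests["t"].dropna() for s in burden_scans.values()], ignore_index=True
        ).to_numpy()
        mixture = projection = None
        if len(z) >= 100:
            mixture = power.fit_effect_mixture(
                z, n_fit=geno.n_donors, k=config.power_k, seed=config.seed
            )
            mixture.to_json(out / "effect_mixture.json")
            written.append(out / "effect_mixture.json")
            projection = power.project_discoveries(
                mixture, list(config.power_n_grid), p_star=burden_thr
            )
            save(projection, "power_projection.tsv")
        manifest.stage_counts[stage] = {"z_scores": int(len(z))}
    except Exception as exc:  # partial outputs stay on disk for debugging
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    config.to_yaml(out / "config.yaml")
    written.append(out / "config.yaml")
    manifest.checksums = {p.name: _checksum(p) for p in written}
    manifest.finished = time.time()
    manifest.write(out / "manifest.json")
    return PipelineResult(
        manifest=manifest,
        donor_traits=donor_traits,
        burden_scans=burden_scans,
        common_scans=common_scans,
        varcomp_tables=varcomp_tables,
        mixture=mixture,
        projection=projection,
        composite=composite,
    )


def _donor_plates(cells: pd.DataFrame) -> pd.Series:
    return cells.groupby("donor_id")["plate_id"].first()
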