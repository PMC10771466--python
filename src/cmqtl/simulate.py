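"""Synthetic cohort generator with known ground truth.

Emulates the structure of an iPSC morphological-profiling cohort: donors
placed on imaging plates (one plate per donor, several wells each), cell
Painting-style traits whose variance is dominated by plate batch effects
with a smaller donor-shared component, colony/isolate cell contexts split
by neighbor count, gene-collapsible rare protein-altering variants, and
independent common variants under Hardy-Weinberg proportions.

Randomness is a single seed fanned out into named substreams (genotypes,
profiles, missingness, metadata), so e.g. planting a phenotype effect does
not perturb the genotype draw.
"""

from __future__ import annotations

import string

import numpy as np
import pandas as pd

from cmqtl.config import ConfigurationError, GroundTruth, SimulationConfig
from cmqtl.genotypes import GenotypeSet

META_COLS = ["cell_id", "plate_id", "well_id", "on_edge", "donor_id", "neighbor_count"]

_STAGE_KEYS = {"genotypes": 1, "profiles": 2, "missingness": 3, "metadata": 4}

PLATE_ROWS, PLATE_COLS = 16, 24  # 384-well screening plate


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), _STAGE_KEYS[stage]]))


def donor_ids(config: SimulationConfig) -> list[str]:
    width = len(str(config.n_donors - 1))
    return [f"D{i:0{width}d}" for i in range(config.n_donors)]


def donor_plate_assignment(config: SimulationConfig) -> np.ndarray:
    """Plate index per donor; contiguous blocks, one plate per donor."""
    return (np.arange(config.n_donors) * config.n_plates) // config.n_donors


def _well_label(position: int) -> str:
    row, col = divmod(position % (PLATE_ROWS * PLATE_COLS), PLATE_COLS)
    return f"{string.ascii_uppercase[row]}{col + 1:02d}"


def _well_on_edge(position: int) -> bool:
    row, col = divmod(position % (PLATE_ROWS * PLATE_COLS), PLATE_COLS)
    return row in (0, PLATE_ROWS - 1) or col in (0, PLATE_COLS - 1)


# --------------------------------------------------------------------------
# Genotypes
# --------------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeSet, GroundTruth]:
    """Draw common and rare variants under Hardy-Weinberg proportions.

    Common variants are independent biallelic SNVs with MAF uniform on
    ``maf_range_common``, laid out position-sorted across autosomes. Rare
    variants are assigned to genes (``rare_variants_per_gene`` each) with
    impact HIGH or MODERATE. Optional planted QC-failure variants (low MAF,
    high missingness, Hardy-Weinberg violation) exercise the filters.
    """
    if config.n_donors <= 0:
        raise ConfigurationError("zero donors")
    rng = _rng(config, "genotypes")
    donors = np.array(donor_ids(config))
    bases = np.array(list("ACGT"))

    records: list[dict] = []
    dosage_cols: list[np.ndarray] = []
    truth = GroundTruth(variance_fractions=dict(config.variance_fractions))

    def add_variant(vid, chrom, pos, dose, filt="PASS"):
        ref, alt = rng.choice(4, size=2, replace=False)
        records.append(
            {"id": vid, "chrom": str(chrom), "pos": int(pos),
             "ref": bases[ref], "alt": bases[alt], "filter": filt}
        )
        dosage_cols.append(dose)

    # common variants: spread over autosomes 1..22, sorted positions
    per_chrom = -(-max(config.n_common_variants, 1) // 22)
    for j in range(config.n_common_variants):
        chrom = 1 + j // per_chrom
        pos = 10_000 + (j % per_chrom) * 5_000
        maf = rng.uniform(*config.maf_range_common)
        dose = rng.binomial(2, maf, size=config.n_donors).astype(float)
        add_variant(f"cv{j:06d}", chrom, pos, dose)

    # rare variants grouped into genes, appended on a separate chromosome run
    lo, hi = config.rare_variants_per_gene
    pos_counter = 10_000
    gene_names = [f"GENE{k:04d}" for k in range(config.n_genes)]
    for k, gene in enumerate(gene_names):
        chrom = 1 + k % 22
        n_var = int(rng.integers(lo, hi + 1))
        carrier = np.zeros(config.n_donors, dtype=bool)
        for m in range(n_var):
            maf = rng.uniform(*config.maf_range_rare)
            dose = rng.binomial(2, maf, size=config.n_donors).astype(float)
            pos_counter += 150
            vid = f"rv_{gene}_{m}"
            add_variant(vid, chrom, 5_000_000 + pos_counter, dose)
            records[-1]["gene"] = gene
            records[-1]["impact"] = "HIGH" if rng.random() < 0.3 else "MODERATE"
            carrier |= dose >= 1
        truth.carriers[gene] = np.nonzero(carrier)[0].tolist()

    # planted QC-failure classes
    fail_chrom, fail_pos = 22, 200_000_000
    for cls, n_fail in dict(config.planted_qc_failures).items():
        ids = []
        for m in range(n_fail):
            fail_pos += 5_000
            vid = f"fail_{cls}_{m}"
            if cls == "low_maf":
                maf = rng.uniform(0.005, 0.04)
                dose = rng.binomial(2, maf, size=config.n_donors).astype(float)
                # ensure at least one alt allele so the variant is polymorphic
                if dose.max() == 0:
                    dose[int(rng.integers(config.n_donors))] = 1.0
            elif cls == "high_missing":
                maf = rng.uniform(*config.maf_range_common)
                dose = rng.binomial(2, maf, size=config.n_donors).astype(float)
                n_miss = max(1, int(np.ceil(0.2 * config.n_donors)))
                dose[rng.choice(config.n_donors, size=n_miss, replace=False)] = np.nan
            elif cls == "hwe_violation":
                # all-heterozygote pattern: maximal HWE departure at MAF 0.5
                dose = np.ones(config.n_donors)
            else:
                raise ConfigurationError(f"unknown QC-failure class {cls!r}")
            add_variant(vid, fail_chrom, fail_pos, dose)
            ids.append(vid)
        truth.planted_fail_ids[cls] = ids

    if config.dosage_missing_fraction > 0:
        miss_rng = _rng(config, "missingness")
        for col in dosage_cols:
            mask = miss_rng.random(config.n_donors) < config.dosage_missing_fraction
            col[mask] = np.nan

    variants = pd.DataFrame(records).set_index("id")
    variants = variants.sort_values(["chrom", "pos"], kind="stable")
    for col in ("gene", "impact"):
        if col not in variants.columns:
            variants[col] = np.nan
    annotation = pd.DataFrame(
        {"gene": variants["gene"].fillna(""), "impact": variants["impact"].fillna("MODIFIER")}
    )
    dosages = np.column_stack(dosage_cols)
    # reorder dosage columns to match the sorted variant table
    order = pd.Index([r["id"] for r in records]).get_indexer(variants.index)
    dosages = dosages[:, order]

    g = GenotypeSet(
        donors=donors,
        variants=variants[["chrom", "pos", "ref", "alt", "filter"]],
        dosages=dosages,
        annotation=annotation,
    )
    truth.effects = list(config.planted_effects)
    truth.validate_against(gene_names, g.variant_ids, config.n_traits)
    return g, truth


def simulate_donor_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Donor sex, age, disease status and source tissue."""
    rng = _rng(config, "metadata")
    n = config.n_donors
    return pd.DataFrame(
        {
            "donor_id": donor_ids(config),
            "sex": rng.choice(["male", "female"], size=n),
            "age": np.clip(np.round(rng.normal(50, 15, size=n)), 18, 85).astype(int),
            "disease": rng.choice(["yes", "no"], size=n),
            "source_tissue": rng.choice(["fibroblast", "Bcell"], size=n, p=[0.7, 0.3]),
        }
    ).set_index("donor_id")


# --------------------------------------------------------------------------
# Single-cell morphology profiles
# --------------------------------------------------------------------------

def _donor_genetic_shift(
    config: SimulationConfig, genotypes: GenotypeSet, truth: GroundTruth
) -> np.ndarray:
    """Donor x trait matrix of planted genetic effects."""
    shift = np.zeros((config.n_donors, config.n_traits))
    for eff in config.planted_effects:
        if not 0 <= eff.trait < config.n_traits:
            raise ConfigurationError(f"planted effect on nonexistent trait {eff.trait}")
        if eff.target_type == "variant":
            try:
                j = genotypes.variants.index.get_loc(eff.target_id)
            except KeyError:
                raise ConfigurationError(f"planted effect on unknown variant {eff.target_id!r}")
            x = np.nan_to_num(genotypes.dosages[:, j])
        else:
            if eff.target_id not in truth.carriers:
                raise ConfigurationError(f"planted effect on unknown gene {eff.target_id!r}")
            x = np.zeros(config.n_donors)
            x[truth.carriers[eff.target_id]] = 1.0
        shift[:, eff.trait] += eff.beta * x
    return shift


def simulate_profiles(
    config: SimulationConfig, genotypes: GenotypeSet, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the single-cell trait table.

    Each cell's trait value is plate effect + well-position effect + donor
    effect (including any planted genetic effect) + cell-level residual,
    all independent Gaussians scaled so the components have the requested
    variance fractions (total cell-level variance 1). Neighbor counts are 0
    with probability ``isolate_fraction``, else 1 + Poisson(3). A fraction
    of cells receives missing values (NaN) in a random subset of traits.
    """
    if len(genotypes.donors) != config.n_donors:
        raise ConfigurationError("genotype donors do not match cohort size")
    if truth is None:
        truth = GroundTruth(variance_fractions=dict(config.variance_fractions))
        truth.carriers = _carriers_from_genotypes(genotypes)
    rng = _rng(config, "profiles")
    frac = {c: config.variance_fractions.get(c, 0.0) for c in ("plate", "well", "donor", "residual")}
    t = config.n_traits

    plates = donor_plate_assignment(config)
    wells_per_plate_donor = config.wells_per_donor
    donors_per_plate = np.bincount(plates, minlength=config.n_plates)

    plate_eff = rng.normal(0, np.sqrt(frac["plate"]), size=(config.n_plates, t))
    # well-position effects are a per-position property of the plate layout,
    # shared across plates; donors land on randomized positions so no two
    # donors systematically share their full well set
    n_positions = PLATE_ROWS * PLATE_COLS
    well_eff = rng.normal(0, np.sqrt(frac["well"]), size=(n_positions, t))
    donor_positions = np.zeros((config.n_donors, wells_per_plate_donor), dtype=int)
    for p in range(config.n_plates):
        members = np.nonzero(plates == p)[0]
        needed = len(members) * wells_per_plate_donor
        perm = rng.permutation(n_positions)
        if needed > n_positions:  # plate over-filled at extreme configs: reuse
            perm = np.resize(perm, needed)
        donor_positions[members] = perm[:needed].reshape(len(members), -1)

    donor_eff = rng.normal(0, np.sqrt(frac["donor"]), size=(config.n_donors, t))
    donor_eff = donor_eff + _donor_genetic_shift(config, genotypes, truth)
    truth.effects = list(config.planted_effects)

    rows_meta = []
    blocks = []
    cell_counter = 0
    for d in range(config.n_donors):
        p = plates[d]
        for w in range(wells_per_plate_donor):
            position = donor_positions[d, w]
            n_cells = max(1, int(rng.poisson(config.cells_per_well_mean)))
            vals = (
                plate_eff[p]
                + well_eff[position]
                + donor_eff[d]
                + rng.normal(0, np.sqrt(frac["residual"]), size=(n_cells, t))
            )
            isolate = rng.random(n_cells) < config.isolate_fraction
            neighbors = np.where(isolate, 0, 1 + rng.poisson(3, size=n_cells))
            blocks.append(vals)
            rows_meta.append(
                pd.DataFrame(
                    {
                        "cell_id": np.arange(cell_counter, cell_counter + n_cells),
                        "plate_id": f"P{p + 1}",
                        "well_id": _well_label(position),
                        "on_edge": _well_on_edge(position),
                        "donor_id": genotypes.donors[d],
                        "neighbor_count": neighbors,
                    }
                )
            )
            cell_counter += n_cells

    values = np.vstack(blocks)
    if config.missing_cell_fraction > 0:
        miss_rng = _rng(config, "missingness")
        n_cells_total = len(values)
        n_affected = int(round(config.missing_cell_fraction * n_cells_total))
        affected = miss_rng.choice(n_cells_total, size=n_affected, replace=False)
        n_traits_missing = max(1, int(round(config.missing_trait_fraction * t)))
        for i in affected:
            cols = miss_rng.choice(t, size=n_traits_missing, replace=False)
            values[i, cols] = np.nan

    meta = pd.concat(rows_meta, ignore_index=True)
    table = pd.concat(
        [meta, pd.DataFrame(values, columns=config.trait_names())], axis=1
    )
    table["cell_id"] = "c" + table["cell_id"].astype(str)
    return table, truth


def _carriers_from_genotypes(genotypes: GenotypeSet) -> dict[str, list[int]]:
    carriers: dict[str, list[int]] = {}
    ann = genotypes.annotation
    genes = ann.loc[ann["gene"].astype(str) != "", "gene"]
    for gene, ids in genes.groupby(genes).groups.items():
        idx = genotypes.variants.index.get_indexer(ids)
        carrier = np.nansum(genotypes.dosages[:, idx], axis=1) >= 1
        carriers[str(gene)] = np.nonzero(carrier)[0].tolist()
    return carriers


# --------------------------------------------------------------------------
# Fast path: well-level trait draws for variance-component calibration
# --------------------------------------------------------------------------

def simulate_well_level_trait(
    fractions: dict[str, float],
    n_donors: int,
    wells_per_donor: int,
    n_plates: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """One trait at well level with the given variance fractions.

    Skips single-cell generation: the well value is plate + well-position +
    donor + well-level residual. Returns the table and the *realized*
    variance fractions (empirical variance of each drawn component across
    rows) — with few factor levels (e.g. 7 plates) the realized batch
    variance differs from its expectation by far more than any estimator's
    error, so realized fractions are the right recovery target.
    """
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError("fractions must sum to 1")
    plates = (np.arange(n_donors) * n_plates) // n_donors
    plate_eff = rng.normal(0, np.sqrt(fractions.get("plate", 0.0)), n_plates)
    donor_eff = rng.normal(0, np.sqrt(fractions.get("donor", 0.0)), n_donors)
    donors_per_plate = int(np.bincount(plates, minlength=n_plates).max())
    n_positions = donors_per_plate * wells_per_donor
    well_eff = rng.normal(0, np.sqrt(fractions.get("well", 0.0)), n_positions)

    rank_in_plate = np.zeros(n_donors, dtype=int)
    seen: dict[int, int] = {}
    for d, p in enumerate(plates):
        rank_in_plate[d] = seen.get(p, 0)
        seen[p] = rank_in_plate[d] + 1

    rows = []
    comps = {"plate": [], "well": [], "donor": [], "residual": []}
    for d in range(n_donors):
        for w in range(wells_per_donor):
            position = rank_in_plate[d] * wells_per_donor + w
            e = rng.normal(0, np.sqrt(fractions.get("residual", 0.0)))
            y = plate_eff[plates[d]] + well_eff[position] + donor_eff[d] + e
            comps["plate"].append(plate_eff[plates[d]])
            comps["well"].append(well_eff[position])
            comps["donor"].append(donor_eff[d])
            comps["residual"].append(e)
            rows.append((f"P{plates[d] + 1}", _well_label(position), f"D{d:04d}", y))
    realized_var = {k: float(np.var(v)) for k, v in comps.items()}
    total_var = sum(realized_var.values())
    realized = {k: v / total_var for k, v in realized_var.items()}
    table = pd.DataFrame(rows, columns=["plate_id", "well_id", "donor_id", "value"])
    return table, realized
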