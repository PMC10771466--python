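"""Single-cell morphology profile processing.

Raw cell x trait tables are QC'd (cell-level missingness, problematic /
non-variable traits), split into colony vs isolate context by neighbor
count, averaged to well level, gaussianized per trait by rank-based inverse
normal transformation across all plates, pruned to a near-nonredundant
composite trait set (pairwise |Pearson r| below threshold), and pseudo-
bulked to one value per donor per trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from cmqtl.simulate import META_COLS

logger = logging.getLogger(__name__)

WELL_META = ["plate_id", "well_id", "donor_id", "on_edge", "n_cells", "neighbor_count"]


class EmptyResultError(ValueError):
    """A QC step removed everything."""


def trait_columns(table: pd.DataFrame) -> list[str]:
    meta = set(META_COLS) | set(WELL_META)
    return [c for c in table.columns if c not in meta]


# --------------------------------------------------------------------------
# Cell- and trait-level QC
# --------------------------------------------------------------------------

def qc_cells(table: pd.DataFrame, max_missing_fraction: float = 0.05) -> pd.DataFrame:
    """Drop cells missing more than ``max_missing_fraction`` of traits."""
    if not 0.0 < max_missing_fraction < 1.0:
        raise ValueError("max_missing_fraction must be in (0,1)")
    traits = trait_columns(table)
    miss = table[traits].isna().mean(axis=1)
    kept = table.loc[miss <= max_missing_fraction]
    logger.info("qc_cells: retained %d / %d cells", len(kept), len(table))
    if kept.empty:
        raise EmptyResultError("cell QC removed all cells")
    return kept


def qc_traits(
    table: pd.DataFrame,
    blocklist: tuple[str, ...] = (),
    variance_tol: float = 1e-12,
) -> pd.DataFrame:
    """Drop blocklisted, structurally absent, and (near) zero-variance traits.

    ``blocklist`` is the user's "a priori problematic" trait list; a trait
    with any all-missing column or with variance <= ``variance_tol`` over
    observed cells is removed.
    """
    traits = trait_columns(table)
    drop = set(blocklist) & set(traits)
    values = table[traits]
    all_missing = values.columns[values.isna().all()]
    drop |= set(all_missing)
    variances = values.var(axis=0, ddof=1)
    drop |= set(variances.index[(variances.fillna(0.0) <= variance_tol)])
    kept = [c for c in traits if c not in drop]
    logger.info("qc_traits: retained %d / %d traits (dropped %d)", len(kept), len(traits), len(drop))
    meta = [c for c in table.columns if c not in traits]
    return table[meta + kept]


def split_context(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(colony, isolate): cells with >=1 neighbor vs none."""
    if "neighbor_count" not in table.columns:
        raise ValueError("table lacks neighbor_count")
    isolate = table["neighbor_count"] == 0
    return table.loc[~isolate], table.loc[isolate]


# --------------------------------------------------------------------------
# Well-level aggregation and the inverse normal transform
# --------------------------------------------------------------------------

def aggregate_wells(table: pd.DataFrame) -> pd.DataFrame:
    """Mean per (plate, well, donor) over retained cells, ignoring missing.

    Carries the retained-cell count, the well's edge flag, and the mean
    neighbor count (used downstream as the colony-context covariate).
    """
    traits = trait_columns(table)
    grouped = table.groupby(["plate_id", "well_id", "donor_id"], sort=True, observed=True)
    out = grouped[traits].mean()
    out.insert(0, "n_cells", grouped.size())
    out.insert(1, "on_edge", grouped["on_edge"].first())
    out.insert(2, "neighbor_count", grouped["neighbor_count"].mean())
    return out.reset_index()


def inverse_normal_transform(
    well_matrix: pd.DataFrame, c: float = 3.0 / 8.0
) -> pd.DataFrame:
    """Rank-based inverse normal transform, per trait, across all rows.

    Each trait value becomes Phi^-1((rank - c) / (n - 2c + 1)) with average
    ranks for ties and c = 3/8 (Blom offset) by default; computed jointly
    across plates so plate differences remain as (gaussianized) signal for
    the variance decomposition and as covariate-absorbed structure in the
    association models.
    """
    out = well_matrix.copy()
    for trait in trait_columns(well_matrix):
        x = well_matrix[trait].to_numpy(dtype=float)
        obs = ~np.isnan(x)
        v = x[obs]
        if np.unique(v).size < 2:
            raise ValueError(f"trait {trait!r} is constant; run qc_traits first")
        ranks = stats.rankdata(v, method="average")
        q = (ranks - c) / (len(v) - 2 * c + 1)
        z = np.full_like(x, np.nan)
        z[obs] = stats.norm.ppf(q)
        out[trait] = z
    return out


# --------------------------------------------------------------------------
# Composite trait selection
# --------------------------------------------------------------------------

@dataclass
class CompositeTraitSet:
    """Greedy near-nonredundant trait set and its selection log."""

    retained: list[str]
    log: list[dict] = field(default_factory=list)
    threshold: float = 0.9


def select_composite_traits(
    correlation_matrices: list[pd.DataFrame],
    threshold: float = 0.9,
    signed: bool = False,
) -> CompositeTraitSet:
    """Iterative greedy pruning of correlated traits.

    At each step: count, per trait, its neighbors at |r| >= ``threshold``
    summed across all matrices (both contexts); retain the max-count trait
    as a hub (ties: lexicographically smallest name) and remove it together
    with all its neighbors; repeat. Remaining zero-neighbor traits are all
    retained. With ``signed=True``, only positive r >= threshold counts.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0,1)")
    if not correlation_matrices:
        raise ValueError("need at least one correlation matrix")
    traits = list(correlation_matrices[0].columns)
    for m in correlation_matrices:
        if list(m.columns) != traits or list(m.index) != traits:
            raise ValueError("correlation matrices must share one trait set")

    # boolean neighbor relation per matrix (diagonal excluded)
    adjacency = np.zeros((len(traits), len(traits)), dtype=int)
    for m in correlation_matrices:
        r = m.to_numpy(dtype=float)
        a = (r if signed else np.abs(r)) >= threshold
        np.fill_diagonal(a, False)
        a = np.nan_to_num(a).astype(bool)
        adjacency += a
    any_adj = adjacency > 0

    name = np.array(traits)
    active = np.ones(len(traits), dtype=bool)
    retained: list[str] = []
    log: list[dict] = []
    iteration = 0
    while active.any():
        counts = (adjacency * active).sum(axis=1)
        counts[~active] = -1
        max_count = counts.max()
        if max_count <= 0:
            rest = sorted(name[active])
            retained.extend(rest)
            log.append({"iteration": iteration, "selected": rest, "removed": []})
            break
        candidates = np.nonzero(counts == max_count)[0]
        hub = candidates[np.argsort(name[candidates])[0]]
        neighbors = np.nonzero(any_adj[hub] & active)[0]
        retained.append(str(name[hub]))
        log.append(
            {
                "iteration": iteration,
                "selected": str(name[hub]),
                "removed": [str(n) for n in name[neighbors]],
            }
        )
        active[hub] = False
        active[neighbors] = False
        iteration += 1

    result = CompositeTraitSet(retained=sorted(retained), log=log, threshold=threshold)
    _assert_nonredundant(result, correlation_matrices, threshold, signed)
    return result


def _assert_nonredundant(
    cset: CompositeTraitSet,
    matrices: list[pd.DataFrame],
    threshold: float,
    signed: bool,
) -> None:
    for m in matrices:
        sub = m.loc[cset.retained, cset.retained].to_numpy(dtype=float)
        np.fill_diagonal(sub, 0.0)
        worst = np.nanmax(sub if signed else np.abs(sub)) if len(cset.retained) > 1 else 0.0
        if worst >= threshold:
            raise AssertionError(
                f"composite set violates |r| < {threshold}: worst retained pair r={worst:.4f}"
            )


def donor_level_correlation(donor_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between traits at donor level."""
    return donor_matrix[trait_columns(donor_matrix)].corr(method="pearson")


# --------------------------------------------------------------------------
# Pseudo-bulking
# --------------------------------------------------------------------------

def pseudo_bulk(
    well_matrix: pd.DataFrame, traits: list[str] | CompositeTraitSet | None = None
) -> pd.DataFrame:
    """Donor x trait means over each donor's wells (one row per donor)."""
    if isinstance(traits, CompositeTraitSet):
        traits = traits.retained
    if traits is None:
        traits = trait_columns(well_matrix)
    missing = set(traits) - set(well_matrix.columns)
    if missing:
        raise ValueError(f"traits absent from well matrix: {sorted(missing)[:5]}")
    out = well_matrix.groupby("donor_id", sort=True, observed=True)[list(traits)].mean()
    empty = out.index[out.isna().all(axis=1)]
    if len(empty):
        logger.warning("pseudo_bulk: dropping %d donors with no wells", len(empty))
        out = out.drop(index=empty)
    return out


def donor_neighbor_means(well_matrix: pd.DataFrame) -> pd.Series:
    """Cell-weighted mean neighbor count per donor (colony covariate)."""
    w = well_matrix
    weighted = (w["neighbor_count"] * w["n_cells"]).groupby(w["donor_id"]).sum()
    return weighted / w.groupby("donor_id")["n_cells"].sum()
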