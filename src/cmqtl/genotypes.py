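"""Genotype QC, Hardy-Weinberg testing, LD pruning, GRM/PCA, burden collapsing.

Dosages are held as a dense donors x variants float matrix with NaN for
missing calls — cohort-genetics scale here is hundreds of donors and (at
desk scale) thousands of variants, where dense is simplest and fastest.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AUTOSOMES = {str(i) for i in range(1, 23)}

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")


@dataclass
class GenotypeSet:
    """Donor x variant dosage matrix plus per-variant metadata.

    ``variants`` is indexed by variant id with columns chrom, pos (1-based),
    ref, alt, filter; ``annotation`` maps variant id -> gene, impact.
    """

    donors: np.ndarray  # donor ids, shape (n_donors,)
    variants: pd.DataFrame  # index: variant id
    dosages: np.ndarray  # float, NaN = missing, shape (n_donors, n_variants)
    annotation: pd.DataFrame  # index: variant id; columns gene, impact

    def __post_init__(self) -> None:
        self.donors = np.asarray(self.donors)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.donors), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.donors)} donors x {len(self.variants)} variants"
            )
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, [0.0, 1.0, 2.0]).all():
            raise ValueError("dosages must be in {0,1,2} or missing")

    @property
    def n_donors(self) -> int:
        return len(self.donors)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants.index.to_numpy()

    # --- per-variant statistics (computed on observed genotypes) ---

    def allele_frequency(self) -> np.ndarray:
        """Alternate-allele frequency per variant over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        af = self.allele_frequency()
        return np.minimum(af, 1.0 - af)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def donor_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def genotype_counts(self) -> np.ndarray:
        """(n_variants, 3) counts of hom-ref / het / hom-alt."""
        out = np.empty((self.n_variants, 3), dtype=int)
        for g in (0, 1, 2):
            out[:, g] = np.nansum(self.dosages == g, axis=0)
        return out

    def hwe_pvalues(self) -> np.ndarray:
        counts = self.genotype_counts()
        return np.array([hwe_exact_test(aa, ab, bb) for aa, ab, bb in counts])

    # --- subsetting ---

    def subset_variants(self, ids: Iterable[str]) -> "GenotypeSet":
        ids = list(ids)
        idx = self.variants.index.get_indexer(ids)
        if (idx < 0).any():
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise KeyError(f"unknown variant ids: {missing[:5]}")
        return replace(
            self,
            variants=self.variants.loc[ids],
            dosages=self.dosages[:, idx],
            annotation=self.annotation.loc[self.annotation.index.intersection(ids)].reindex(ids).dropna(how="all"),
        )

    def subset_donors(self, mask: np.ndarray) -> "GenotypeSet":
        return replace(self, donors=self.donors[mask], dosages=self.dosages[mask])

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.donors, columns=self.variants.index)


@dataclass
class GeneBurdenMatrix:
    """Donor x gene carrier indicators for qualifying rare variants."""

    indicators: pd.DataFrame  # donors x genes, values in {0,1}
    contributing_variants: dict[str, list[str]] = field(default_factory=dict)

    @property
    def carrier_counts(self) -> pd.Series:
        return self.indicators.sum(axis=0).astype(int)

    @property
    def genes(self) -> list[str]:
        return list(self.indicators.columns)


@dataclass
class AncestryPCs:
    """Top ancestry principal components from a genetic relatedness matrix."""

    components: pd.DataFrame  # donors x PC1..PCk, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray


# --------------------------------------------------------------------------
# Hardy-Weinberg exact test
# --------------------------------------------------------------------------

def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test (Wigginton-style enumeration).

    Enumerates all heterozygote counts compatible with the observed allele
    counts via the stable probability recurrence, and sums the probabilities
    of configurations no more likely than the observed one.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotype")
    # work with the minor allele
    n_rare = 2 * min(n_aa, n_bb) + n_ab
    # heterozygote counts share the parity of the rare-allele count
    het_min = n_rare % 2
    het_max = min(n_rare, 2 * n - n_rare)
    n_het_values = (het_max - het_min) // 2 + 1
    probs = np.empty(n_het_values, dtype=float)

    # start from the midpoint for numerical stability of the recurrence
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if (mid - het_min) % 2 != 0:
        mid += 1
    idx_mid = (mid - het_min) // 2
    probs[idx_mid] = 1.0
    # downward: P(h-2) = P(h) * h*(h-1) / ((r-h+2)/2 * (c-h+2)/2) with
    # r = rare hom count*2 relation; use standard ratios
    het = mid
    rare_hom = (n_rare - mid) // 2
    common_hom = n - mid - rare_hom
    h, rh, ch = het, rare_hom, common_hom
    for i in range(idx_mid, 0, -1):
        probs[i - 1] = probs[i] * (h * (h - 1)) / (4.0 * (rh + 1) * (ch + 1))
        h -= 2
        rh += 1
        ch += 1
    h, rh, ch = het, rare_hom, common_hom
    for i in range(idx_mid, n_het_values - 1):
        probs[i + 1] = probs[i] * (4.0 * rh * ch) / ((h + 2.0) * (h + 1.0))
        h += 2
        rh -= 1
        ch -= 1
    probs /= probs.sum()
    p_obs = probs[(n_ab - het_min) // 2]
    # two-sided: sum configurations with probability <= observed
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


# --------------------------------------------------------------------------
# Common-variant QC
# --------------------------------------------------------------------------

@dataclass
class QCReport:
    counts: dict[str, int]

    def __str__(self) -> str:
        return ", ".join(f"{k}={v}" for k, v in self.counts.items())


def qc_common_variants(
    g: GenotypeSet,
    maf_min: float = 0.05,
    miss_max: float = 0.05,
    hwe_p_min: float = 1e-5,
    donor_miss_max: float = 0.10,
    max_indel_bp: int = 5,
    require_pass: bool = True,
) -> tuple[GenotypeSet, QCReport]:
    """Variant and donor QC for the common-variant association arm.

    Structural filters first (autosomal, biallelic SNV/short-indel, unique
    position, FILTER=PASS), then donors with call rate below
    ``1 - donor_miss_max`` are dropped, then the statistical filters
    (MAF, missingness, Hardy-Weinberg exact p).
    """
    v = g.variants
    counts = {"input": g.n_variants}

    chrom = v["chrom"].astype(str).str.removeprefix("chr")
    autosomal = chrom.isin(AUTOSOMES)
    alt = v["alt"].astype(str)
    biallelic = ~alt.str.contains(",")
    indel_len = (v["ref"].astype(str).str.len() - alt.str.len()).abs()
    small = indel_len <= max_indel_bp
    dup = v.duplicated(subset=["chrom", "pos"], keep=False)
    structural = autosomal & biallelic & small & ~dup
    if require_pass and "filter" in v.columns:
        structural &= v["filter"].fillna("PASS").isin(["PASS", "."])
    g = g.subset_variants(v.index[structural.to_numpy()])
    counts["structural_pass"] = g.n_variants

    donor_keep = g.donor_call_rate() >= 1.0 - donor_miss_max
    n_dropped = int((~donor_keep).sum())
    if n_dropped:
        g = g.subset_donors(donor_keep)
    counts["donors_dropped"] = n_dropped

    maf = g.maf()
    call = g.call_rate()
    hwe = g.hwe_pvalues()
    keep = (maf >= maf_min) & (1.0 - call <= miss_max) & (hwe >= hwe_p_min)
    counts["maf_fail"] = int((maf < maf_min).sum())
    counts["missing_fail"] = int((1.0 - call > miss_max).sum())
    counts["hwe_fail"] = int((hwe < hwe_p_min).sum())
    g = g.subset_variants(g.variants.index[keep])
    counts["retained"] = g.n_variants
    report = QCReport(counts)
    logger.info("common-variant QC: %s", report)
    return g, report


# --------------------------------------------------------------------------
# LD pruning
# --------------------------------------------------------------------------

def _pairwise_r2(x: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns (mean-imputed)."""
    x = x.copy()
    col_mean = np.nanmean(x, axis=0)
    nan_mask = np.isnan(x)
    if nan_mask.any():
        x[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    sd[sd == 0] = np.nan
    r = (xc.T @ xc) / len(x) / np.outer(sd, sd)
    return r**2


def ld_prune(
    g: GenotypeSet,
    mode: Literal["bp", "count"] = "bp",
    r2_threshold: float | None = None,
    window: int | None = None,
    step: int | None = None,
    exclude_regions: Sequence[tuple[str, int, int]] = (),
) -> list[str]:
    """Greedy sliding-window LD pruning; returns retained variant ids.

    ``bp`` mode defaults to r² > 0.1 in 50 kb windows sliding by 10 kb
    (ancestry-PCA pruning); ``count`` mode defaults to r² > 0.2 in windows
    of 50 variants shifting by 5 (PLINK --indep-pairwise style, used ahead
    of the effect-size-mixture fit). Within each window, while any retained
    pair exceeds the threshold, the member with the smaller MAF is removed
    (tie: the later position). ``exclude_regions`` are 0-based half-open
    (chrom, start, end) intervals (long-range LD) removed up front.
    """
    defaults = {"bp": (0.1, 50_000, 10_000), "count": (0.2, 50, 5)}
    if mode not in defaults:
        raise ValueError(f"unknown mode {mode!r}")
    d_r2, d_win, d_step = defaults[mode]
    r2_threshold = d_r2 if r2_threshold is None else r2_threshold
    window = d_win if window is None else window
    step = d_step if step is None else step

    v = g.variants
    pos = v["pos"].to_numpy()
    chroms = v["chrom"].astype(str).to_numpy()
    for c in np.unique(chroms):
        p = pos[chroms == c]
        if (np.diff(p) < 0).any():
            raise ValueError(f"variants on chromosome {c} are not position-sorted")

    keep_ids: list[str] = []
    maf_all = pd.Series(g.maf(), index=v.index)
    for c in pd.unique(chroms):
        mask = chroms == c
        ids = v.index[mask].to_numpy()
        p = pos[mask]
        in_excluded = np.zeros(len(ids), dtype=bool)
        for ec, start, end in exclude_regions:
            if str(ec).removeprefix("chr") == str(c).removeprefix("chr"):
                in_excluded |= (p >= start + 1) & (p <= end)  # BED half-open -> 1-based
        ids = ids[~in_excluded]
        p = p[~in_excluded]
        if len(ids) == 0:
            continue
        retained = dict.fromkeys(ids, True)  # ordered
        dose = g.dosage_frame()

        def window_slices() -> Iterable[np.ndarray]:
            if mode == "bp":
                lo = p.min()
                while lo <= p.max():
                    yield ids[(p >= lo) & (p < lo + window)]
                    lo += step
            else:
                for start_i in range(0, len(ids), step):
                    yield ids[start_i : start_i + window]
                    if start_i + window >= len(ids):
                        break

        for win_ids in window_slices():
            active = [i for i in win_ids if retained[i]]
            if len(active) < 2:
                continue
            x = dose[active].to_numpy()
            r2 = _pairwise_r2(x)
            pos_of = {i: q for i, q in zip(ids, p)}
            while True:
                iu = np.triu_indices(len(active), k=1)
                vals = r2[iu]
                bad = vals > r2_threshold
                if not bad.any() or len(active) < 2:
                    break
                j = int(np.nanargmax(np.where(bad, vals, -np.inf)))
                a, b = active[iu[0][j]], active[iu[1][j]]
                ma, mb = maf_all[a], maf_all[b]
                if ma < mb:
                    drop = a
                elif mb < ma:
                    drop = b
                else:
                    drop = a if pos_of[a] > pos_of[b] else b
                retained[drop] = False
                k = active.index(drop)
                active.pop(k)
                r2 = np.delete(np.delete(r2, k, axis=0), k, axis=1)
        keep_ids.extend(i for i in ids if retained[i])
    return keep_ids


# --------------------------------------------------------------------------
# GRM and ancestry PCA
# --------------------------------------------------------------------------

def compute_grm(g: GenotypeSet) -> pd.DataFrame:
    """Genetic relatedness matrix, GCTA convention.

    G_jk = (1/M) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i)),
    with missing dosages mean-imputed per variant and monomorphic variants
    skipped.
    """
    x = g.dosages.copy()
    col_mean = np.nanmean(x, axis=0)
    nan_mask = np.isnan(x)
    if nan_mask.any():
        x[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    p = x.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.warning("compute_grm: skipping %d monomorphic variants", n_mono)
    if not poly.any():
        raise ValueError("no polymorphic variants for GRM")
    x = x[:, poly]
    p = p[poly]
    w = (x - 2 * p) / np.sqrt(2 * p * (1 - p))
    grm = (w @ w.T) / w.shape[1]
    return pd.DataFrame(grm, index=g.donors, columns=g.donors)


def pca_from_grm(grm: pd.DataFrame, k: int = 20) -> AncestryPCs:
    """Top-k eigenvectors of the GRM scaled by sqrt(eigenvalue).

    Sign convention: within each PC the largest-magnitude loading is made
    positive, so results are deterministic across LAPACK builds.
    """
    n = len(grm)
    if k > n:
        raise ValueError(f"k={k} exceeds number of donors {n}")
    a = np.asarray(grm, dtype=float)
    a = (a + a.T) / 2.0
    vals, vecs = np.linalg.eigh(a)
    order = np.argsort(vals)[::-1][:k]
    vals = vals[order]
    vecs = vecs[:, order]
    for j in range(k):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    comps = vecs * np.sqrt(np.clip(vals, 0.0, None))
    frame = pd.DataFrame(comps, index=grm.index, columns=[f"PC{i+1}" for i in range(k)])
    return AncestryPCs(components=frame, eigenvalues=vals)


# --------------------------------------------------------------------------
# Rare-variant burden collapsing
# --------------------------------------------------------------------------

def collapse_rare_burden(
    g: GenotypeSet,
    maf_max: float = 0.01,
    call_rate_min: float = 0.95,
    impacts: frozenset[str] | set[str] = frozenset({"HIGH", "MODERATE"}),
    min_carrier_fraction: float = 0.02,
    require_pass: bool = True,
) -> GeneBurdenMatrix:
    """Collapse qualifying rare variants to a per-gene carrier indicator.

    Qualifying: autosomal, FILTER=PASS, call rate > ``call_rate_min``,
    MAF < ``maf_max``, annotated impact in ``impacts``. A donor is a carrier
    of a gene iff it has >=1 alternate allele at any qualifying variant.
    Genes carried by fewer than ceil(min_carrier_fraction * n_donors) donors
    are dropped.
    """
    ann = g.annotation
    v = g.variants.join(ann, how="left")
    chrom = v["chrom"].astype(str).str.removeprefix("chr")
    mask = chrom.isin(AUTOSOMES).to_numpy()
    if require_pass and "filter" in v.columns:
        mask &= v["filter"].fillna("PASS").isin(["PASS", "."]).to_numpy()
    mask &= (g.call_rate() > call_rate_min) & (g.maf() < maf_max)
    mask &= v["impact"].isin(list(impacts)).to_numpy()
    mask &= v["gene"].notna().to_numpy() & (v["gene"].astype(str) != "").to_numpy()

    qualifying = v.index[mask]
    min_carriers = math.ceil(min_carrier_fraction * g.n_donors)
    indicators: dict[str, np.ndarray] = {}
    contributing: dict[str, list[str]] = {}
    for gene, sub in v.loc[qualifying].groupby("gene", sort=True):
        idx = g.variants.index.get_indexer(sub.index)
        carrier = np.nansum(g.dosages[:, idx], axis=1) >= 1
        if int(carrier.sum()) >= min_carriers:
            indicators[str(gene)] = carrier.astype(int)
            contributing[str(gene)] = list(sub.index)
    frame = pd.DataFrame(indicators, index=g.donors)
    logger.info(
        "burden collapsing: %d qualifying variants -> %d genes with >= %d carriers",
        len(qualifying), frame.shape[1], min_carriers,
    )
    return GeneBurdenMatrix(indicators=frame, contributing_variants=contributing)
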