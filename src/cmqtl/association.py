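"""Burden and common-variant association testing with permutation nulls.

Both arms share one covariate model: gaussianized donor-level trait ~
predictor + age + sex + ancestry PCs 1-4 + plate indicators (+ mean
neighbor count in the colony context). The scan is ordinary least squares;
with plates entering as fixed categorical indicators this matches a
fastGWA-lr style linear-regression engine at donor-level data. Tests are
vectorized by residualizing traits and predictors on the shared covariates
(Frisch-Waugh), which leaves per-pair statistics exactly equal to the full
OLS fit with the correct residual degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from cmqtl.genotypes import GeneBurdenMatrix, GenotypeSet

logger = logging.getLogger(__name__)

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))  # 0.4549 to 4 s.f.


@dataclass
class ScanSummary:
    """A scan's tests plus thresholds, inflation, and hit lists."""

    tests: pd.DataFrame
    significance_threshold: float
    suggestive_threshold: float
    lambda_gc: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.tests.loc[self.tests["p"] < self.significance_threshold]

    @property
    def suggestive(self) -> pd.DataFrame:
        return self.tests.loc[self.tests["p"] < self.suggestive_threshold]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    return alpha / n_tests


def genomic_lambda(p_values: np.ndarray | pd.Series) -> float:
    """Genomic inflation factor: median observed chi2_1 over its null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)


# --------------------------------------------------------------------------
# Covariate model
# --------------------------------------------------------------------------

def build_covariates(
    metadata: pd.DataFrame,
    pcs: pd.DataFrame | None = None,
    plates: pd.Series | None = None,
    neighbor_means: pd.Series | None = None,
    context: str = "colony",
) -> pd.DataFrame:
    """Donor-indexed covariate matrix (with intercept).

    age (quantitative), sex (indicator), ancestry PCs 1-4, plate indicator
    columns (first level dropped), and in the colony context the donor's
    mean neighbor count.
    """
    donors = metadata.index
    cols = {"intercept": np.ones(len(donors))}
    cols["age"] = metadata["age"].astype(float).to_numpy()
    sex = metadata["sex"]
    cols["sex_male"] = (sex.astype(str) == "male").astype(float).to_numpy()
    frame = pd.DataFrame(cols, index=donors)
    if pcs is not None:
        frame = frame.join(pcs.iloc[:, :4].astype(float))
    if plates is not None:
        dummies = pd.get_dummies(plates.reindex(donors), prefix="plate", drop_first=True)
        frame = frame.join(dummies.astype(float))
    if context == "colony":
        if neighbor_means is None:
            raise ValueError("colony context requires neighbor_means")
        frame["neighbor_count"] = neighbor_means.reindex(donors).astype(float)
    if frame.isna().any().any():
        missing = frame.columns[frame.isna().any()].tolist()
        raise ValueError(f"covariates contain missing values: {missing}")
    return frame


# --------------------------------------------------------------------------
# Vectorized OLS scan core
# --------------------------------------------------------------------------

def _residualize(a: np.ndarray, q: np.ndarray) -> np.ndarray:
    return a - q @ (q.T @ a)

def ols_scan(
    predictors: pd.DataFrame,
    traits: pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """OLS of every trait on every predictor with shared covariates.

    Returns long-format (predictor, trait, beta, se, t, p, n). Predictors
    that are collinear with the covariates (no residual variation) are
    skipped with a diagnostic row marked by NaN statistics.
    """
    donors = traits.index
    if not (predictors.index.equals(donors) and covariates.index.equals(donors)):
        predictors = predictors.loc[donors]
        covariates = covariates.loc[donors]
    C = covariates.to_numpy(dtype=float)
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    q, _ = np.linalg.qr(C)
    Y = _residualize(traits.to_numpy(dtype=float), q)
    X = _residualize(predictors.to_numpy(dtype=float), q)
    n, p_cov = C.shape
    df = n - p_cov - 1
    if df <= 0:
        raise ValueError("not enough donors for the covariate model")

    xx = (X**2).sum(axis=0)  # per predictor
    degenerate = xx < 1e-10 * n
    xx_safe = np.where(degenerate, 1.0, xx)
    xty = X.T @ Y  # predictors x traits
    beta = xty / xx_safe[:, None]
    yy = (Y**2).sum(axis=0)  # per trait
    rss = yy[None, :] - beta**2 * xx_safe[:, None]
    rss = np.clip(rss, 0.0, None)
    se = np.sqrt(rss / df / xx_safe[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)

    out = pd.DataFrame(
        {
            "predictor": np.repeat(predictors.columns.to_numpy(), traits.shape[1]),
            "trait": np.tile(traits.columns.to_numpy(), predictors.shape[1]),
            "beta": beta.ravel(),
            "se": se.ravel(),
            "t": t.ravel(),
            "p": np.clip(p.ravel(), np.finfo(float).tiny, 1.0),
            "n": n,
        }
    )
    if degenerate.any():
        bad = predictors.columns[degenerate]
        logger.warning("ols_scan: %d predictors collinear with covariates, skipped", len(bad))
        mask = out["predictor"].isin(bad)
        out.loc[mask, ["beta", "se", "t", "p"]] = np.nan
    return out


# --------------------------------------------------------------------------
# The two association arms
# --------------------------------------------------------------------------

def burden_regression(
    traits: pd.DataFrame,
    burden: GeneBurdenMatrix,
    covariates: pd.DataFrame,
    context: str = "colony",
) -> pd.DataFrame:
    """Gene-level rare-variant burden scan over all traits."""
    tests = ols_scan(burden.indicators.astype(float), traits, covariates)
    tests = tests.rename(columns={"predictor": "gene"})
    tests["context"] = context
    return tests


def common_variant_scan(
    traits: pd.DataFrame,
    genotypes: GenotypeSet | pd.DataFrame,
    covariates: pd.DataFrame,
    context: str = "colony",
) -> pd.DataFrame:
    """Per-variant additive-dosage scan over all traits.

    Variants with missing dosages are tested per variant on the donors with
    observed calls; variants monomorphic after missingness are skipped.
    """
    dose = genotypes.dosage_frame() if isinstance(genotypes, GenotypeSet) else genotypes
    dose = dose.loc[traits.index]
    complete = dose.columns[dose.notna().all()]
    partial = dose.columns.difference(complete, sort=False)

    results = []
    if len(complete):
        nondegenerate = [c for c in complete if dose[c].nunique() > 1]
        skipped = len(complete) - len(nondegenerate)
        if skipped:
            logger.warning("common_variant_scan: %d monomorphic variants skipped", skipped)
        if nondegenerate:
            results.append(ols_scan(dose[nondegenerate], traits, covariates))
    for variant in partial:
        obs = dose[variant].notna()
        if dose.loc[obs, variant].nunique() < 2 or obs.sum() <= covariates.shape[1] + 1:
            logger.warning("common_variant_scan: %s monomorphic/underdetermined after missingness", variant)
            continue
        results.append(
            ols_scan(dose.loc[obs, [variant]], traits.loc[obs], covariates.loc[obs])
        )
    if not results:
        return pd.DataFrame(columns=["variant", "trait", "beta", "se", "t", "p", "n", "context"])
    tests = pd.concat(results, ignore_index=True).rename(columns={"predictor": "variant"})
    tests["context"] = context
    return tests


def summarize_scan(
    tests: pd.DataFrame,
    significance_threshold: float,
    suggestive_threshold: float,
) -> ScanSummary:
    lam = genomic_lambda(tests["p"].dropna())
    return ScanSummary(
        tests=tests,
        significance_threshold=significance_threshold,
        suggestive_threshold=suggestive_threshold,
        lambda_gc=lam,
    )


# --------------------------------------------------------------------------
# Permutation null
# --------------------------------------------------------------------------

@dataclass
class PermutationNull:
    """Pooled null p-values and per-permutation inflation factors."""

    p_values: np.ndarray
    lambdas: np.ndarray
    n_perm: int
    mode: str
    per_perm_min_p: np.ndarray = field(default_factory=lambda: np.empty(0))


def permutation_null(
    traits: pd.DataFrame,
    predictors: pd.DataFrame,
    covariates: pd.DataFrame,
    mode: str = "shuffle_traits",
    n_perm: int = 10,
    seed: int = 0,
) -> PermutationNull:
    """Re-run the scan with donor labels permuted on one side.

    ``shuffle_traits`` permutes trait rows across donors (rare-variant arm
    validation); ``shuffle_genotypes`` permutes the predictor rows (common-
    variant arm). Covariates stay attached to the unshuffled side, so any
    signal tied to genotype-trait alignment is destroyed while the
    covariate structure is preserved.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("shuffle_traits", "shuffle_genotypes"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    pooled, lams, mins = [], [], []
    for _ in range(n_perm):
        perm = rng.permutation(len(traits))
        if mode == "shuffle_traits":
            t = pd.DataFrame(traits.to_numpy()[perm], index=traits.index, columns=traits.columns)
            x = predictors
        else:
            t = traits
            x = pd.DataFrame(predictors.to_numpy()[perm], index=predictors.index, columns=predictors.columns)
        tests = ols_scan(x, t, covariates)
        p = tests["p"].dropna().to_numpy()
        pooled.append(p)
        lams.append(genomic_lambda(p))
        mins.append(p.min())
    return PermutationNull(
        p_values=np.concatenate(pooled),
        lambdas=np.array(lams),
        n_perm=n_perm,
        mode=mode,
        per_perm_min_p=np.array(mins),
    )
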