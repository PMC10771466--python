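"""Variance decomposition of well-level traits by linear mixed model.

Each gaussianized trait is modelled with crossed random intercepts for the
cohort's technical and biological factors (disease status, source tissue,
sex, plate, well position, edge flag, donor/cell-line identity) plus fixed
covariates (age, ancestry PCs, and mean neighbor count in the colony
context). Variance ratios are estimated by REML with the residual variance
and fixed effects profiled out, optimizing over log variance ratios — a
boundary-safe parameterization. Per-component significance uses a
likelihood-ratio test against the 0.5*chi2_0 + 0.5*chi2_1 boundary mixture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

# covariance factors of the default well-level model; donor identity last so
# its share is what remains after the technical factors
DEFAULT_RANDOM = ["disease", "source_tissue", "sex", "plate_id", "well_id", "on_edge", "donor_id"]
DEFAULT_FIXED = ["age", "PC1", "PC2", "PC3", "PC4"]


@dataclass
class VarianceDecomposition:
    """Per-component variance fractions and significance for one trait."""

    trait: str
    fractions: dict[str, float]  # random factors + "fixed" + "residual"; sums to 1
    variances: dict[str, float]  # absolute variance components (incl. residual)
    fixed_effects: dict[str, float]
    pvalues: dict[str, float] = field(default_factory=dict)
    pvalues_bonferroni: dict[str, float] = field(default_factory=dict)
    loglik: float = np.nan
    converged: bool = True
    diagnostics: str = ""

    def fraction_sum(self) -> float:
        return float(sum(self.fractions.values()))


class _REMLProblem:
    """Profiled REML for a crossed random-intercept model.

    V = sigma2 * (I + sum_f gamma_f Z_f Z_f'); beta and sigma2 are profiled
    out, leaving an optimization over theta = log gamma.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, Z: list[np.ndarray]):
        self.y = y
        self.X = X
        self.Z = Z
        self.ZZ = [Zf @ Zf.T for Zf in Z]  # precomputed: the optimizer loops
        self.n, self.p = X.shape

    def _decompose(self, theta: np.ndarray):
        V0 = np.eye(self.n)
        for g, ZZf in zip(np.exp(theta), self.ZZ):
            V0 += g * ZZf
        L = np.linalg.cholesky(V0)
        logdet_v = 2.0 * np.log(np.diag(L)).sum()
        Xi = np.linalg.solve(L, self.X)  # L^-1 X
        yi = np.linalg.solve(L, self.y)
        xtvx = Xi.T @ Xi
        xtvy = Xi.T @ yi
        beta = np.linalg.solve(xtvx, xtvy)
        quad = float(yi @ yi - xtvy @ beta)
        sign, logdet_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite")
        return logdet_v, logdet_x, beta, max(quad, 1e-300)

    def reml_loglik(self, theta: np.ndarray) -> float:
        n, p = self.n, self.p
        logdet_v, logdet_x, _, quad = self._decompose(theta)
        sigma2 = quad / (n - p)
        return -0.5 * (
            (n - p) * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_v + logdet_x
        )

    def fit(self, max_restarts: int = 3) -> tuple[np.ndarray, float, bool]:
        k = len(self.Z)
        if k == 0:
            return np.empty(0), self.reml_loglik(np.empty(0)), True
        best = None
        # start at gamma=1; extra starts only if the optimizer struggles
        for x0 in [np.zeros(k), np.full(k, -3.0), np.full(k, 2.0)][:max_restarts]:
            try:
                res = optimize.minimize(
                    lambda t: -self.reml_loglik(t),
                    x0,
                    method="L-BFGS-B",
                    bounds=[(-14.0, 8.0)] * k,
                )
            except np.linalg.LinAlgError:
                continue
            if best is None or res.fun < best.fun - 1e-9:
                best = res
            if best is not None and best.success:
                break
        if best is None:
            raise RuntimeError("REML optimization failed from all starts")
        return best.x, -best.fun, bool(best.success)


def _design_matrices(
    design: pd.DataFrame, random_factors: list[str], fixed_terms: list[str]
) -> tuple[np.ndarray, list[np.ndarray], list[str]]:
    X_cols = [np.ones(len(design))]
    for term in fixed_terms:
        X_cols.append(design[term].to_numpy(dtype=float))
    X = np.column_stack(X_cols)
    Z, kept = [], []
    for factor in random_factors:
        codes, levels = pd.factorize(design[factor])
        if len(levels) < 2:
            raise ValueError(f"random factor {factor!r} has <2 levels")
        Zf = np.zeros((len(design), len(levels)))
        Zf[np.arange(len(design)), codes] = 1.0
        Z.append(Zf)
        kept.append(factor)
    return X, Z, kept


def fit_variance_components(
    trait_values: pd.Series | np.ndarray,
    design: pd.DataFrame,
    random_factors: list[str] | None = None,
    fixed_terms: list[str] | None = None,
    trait: str = "trait",
    compute_pvalues: bool = True,
    n_traits_for_correction: int = 1,
) -> VarianceDecomposition:
    """REML variance decomposition of one well-level trait.

    Returns fractions of total variance (random components + residual +
    variance of the fitted fixed-effect predictor across rows), which sum
    to 1 by construction, plus boundary-mixture LRT p-values per random
    factor and GLS t-test p-values per fixed term, Bonferroni-adjusted by
    ``n_traits_for_correction``.
    """
    random_factors = list(DEFAULT_RANDOM if random_factors is None else random_factors)
    fixed_terms = list(DEFAULT_FIXED if fixed_terms is None else fixed_terms)
    y = np.asarray(trait_values, dtype=float)
    if np.isnan(y).any():
        raise ValueError("missing trait values; aggregate/QC upstream")
    X, Z, random_factors = _design_matrices(design, random_factors, fixed_terms)

    problem = _REMLProblem(y, X, Z)
    try:
        theta, loglik, ok = problem.fit()
    except RuntimeError as exc:
        return VarianceDecomposition(
            trait=trait, fractions={}, variances={}, fixed_effects={},
            converged=False, diagnostics=str(exc),
        )
    logdet_v, logdet_x, beta, quad = problem._decompose(theta)
    sigma2 = quad / (problem.n - problem.p)
    gammas = np.exp(theta)
    variances = {f: float(g * sigma2) for f, g in zip(random_factors, gammas)}
    variances["residual"] = float(sigma2)

    fixed_pred = X @ beta
    var_fixed = float(np.var(fixed_pred))  # intercept drops out of the variance
    total = sum(variances.values()) + var_fixed
    fractions = {f: v / total for f, v in variances.items()}
    fractions["fixed"] = var_fixed / total
    fixed_effects = {"intercept": float(beta[0])}
    fixed_effects.update({t: float(b) for t, b in zip(fixed_terms, beta[1:])})

    decomp = VarianceDecomposition(
        trait=trait,
        fractions=fractions,
        variances=variances,
        fixed_effects=fixed_effects,
        loglik=loglik,
        converged=ok,
        diagnostics="" if ok else "optimizer reported non-convergence",
    )
    if compute_pvalues:
        for factor in random_factors:
            _, p = test_component_significance(
                y, design, random_factors, fixed_terms, factor, full_loglik=loglik
            )
            decomp.pvalues[factor] = p
        for term, p in _fixed_term_pvalues(problem, theta, fixed_terms).items():
            decomp.pvalues[term] = p
        decomp.pvalues_bonferroni = {
            k: min(1.0, v * n_traits_for_correction) for k, v in decomp.pvalues.items()
        }
    return decomp


def _fixed_term_pvalues(
    problem: _REMLProblem, theta: np.ndarray, fixed_terms: list[str]
) -> dict[str, float]:
    """GLS Wald t-tests for the fixed terms at the fitted covariance."""
    logdet_v, logdet_x, beta, quad = problem._decompose(theta)
    sigma2 = quad / (problem.n - problem.p)
    V0 = np.eye(problem.n)
    for g, Zf in zip(np.exp(theta), problem.Z):
        V0 += g * (Zf @ Zf.T)
    L = np.linalg.cholesky(V0)
    Xi = np.linalg.solve(L, problem.X)
    cov = sigma2 * np.linalg.inv(Xi.T @ Xi)
    df = problem.n - problem.p
    out = {}
    for j, term in enumerate(fixed_terms, start=1):
        t = beta[j] / np.sqrt(cov[j, j])
        out[term] = float(2.0 * stats.t.sf(abs(t), df))
    return out


def test_component_significance(
    trait_values: pd.Series | np.ndarray,
    design: pd.DataFrame,
    random_factors: list[str],
    fixed_terms: list[str],
    component: str,
    full_loglik: float | None = None,
) -> tuple[float, float]:
    """Boundary LRT for one random component; returns (statistic, p).

    Refits the model without ``component``; the statistic 2*(ll_full -
    ll_reduced) is referred to the equal mixture of a point mass at 0 and
    chi-square with 1 df, the standard null for a single variance tested on
    the boundary.
    """
    if component not in random_factors:
        raise ValueError(f"component {component!r} not in the random structure")
    y = np.asarray(trait_values, dtype=float)
    if full_loglik is None:
        X, Z, kept = _design_matrices(design, list(random_factors), list(fixed_terms))
        _, full_loglik, _ = _REMLProblem(y, X, Z).fit()
    reduced_factors = [f for f in random_factors if f != component]
    X, Z, _ = _design_matrices(design, reduced_factors, list(fixed_terms))
    _, reduced_loglik, _ = _REMLProblem(y, X, Z).fit()
    stat = max(0.0, 2.0 * (full_loglik - reduced_loglik))
    p = 1.0 if stat <= 1e-12 else 0.5 * float(stats.chi2.sf(stat, df=1))
    return stat, p


def decompose_traits(
    well_matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    pcs: pd.DataFrame | None = None,
    traits: list[str] | None = None,
    context: str = "colony",
    n_traits_for_correction: int | None = None,
    compute_pvalues: bool = True,
) -> pd.DataFrame:
    """Decompose every trait of a well matrix; tidy long-format output.

    ``metadata`` is donor-indexed (sex, age, disease, source_tissue); PCs
    donor-indexed ancestry components. In the colony context the mean
    neighbor count enters as a fixed covariate.
    """
    from cmqtl.profiles import trait_columns

    traits = traits or trait_columns(well_matrix)
    n_corr = n_traits_for_correction or len(traits)
    design = well_matrix.merge(
        metadata, left_on="donor_id", right_index=True, how="left", validate="many_to_one"
    )
    fixed = ["age"]
    if pcs is not None:
        design = design.merge(pcs.iloc[:, :4], left_on="donor_id", right_index=True, how="left")
        fixed += list(pcs.columns[:4])
    if context == "colony" and "neighbor_count" in design.columns:
        fixed.append("neighbor_count")
    random_factors = [
        f for f in DEFAULT_RANDOM if f in design.columns and design[f].nunique() > 1
    ]
    rows = []
    for trait in traits:
        d = fit_variance_components(
            design[trait], design, random_factors, fixed,
            trait=trait, compute_pvalues=compute_pvalues,
            n_traits_for_correction=n_corr,
        )
        for comp, frac in d.fractions.items():
            rows.append(
                {
                    "trait": trait,
                    "context": context,
                    "component": comp,
                    "fraction": frac,
                    "p": d.pvalues.get(comp, np.nan),
                    "p_bonferroni": d.pvalues_bonferroni.get(comp, np.nan),
                    "converged": d.converged,
                }
            )
    return pd.DataFrame(rows)
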