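"""Effect-size mixture modelling and discovery-power projection.

The distribution of true standardized per-test effect sizes is modelled as
a zero-mean Gaussian scale mixture with a pinned null spike: a z-score from
a study of N samples is marginally z ~ sum_k pi_k * Normal(0, N*tau2_k + 1),
where tau2_k is the per-sample true-effect variance of component k and the
+1 is the sampling variance of a standardized test statistic. Fitting is
maximum likelihood by EM on the concatenated summary statistics across all
traits. Projection to a larger sample size N' replaces the component
variances by N'*tau2_k + 1 and integrates the two-sided tail beyond the
significance threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class EffectSizeMixture:
    """Fitted scale mixture of the standardized true-effect distribution."""

    weights: np.ndarray  # pi_k, sums to 1
    tau2: np.ndarray  # per-sample true-effect variances; tau2[0] == 0 (null spike)
    n_fit: int  # sample size of the fitted study
    n_tests: int
    loglik: float = np.nan
    converged: bool = True
    n_iter: int = 0
    ll_trace: list | None = None  # per-iteration log-likelihood of the best restart

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.tau2 = np.asarray(self.tau2, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if (self.tau2 < 0).any():
            raise ValueError("component variances must be non-negative")
        if self.tau2[0] != 0.0:
            raise ValueError("component 0 is the pinned null spike (tau2=0)")

    @property
    def null_weight(self) -> float:
        return float(self.weights[0])

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["weights"] = self.weights.tolist()
        d["tau2"] = self.tau2.tolist()
        d.pop("ll_trace", None)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "EffectSizeMixture":
        return cls(**json.loads(Path(path).read_text()))


_LOG_2PI = np.log(2.0 * np.pi)


def _component_densities(z2: np.ndarray, weights: np.ndarray, var: np.ndarray) -> np.ndarray:
    """weights_k * N(z | 0, var_k), computed from precomputed z^2."""
    return weights * np.exp(-0.5 * (z2[:, None] / var + np.log(var) + _LOG_2PI))


def _loglik(z: np.ndarray, weights: np.ndarray, var: np.ndarray) -> float:
    dens = _component_densities(np.asarray(z) ** 2, weights, np.asarray(var, dtype=float))
    return float(np.log(dens.sum(axis=1)).sum())


def _em(
    z2: np.ndarray,
    weights: np.ndarray,
    var: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, bool, int, list[float]]:
    """EM iterations on squared z-scores; component 0 variance stays pinned."""
    prev = -np.inf
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dens = _component_densities(z2, weights, var)
        total = dens.sum(axis=1)
        ll = float(np.log(total).sum())
        trace.append(ll)
        resp = dens / total[:, None]
        weights = resp.mean(axis=0)
        weights = weights / weights.sum()
        m2 = (resp * z2[:, None]).sum(axis=0) / np.maximum(resp.sum(axis=0), 1e-300)
        var = var.copy()
        var[1:] = np.maximum(m2[1:], 1.0)  # marginal variance can't drop below noise
        if it > 1 and ll - prev < tol:
            converged = True
            prev = ll
            break
        prev = ll
    return weights, var, prev, converged, it, trace


def fit_effect_mixture(
    z_scores: np.ndarray | pd.Series,
    n_fit: int,
    k: int = 4,
    seed: int = 0,
    n_restarts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> EffectSizeMixture:
    """ML fit of the z-score scale mixture by EM with seeded restarts.

    Component 0 is pinned at tau2=0 (pure sampling noise); the other k-1
    component variances are free. Convergence: log-likelihood change below
    ``tol``; the best of ``n_restarts`` random initializations is returned,
    flagged non-converged if no restart reached ``tol``.
    """
    z = np.asarray(z_scores, dtype=float).ravel()
    if not np.isfinite(z).all():
        raise ValueError("z-scores must be finite")
    if k < 2:
        raise ValueError("need k >= 2 (null spike plus at least one component)")
    rng = np.random.default_rng(seed)
    z2 = z**2

    def init(restart: int) -> tuple[np.ndarray, np.ndarray]:
        weights = np.full(k, 1.0 / k)
        # free variances initialized from spread quantiles of z^2
        qs = np.quantile(z2, np.linspace(0.5, 0.999, k - 1))
        jitter = rng.uniform(0.5, 2.0, size=k - 1) if restart else np.ones(k - 1)
        var = np.empty(k)
        var[0] = 1.0
        var[1:] = np.maximum(1.0 + (qs - 1.0) * jitter, 1.0 + 1e-6)
        return weights, var

    # pick the best initialization by a short EM on a subsample, then run
    # the full-tolerance EM once from the winner — restarts stay cheap on
    # large concatenated summary-statistic sets
    if len(z2) > 30_000 and n_restarts > 1:
        sub = rng.choice(z2, size=20_000, replace=False)
        best_init = None
        for restart in range(n_restarts):
            w0, v0 = init(restart)
            w1, v1, ll1, *_ = _em(sub, w0, v0, tol=1e-6, max_iter=300)
            if best_init is None or ll1 > best_init[0]:
                best_init = (ll1, w1, v1)
        starts = [(best_init[1], best_init[2])]
    else:
        starts = [init(r) for r in range(n_restarts)]

    best = None
    for w0, v0 in starts:
        weights, var, ll, converged, it, trace = _em(z2, w0, v0, tol=tol, max_iter=max_iter)
        if best is None or ll > best[0]:
            best = (ll, weights, var, converged, it, trace)

    ll, weights, var, converged, it, trace = best
    # Components whose marginal variance is within sampling noise of 1 are
    # indistinguishable from the spike (the weight split between them is not
    # identified); fold them into it. 3*sqrt(2/n) is 3 sd of a variance
    # estimate from n standard-normal draws.
    excess = var - 1.0
    null_like = excess <= max(1e-6, 3.0 * np.sqrt(2.0 / len(z)))
    null_like[0] = True
    merged_w = np.concatenate([[weights[null_like].sum()], weights[~null_like]])
    merged_var = np.concatenate([[1.0], var[~null_like]])
    tau2 = np.maximum(merged_var - 1.0, 0.0) / n_fit
    tau2[0] = 0.0
    if not converged:
        logger.warning("fit_effect_mixture: EM did not converge within %d iterations", max_iter)
    return EffectSizeMixture(
        weights=merged_w, tau2=tau2, n_fit=n_fit, n_tests=len(z),
        loglik=ll, converged=converged, n_iter=it, ll_trace=trace,
    )


def expected_significant_fraction(
    mix: EffectSizeMixture, n: float, p_star: float
) -> float:
    """P(|z| > z*) under the mixture at sample size ``n``.

    z* is the two-sided normal quantile of ``p_star``; the null spike
    contributes exactly ``p_star`` (the false-positive construction of the
    threshold).
    """
    if not 0.0 < p_star < 1.0:
        raise ValueError("p_star must be in (0,1)")
    z_star = stats.norm.isf(p_star / 2.0)
    scale = np.sqrt(n * mix.tau2 + 1.0)
    tails = 2.0 * stats.norm.sf(z_star / scale)
    return float(np.dot(mix.weights, tails))


def project_discoveries(
    mix: EffectSizeMixture,
    n_grid: list[int] | np.ndarray,
    p_star: float = 2.2e-8,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Expected significant-test fraction and count over a sample-size grid."""
    t = mix.n_tests if n_tests is None else n_tests
    rows = []
    for n in n_grid:
        frac = expected_significant_fraction(mix, float(n), p_star)
        rows.append({"N": int(n), "expected_fraction": frac, "expected_count": t * frac})
    return pd.DataFrame(rows)


def prune_for_common_fit(genotypes) -> list[str]:
    """Approximate-linkage-equilibrium set for the common-variant arm.

    PLINK --indep-pairwise convention: windows of 50 variants shifting by
    5, pruning pairs with r² > 0.2.
    """
    from cmqtl.genotypes import ld_prune

    return ld_prune(genotypes, mode="count", r2_threshold=0.2, window=50, step=5)
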