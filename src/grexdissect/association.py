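"""Permutation-calibrated likelihood-ratio association tests.

Each gene variable (observed expression, GReX or EReX) is tested against
binary case/control status with a logistic likelihood-ratio test: the null
model regresses status on a component-specific covariate set, the full model
adds the gene variable.  P-values come from Freedman-Lane permutations of the
gene variable's covariate-adjusted residuals, with adaptive escalation of the
permutation count when no permuted statistic reaches the observed one.

The Newton fit and the permutation loop are JIT-compiled (numba); per-gene
RNG substreams are derived from (seed, component, gene) so results do not
depend on evaluation order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import chi2

from .datatypes import CovariateTable, ExpressionBundle, Phenotype

logger = logging.getLogger(__name__)

__all__ = [
    "CovariatePolicy",
    "AssociationResult",
    "lrt_statistic",
    "permutation_p",
    "perm_p_from_counts",
    "run_association",
    "bh_fdr",
    "expression_pcs",
]

_LL_TOL = 1e-10
_MAX_ITER = 100


@njit(cache=True)
def _fit_logistic(X, y, beta_init, tol, max_iter, ridge_last):
    """Newton-Raphson logistic fit; returns (loglik, beta, converged).

    ``ridge_last`` > 0 adds an L2 penalty on the last coefficient only (used
    for flagged refits under perfect separation).
    """
    n, p = X.shape
    beta = beta_init.copy()
    eta = X @ beta
    ll_prev = 0.0
    for i in range(n):
        e = eta[i]
        if e > 0.0:
            ll_prev += y[i] * e - e - np.log1p(np.exp(-e))
        else:
            ll_prev += y[i] * e - np.log1p(np.exp(e))
    ll_prev -= 0.5 * ridge_last * beta[p - 1] * beta[p - 1]
    converged = False
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu) + 1e-12
        grad = X.T @ (y - mu)
        grad[p - 1] -= ridge_last * beta[p - 1]
        H = X.T @ (X * w.reshape(n, 1))
        for j in range(p):
            H[j, j] += 1e-10
        H[p - 1, p - 1] += ridge_last
        delta = np.linalg.solve(H, grad)
        step = 1.0
        ll_new = ll_prev
        beta_new = beta
        for _half in range(40):
            beta_new = beta + step * delta
            eta_new = X @ beta_new
            ll_new = 0.0
            for i in range(n):
                e = eta_new[i]
                if e > 0.0:
                    ll_new += y[i] * e - e - np.log1p(np.exp(-e))
                else:
                    ll_new += y[i] * e - np.log1p(np.exp(e))
            ll_new -= 0.5 * ridge_last * beta_new[p - 1] * beta_new[p - 1]
            if ll_new >= ll_prev - 1e-12:
                break
            step *= 0.5
        beta = beta_new
        eta = X @ beta
        if abs(ll_new - ll_prev) < tol * (1.0 + abs(ll_new)):
            ll_prev = ll_new
            converged = True
            break
        ll_prev = ll_new
    return ll_prev, beta, converged


@njit(cache=True)
def _perm_exceed(C, y, g_fitted, g_resid, beta0, ll_null, obs_stat, B, seed, tol, max_iter):
    """Count Freedman-Lane permutation statistics >= the observed statistic."""
    np.random.seed(seed)
    n, q = C.shape
    X = np.empty((n, q + 1))
    X[:, :q] = C
    exceed = 0
    thresh = obs_stat * (1.0 - 1e-12) - 1e-12
    for _b in range(B):
        perm = np.random.permutation(n)
        for i in range(n):
            X[i, q] = g_fitted[i] + g_resid[perm[i]]
        ll_full, _, _ = _fit_logistic(X, y, beta0, tol, max_iter, 0.0)
        stat = 2.0 * (ll_full - ll_null)
        if stat >= thresh:
            exceed += 1
    return exceed


def _design(covariates: Optional[np.ndarray], n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != n:
        covariates = covariates.T
    return np.column_stack([np.ones(n), covariates])


def _null_fit(C: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    ll, beta, conv = _fit_logistic(
        C, y, np.zeros(C.shape[1]), _LL_TOL, _MAX_ITER, 0.0
    )
    if not conv:
        raise RuntimeError("null logistic model failed to converge")
    return ll, beta


def lrt_statistic(
    status: np.ndarray,
    gene_variable: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> tuple[float, bool]:
    """Logistic likelihood-ratio statistic 2(l_full - l_null), floored at 0.

    Returns ``(stat, flagged)``; ``flagged`` marks a quasi-separated fit that
    was re-run with a small ridge penalty (1e-6) on the gene coefficient.
    """
    y = np.asarray(status, dtype=float)
    g = np.asarray(gene_variable, dtype=float)
    n = len(y)
    C = _design(covariates, n)
    if n < C.shape[1] + 1 + 5:
        raise ValueError("too few samples for the number of model parameters")
    if len(set(np.unique(y))) < 2:
        raise ValueError("status must contain both classes")
    ll_null, beta_null = _null_fit(C, y)
    X = np.column_stack([C, g])
    beta0 = np.append(beta_null, 0.0)
    ll_full, beta_full, conv = _fit_logistic(X, y, beta0, _LL_TOL, _MAX_ITER, 0.0)
    flagged = (not conv) or abs(beta_full[-1]) * (g.std() + 1e-300) > 30
    if flagged:
        ll_full, beta_full, conv = _fit_logistic(X, y, beta0, _LL_TOL, _MAX_ITER, 1e-6)
        if not conv:
            raise RuntimeError("full logistic model failed to converge")
    return max(0.0, 2.0 * (ll_full - ll_null)), flagged


@dataclass
class AssociationResult:
    gene_id: str
    component: str
    lrt_stat: float
    perm_p: float
    b_exceed: int
    B: int
    q_value: float = np.nan
    analytic_p: float = np.nan
    escalated: bool = False
    p_is_upper_bound: bool = False
    flagged: bool = False


def _freedman_lane_parts(g: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    coef, *_ = np.linalg.lstsq(C, g, rcond=None)
    fitted = C @ coef
    return fitted, g - fitted


def _substream_seed(seed: int, component: str, gene_id: str, k: int = 0) -> int:
    ss = np.random.SeedSequence(
        [int(seed), zlib.crc32(component.encode()), zlib.crc32(gene_id.encode()), k]
    )
    return int(ss.generate_state(1)[0] % (2 ** 31))


def perm_p_from_counts(b_exceed: int, B: int) -> float:
    """Permutation p-value b/B; with zero exceedances, the upper bound 1/B."""
    if B <= 0 or b_exceed < 0 or b_exceed > B:
        raise ValueError("need 0 <= b_exceed <= B with B > 0")
    return b_exceed / B if b_exceed > 0 else 1.0 / B


def permutation_p(
    status: np.ndarray,
    gene_variable: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    B_initial: int = 8000,
    B_max: int = 1_000_000,
    seed: int = 0,
    gene_id: str = "",
    component: str = "observed",
) -> AssociationResult:
    """Freedman-Lane permutation p-value for the logistic LRT.

    The gene variable is regressed on the covariates; its residuals are
    permuted and added back to the fitted values, and the LRT is recomputed
    per permutation.  If no permuted statistic reaches the observed one after
    ``B_initial`` permutations, the count escalates to ``B_max`` total; a
    still-empty exceedance set yields ``perm_p = 1/B_max`` flagged as an
    upper bound.
    """
    y = np.asarray(status, dtype=float)
    g = np.asarray(gene_variable, dtype=float)
    n = len(y)
    C = _design(covariates, n)
    obs_stat, flagged = lrt_statistic(status, gene_variable, covariates)
    ll_null, beta_null = _null_fit(C, y)
    beta0 = np.append(beta_null, 0.0)

    if g.std() == 0:
        # constant gene variable: statistic is 0 under every permutation
        return AssociationResult(
            gene_id, component, 0.0, 1.0, B_initial, B_initial,
            analytic_p=1.0, flagged=False,
        )

    fitted, resid = _freedman_lane_parts(g, C)
    s0 = _substream_seed(seed, component, gene_id, 0)
    b = int(_perm_exceed(C, y, fitted, resid, beta0, ll_null, obs_stat,
                         B_initial, s0, _LL_TOL, _MAX_ITER))
    B = B_initial
    escalated = False
    if b == 0 and B_max > B_initial:
        escalated = True
        s1 = _substream_seed(seed, component, gene_id, 1)
        b += int(_perm_exceed(C, y, fitted, resid, beta0, ll_null, obs_stat,
                              B_max - B_initial, s1, _LL_TOL, _MAX_ITER))
        B = B_max
    upper = b == 0
    perm_p = perm_p_from_counts(b, B)
    return AssociationResult(
        gene_id, component, obs_stat, perm_p, b, B,
        analytic_p=float(chi2.sf(obs_stat, 1)),
        escalated=escalated, p_is_upper_bound=upper, flagged=flagged,
    )


@dataclass
class CovariatePolicy:
    """Which covariate tags enter the null model for each component.

    Expression PCs are confounders for observed expression and EReX but not
    for GReX (GReX derives from genotype only); genotype PCs enter all three
    to guard against population stratification.
    """

    tags_by_component: dict[str, tuple[str, ...]] = field(default_factory=lambda: {
        "observed": ("clinical", "expression_pc", "genotype_pc"),
        "grex": ("clinical", "genotype_pc"),
        "erex": ("clinical", "expression_pc", "genotype_pc"),
    })

    def __post_init__(self) -> None:
        for comp in ("observed", "grex", "erex"):
            tags = self.tags_by_component.get(comp)
            if tags is None:
                raise ValueError(f"policy missing component {comp!r}")
            if comp in ("observed", "erex") and "expression_pc" not in tags:
                raise ValueError(f"{comp} policy must include expression_pc")
            if comp == "grex" and "expression_pc" in tags:
                raise ValueError("grex policy must exclude expression_pc")
            if "genotype_pc" not in tags:
                raise ValueError(f"{comp} policy must include genotype_pc")

    def tags(self, component: str) -> tuple[str, ...]:
        return self.tags_by_component[component]


def expression_pcs(observed: np.ndarray, n_pcs: int = 10) -> np.ndarray:
    """Top principal-component scores of the centered observed expression."""
    X = np.asarray(observed, dtype=float)
    Xc = X - X.mean(axis=0)
    k = min(n_pcs, Xc.shape[0] - 1, Xc.shape[1])
    if k <= 0:
        return np.empty((X.shape[0], 0))
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    return U[:, :k] * s[:k]


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def run_association(
    bundle: ExpressionBundle,
    phenotype: Phenotype,
    covariates: CovariateTable,
    policy: Optional[CovariatePolicy] = None,
    B_initial: int = 8000,
    B_max: int = 1_000_000,
    seed: int = 0,
    components: Sequence[str] = ("observed", "grex", "erex"),
    n_expression_pcs: int = 10,
) -> pd.DataFrame:
    """LRT + permutation association for every gene and requested component.

    Expression PCs are computed from the observed matrix and appended to the
    covariate table when absent; the policy decides which tags enter each
    component's null model.  Returns a long-form table with one row per
    (gene, component) including BH q-values computed within component.
    """
    if policy is None:
        policy = CovariatePolicy()
    if bundle.sample_ids != phenotype.sample_ids or bundle.sample_ids != covariates.sample_ids:
        raise ValueError("bundle, phenotype and covariates must be sample-aligned")
    has_expr_pcs = any(t == "expression_pc" for t in covariates.tags.values())
    if not has_expr_pcs and n_expression_pcs > 0:
        pcs = expression_pcs(bundle.observed, n_expression_pcs)
        names = [f"expr_pc{j + 1}" for j in range(pcs.shape[1])]
        covariates = covariates.with_columns(names, pcs, "expression_pc")

    y = phenotype.status
    rows: list[AssociationResult] = []
    for comp in components:
        matrix = bundle.component(comp)
        cov = covariates.matrix(policy.tags(comp))
        for gi, gene in enumerate(bundle.gene_ids):
            res = permutation_p(
                y, matrix[:, gi], cov, B_initial=B_initial, B_max=B_max,
                seed=seed, gene_id=gene, component=comp,
            )
            rows.append(res)
        n_esc = sum(r.escalated for r in rows if r.component == comp)
        if n_esc:
            logger.info("component %s: %d genes escalated to B=%d", comp, n_esc, B_max)

    table = pd.DataFrame([r.__dict__ for r in rows])
    table["q_value"] = np.nan
    for comp in components:
        mask = table["component"] == comp
        table.loc[mask, "q_value"] = bh_fdr(table.loc[mask, "perm_p"].to_numpy())
    return table
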