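"""Top-N hypergeometric enrichment, threshold counting and pi1 estimation.

Given per-gene association p-values, genes are ranked and the over-
representation of a pathway among the N top-ranked genes is scored with the
upper tail of the hypergeometric distribution, relative to the universe of
genes with all components available.  The proportion of true-alternative
tests (pi1) in a p-value collection is estimated against a uniform null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .datatypes import GeneSet

__all__ = [
    "hypergeom_upper_tail",
    "rank_genes",
    "top_n_enrichment",
    "estimate_pi1",
    "threshold_counts",
    "EnrichmentResult",
    "Pi1Estimate",
]


def hypergeom_upper_tail(universe_size: int, K: int, n_draw: int, x_observed: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(universe_size, K, n_draw).

    Summed in log space over the upper support for numerical safety at
    extreme tails.
    """
    if not (0 <= K <= universe_size and 0 <= n_draw <= universe_size):
        raise ValueError("inconsistent hypergeometric counts")
    if not (0 <= x_observed <= min(K, n_draw)):
        raise ValueError(
            f"x={x_observed} outside [0, min(K={K}, n={n_draw})]"
        )
    if x_observed <= max(0, n_draw + K - universe_size):
        return 1.0  # x at or below the smallest possible overlap
    support = np.arange(x_observed, min(K, n_draw) + 1)
    logp = hypergeom.logpmf(support, universe_size, K, n_draw)
    # floor at the smallest subnormal so the value stays in (0, 1]
    return float(min(1.0, max(np.exp(logsumexp(logp)), 5e-324)))


@dataclass
class EnrichmentResult:
    set_name: str
    N_top: int
    universe_size: int
    pathway_in_universe: int
    overlap: int
    p_value: float


def rank_genes(
    p_values: dict[str, float],
    lrt_stats: dict[str, float] | None = None,
) -> list[str]:
    """Total order on genes: ascending p, ties broken by larger LRT statistic,
    then lexicographic gene id.  Tied p-values are common at the b/B
    resolution of permutation p-values, so a deterministic tie-break matters.
    """
    def key(g: str):
        stat = 0.0 if lrt_stats is None else lrt_stats.get(g, 0.0)
        return (p_values[g], -stat, g)

    return sorted(p_values, key=key)


def top_n_enrichment(
    ranked_genes: Sequence[str],
    gene_set: GeneSet | Iterable[str],
    universe: Iterable[str],
    n_values: Sequence[int] = (30, 60, 100, 150, 200, 300),
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a gene set among top-N genes.

    For each N: x = |top-N ∩ set ∩ universe|, K = |set ∩ universe|; N larger
    than the ranked list is truncated with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    universe = set(universe)
    if not set(ranked_genes) <= universe:
        raise ValueError("ranked gene list must be a subset of the universe")
    members = gene_set.members if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    name = gene_set.name if isinstance(gene_set, GeneSet) else "gene_set"
    K = len(members & universe)
    M = len(universe)
    results = []
    for N in n_values:
        n_eff = min(N, len(ranked_genes))
        if n_eff < N:
            logger.warning("top-N=%d truncated to ranked list length %d", N, n_eff)
        top = set(ranked_genes[:n_eff])
        x = len(top & members & universe)
        p = hypergeom_upper_tail(M, K, n_eff, x)
        results.append(EnrichmentResult(name, n_eff, M, K, x, p))
    return results


@dataclass
class Pi1Estimate:
    pi1: float
    lam: float
    m: int


def estimate_pi1(p_values: Sequence[float], lam: float = 0.5) -> Pi1Estimate:
    """Proportion of true-alternative tests under a uniform null.

    pi0 is estimated from the density of p-values above the threshold
    ``lam`` (pi0 = #{p > lam} / ((1 - lam) m)); pi1 = 1 - pi0, clamped to
    [0, 1].  A single fixed lambda keeps the estimator deterministic.
    """
    if not (0 < lam < 1):
        raise ValueError("lambda must lie in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size < 10:
        import warnings

        warnings.warn("pi1 estimate from fewer than 10 p-values is unstable")
    pi0 = np.sum(p > lam) / ((1.0 - lam) * p.size)
    pi1 = float(np.clip(1.0 - pi0, 0.0, 1.0))
    return Pi1Estimate(pi1, lam, int(p.size))


def threshold_counts(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.Series, pd.DataFrame, dict[str, list[str]]]:
    """Per-component counts of genes with perm_p strictly below alpha.

    ``table`` is long-form with columns gene_id / component / perm_p.
    Returns (counts per component, pairwise overlap counts, significant gene
    lists per component).
    """
    if table.empty:
        return pd.Series(dtype=int), pd.DataFrame(), {}
    components = list(dict.fromkeys(table["component"]))
    sig: dict[str, list[str]] = {}
    for comp in components:
        sub = table[table["component"] == comp]
        sig[comp] = sorted(sub.loc[sub["perm_p"] < alpha, "gene_id"])
    counts = pd.Series({c: len(sig[c]) for c in components}, dtype=int)
    overlap = pd.DataFrame(
        [
            [len(set(sig[a]) & set(sig[b])) for b in components]
            for a in components
        ],
        index=components,
        columns=components,
    )
    return counts, overlap, sig
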