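"""Synthetic cohorts with a known genetic/environmental expression architecture.

Each gene's observed expression is built as an exact sum

    observed = true_grex + true_env + noise

where ``true_grex`` is a sparse linear function of simulated SNP dosages
scaled to a target cis-heritability, ``true_env`` is an environmental
component that may shift with case/control status, and ``noise`` is residual
measurement error.  The generator returns the true weights and components so
every downstream stage (prediction, residualization, association, enrichment)
can be checked against ground truth.

All randomness flows from a single :class:`numpy.random.Generator` in a fixed
draw order: genotypes, causal-variant choice, weights, phenotype, environment,
noise, clinical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CovariateTable,
    ExpressionBundle,
    GenotypeMatrix,
    Phenotype,
    WeightMatrix,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_weights",
    "simulate_cohort",
    "default_gene_ids",
]


def default_gene_ids(n_genes: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n_genes)]


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic case/control expression cohort.

    Defaults mirror a blood-cohort design of 922 individuals split into 463
    cases and 459 controls, with a per-gene cis-heritability of 0.15 — inside
    the 0.10-0.26 range twin studies report for blood expression.
    """

    n_samples: int = 922
    n_cases: int = 463
    n_genes: int = 200
    snps_per_gene: int = 30
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_per_gene: float | Sequence[float] = 0.15
    n_causal_weights_per_gene: int = 8
    env_effect_genes: Sequence[str] = field(default_factory=list)
    env_effect_size: float = 0.0
    grex_effect_genes: Sequence[str] = field(default_factory=list)
    grex_effect_size: float = 0.0
    n_covariates: int = 5
    n_genotype_pcs: int = 5
    env_share: float = 0.7  # fraction of non-genetic variance that is environmental
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_cases < self.n_samples):
            raise ValueError("need 0 < n_cases < n_samples")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        h2 = self.h2_values()
        if np.any(h2 < 0) or np.any(h2 >= 1):
            raise ValueError("h2 values must lie in [0, 1)")
        if not (0 <= self.env_share <= 1):
            raise ValueError("env_share must lie in [0, 1]")
        genes = set(self.gene_ids())
        for name in ("env_effect_genes", "grex_effect_genes"):
            extra = set(getattr(self, name)) - genes
            if extra:
                raise ValueError(f"{name} not in simulated genes: {sorted(extra)[:5]}")
        if self.n_causal_weights_per_gene > self.snps_per_gene:
            raise ValueError("n_causal_weights_per_gene exceeds snps_per_gene")

    def gene_ids(self) -> list[str]:
        return default_gene_ids(self.n_genes)

    def h2_values(self) -> np.ndarray:
        h2 = np.asarray(self.h2_per_gene, dtype=float)
        if h2.ndim == 0:
            h2 = np.full(self.n_genes, float(h2))
        if h2.shape != (self.n_genes,):
            raise ValueError("h2_per_gene must be scalar or length n_genes")
        return h2


@dataclass
class GroundTruth:
    """True components underlying a simulated cohort (samples x genes)."""

    gene_ids: list[str]
    true_grex: np.ndarray
    true_env: np.ndarray
    noise: np.ndarray
    true_h2: np.ndarray
    labels: list[str]  # per gene: env_driven / grex_driven / both / null


def simulate_genotypes(
    n_samples: int,
    n_variants: int,
    maf_range: tuple[float, float],
    seed: int | np.random.Generator = 0,
    variant_ids: Optional[Sequence[str]] = None,
    sample_ids: Optional[Sequence[str]] = None,
) -> GenotypeMatrix:
    """Independent biallelic variants with Binomial(2, f) dosages.

    Each variant's ALT frequency f is drawn uniformly from ``maf_range``;
    genotypes are Hardy-Weinberg-consistent by construction.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=n_variants)
    dosages = rng.binomial(2, freqs[None, :], size=(n_samples, n_variants)).astype(float)
    if variant_ids is None:
        variant_ids = [f"v{j + 1:06d}" for j in range(n_variants)]
    if sample_ids is None:
        sample_ids = [f"s{i + 1:04d}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, n_variants + 1) * 1000,
            "ref": "A",
            "alt": "G",
        },
        index=list(variant_ids),
    )
    return GenotypeMatrix(list(sample_ids), list(variant_ids), dosages, meta)


def simulate_weights(
    genes: Sequence[str],
    variants_by_gene: dict[str, Sequence[str]],
    n_causal: int,
    effect_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
    tissue_label: str = "synthetic",
) -> WeightMatrix:
    """Sparse weights: per gene, ``n_causal`` variants get N(0, effect_sd^2) effects."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for gene in genes:
        cis = list(variants_by_gene[gene])
        if n_causal > len(cis):
            raise ValueError(f"n_causal={n_causal} exceeds {len(cis)} cis variants for {gene}")
        if n_causal == 0:
            continue
        chosen = rng.choice(len(cis), size=n_causal, replace=False)
        w = rng.normal(0.0, effect_sd, size=n_causal)
        for k, j in enumerate(sorted(chosen)):
            rows.append((gene, cis[j], w[k], "G"))
    table = pd.DataFrame(rows, columns=["gene", "variant", "weight", "effect_allele"])
    return WeightMatrix(tissue_label, table)


def _draw_status(
    rng: np.random.Generator,
    liability: np.ndarray,
    n_cases: int,
    n_controls: int,
) -> np.ndarray:
    """Logistic draws on the liability, then subsampling to exact counts.

    Returns the indices of the selected samples and their status; the input
    may be a larger pool than n_cases + n_controls.
    """
    prob = 1.0 / (1.0 + np.exp(-liability))
    raw = rng.random(len(liability)) < prob
    case_idx = np.flatnonzero(raw)
    ctrl_idx = np.flatnonzero(~raw)
    if len(case_idx) < n_cases or len(ctrl_idx) < n_controls:
        raise ValueError(
            f"cannot form {n_cases} cases / {n_controls} controls from pool of "
            f"{len(liability)} ({len(case_idx)} raw cases)"
        )
    keep_cases = rng.choice(case_idx, size=n_cases, replace=False)
    keep_ctrls = rng.choice(ctrl_idx, size=n_controls, replace=False)
    keep = np.sort(np.concatenate([keep_cases, keep_ctrls]))
    status = np.zeros(len(liability), dtype=int)
    status[keep_cases] = 1
    return keep, status[keep]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, ExpressionBundle, CovariateTable, Phenotype, WeightMatrix, GroundTruth]:
    """Generate a full cohort with known architecture.

    Per gene g the genetic value is ``dosages @ w_g`` with weights rescaled so
    the realized variance ratio Var(genetic)/Var(total) equals the configured
    h2 (total variance 1); the returned :class:`WeightMatrix` stores the
    rescaled weights, so predicting with them reproduces ``true_grex``
    exactly.  Environmental values are N(0, sigma_env^2) plus
    ``env_effect_size * sigma_env * status`` for the environment-linked genes.
    When genetic effect genes are configured, status comes from a logistic
    model on the summed standardized genetic values (log-odds slope
    ``grex_effect_size``) in an oversampled pool, subsampled to the exact
    case/control counts.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    h2 = config.h2_values()
    n_controls = config.n_samples - config.n_cases

    grex_linked = config.grex_effect_genes
    pool_n = config.n_samples if not grex_linked else int(np.ceil(config.n_samples * 2.5))

    n_variants = config.n_genes * config.snps_per_gene
    geno = simulate_genotypes(pool_n, n_variants, config.maf_range, rng)
    variants_by_gene = {
        g: geno.variant_ids[i * config.snps_per_gene:(i + 1) * config.snps_per_gene]
        for i, g in enumerate(genes)
    }
    raw_weights = simulate_weights(
        genes, variants_by_gene, config.n_causal_weights_per_gene, 1.0, rng
    )

    # genetic values, rescaled to hit the target variance ratio exactly
    vidx = {v: j for j, v in enumerate(geno.variant_ids)}
    true_grex = np.zeros((pool_n, config.n_genes))
    rows = []
    for gi, g in enumerate(genes):
        entries = raw_weights.entries_for_gene(g)
        if len(entries) == 0 or h2[gi] == 0:
            if len(entries) and h2[gi] == 0:
                for _, r in entries.iterrows():
                    rows.append((g, r["variant"], 0.0, "G"))
            continue
        cols = [vidx[v] for v in entries["variant"]]
        w = entries["weight"].to_numpy(float)
        raw = geno.dosages[:, cols] @ w
        v = raw.var()
        scale = 0.0 if v == 0 else np.sqrt(h2[gi] / v)
        true_grex[:, gi] = raw * scale
        for vid, wk in zip(entries["variant"], w * scale):
            rows.append((g, vid, wk, "G"))
    weights = WeightMatrix(
        "synthetic", pd.DataFrame(rows, columns=["gene", "variant", "weight", "effect_allele"])
    )

    # phenotype
    if grex_linked:
        gidx = [genes.index(g) for g in grex_linked]
        z = true_grex[:, gidx]
        sd = z.std(axis=0)
        sd[sd == 0] = 1.0
        z = (z - z.mean(axis=0)) / sd
        liability = config.grex_effect_size * z.sum(axis=1) / np.sqrt(len(gidx))
        keep, status = _draw_status(rng, liability, config.n_cases, n_controls)
    else:
        # no genetic liability: assign exact case/control counts at random
        keep = np.arange(pool_n)
        status = np.zeros(pool_n, dtype=int)
        status[rng.choice(pool_n, size=config.n_cases, replace=False)] = 1

    geno = geno.subset_samples([geno.sample_ids[i] for i in keep])
    true_grex = true_grex[keep, :]
    n = config.n_samples

    # environmental component and noise
    sigma_env = np.sqrt(config.env_share * (1.0 - h2))
    sigma_noise = np.sqrt((1.0 - config.env_share) * (1.0 - h2))
    env_linked = set(config.env_effect_genes)
    true_env = rng.normal(0.0, 1.0, size=(n, config.n_genes)) * sigma_env[None, :]
    for gi, g in enumerate(genes):
        if g in env_linked:
            true_env[:, gi] += config.env_effect_size * sigma_env[gi] * status
    noise = rng.normal(0.0, 1.0, size=(n, config.n_genes)) * sigma_noise[None, :]

    observed = true_grex + true_env + noise

    # covariates: clinical noise columns + genotype PCs
    cov_values = rng.normal(size=(n, config.n_covariates))
    cov_names = [f"cov{j + 1}" for j in range(config.n_covariates)]
    tags = {c: "clinical" for c in cov_names}
    n_pcs = min(config.n_genotype_pcs, n - 1, geno.n_variants)
    if n_pcs > 0:
        from sklearn.decomposition import PCA

        pca = PCA(n_components=n_pcs, svd_solver="randomized",
                  random_state=int(rng.integers(2 ** 31)))
        pcs = pca.fit_transform(geno.dosages - geno.dosages.mean(axis=0))
        pc_names = [f"geno_pc{j + 1}" for j in range(n_pcs)]
        cov_values = np.column_stack([cov_values, pcs])
        cov_names += pc_names
        tags.update({c: "genotype_pc" for c in pc_names})
    covariates = CovariateTable(
        list(geno.sample_ids),
        pd.DataFrame(cov_values, index=geno.sample_ids, columns=cov_names),
        tags,
    )

    labels = []
    for g in genes:
        e, r = g in env_linked and config.env_effect_size != 0, g in set(grex_linked) and config.grex_effect_size != 0
        labels.append("both" if (e and r) else "env_driven" if e else "grex_driven" if r else "null")

    bundle = ExpressionBundle(list(geno.sample_ids), genes, observed)
    phenotype = Phenotype(list(geno.sample_ids), status)
    truth = GroundTruth(genes, true_grex, true_env, noise, h2.copy(), labels)
    return geno, bundle, covariates, phenotype, weights, truth


def write_ground_truth(truth: GroundTruth, sample_ids: Sequence[str], path) -> None:
    """Persist true components in long TSV form plus per-gene metadata columns."""
    per_gene = pd.DataFrame(
        {"gene": truth.gene_ids, "true_h2": truth.true_h2, "label": truth.labels}
    )
    per_gene.to_csv(path, sep="\t", index=False, float_format="%.12g")
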