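"""Core domain containers for the expression-dissection pipeline.

The pipeline operates on a case/control cohort with three parallel views of
each gene's expression: the observed value, the genetically regulated
component (GReX) imputed from cis-SNP dosages through a sparse weight model,
and the environmentally regulated component (EReX) defined as the residual of
observed expression on GReX.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "WeightMatrix",
    "ExpressionBundle",
    "CovariateTable",
    "Phenotype",
    "GeneSet",
    "COVARIATE_TAGS",
]

COVARIATE_TAGS = ("clinical", "expression_pc", "genotype_pc")


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for i in ids:
            if i in seen:
                dup = i
                break
            seen.add(i)
        raise ValueError(f"duplicated {what}: {dup!r}")


@dataclass
class GenotypeMatrix:
    """Per-individual ALT-allele dosages for biallelic variants.

    ``dosages`` is ``n_samples x n_variants`` with values in [0, 2] (missing
    genotypes are mean-imputed at read time).  ``variant_meta`` is indexed by
    variant id with columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt``.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray
    variant_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.variant_ids, "variant id")
        if self.dosages.size and (
            np.nanmin(self.dosages) < -1e-9 or np.nanmax(self.dosages) > 2 + 1e-9
        ):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return GenotypeMatrix(
            list(sample_ids), list(self.variant_ids), self.dosages[rows, :],
            self.variant_meta,
        )

    def subset_variants(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = {v: i for i, v in enumerate(self.variant_ids)}
        cols = [idx[v] for v in variant_ids]
        return GenotypeMatrix(
            list(self.sample_ids), list(variant_ids), self.dosages[:, cols],
            self.variant_meta.loc[list(variant_ids)],
        )


@dataclass
class WeightMatrix:
    """Sparse gene x variant effect weights defining a cis prediction model.

    ``table`` holds one row per (gene, variant) pair with columns ``gene``,
    ``variant``, ``weight``, ``effect_allele``.  One instance corresponds to
    one tissue's prediction model.
    """

    tissue_label: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "variant", "weight", "effect_allele"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"weight table missing columns: {sorted(missing)}")
        if self.table.duplicated(["gene", "variant"]).any():
            dup = self.table[self.table.duplicated(["gene", "variant"])].iloc[0]
            raise ValueError(
                f"duplicate weight entry for gene={dup['gene']!r} variant={dup['variant']!r}"
            )
        if len(self.table) and not np.isfinite(self.table["weight"].to_numpy(float)).all():
            raise ValueError("non-finite weight encountered")

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.table["gene"]))

    def entries_for_gene(self, gene: str) -> pd.DataFrame:
        sub = self.table[self.table["gene"] == gene]
        return sub.sort_values("variant", kind="mergesort")

    def n_entries(self) -> int:
        return len(self.table)


@dataclass
class ExpressionBundle:
    """Observed, GReX and EReX expression matrices over shared samples/genes.

    All matrices are ``n_samples x n_genes``; ``grex`` and ``erex`` may be
    ``None`` before the corresponding pipeline stage has run.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    observed: np.ndarray
    grex: Optional[np.ndarray] = None
    erex: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        shape = (len(self.sample_ids), len(self.gene_ids))
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.gene_ids, "gene id")
        for name in ("observed", "grex", "erex"):
            m = getattr(self, name)
            if m is None:
                continue
            m = np.asarray(m, dtype=float)
            setattr(self, name, m)
            if m.shape != shape:
                raise ValueError(f"{name} matrix shape {m.shape} != {shape}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def component(self, name: str) -> np.ndarray:
        if name not in ("observed", "grex", "erex"):
            raise KeyError(name)
        m = getattr(self, name)
        if m is None:
            raise ValueError(f"component {name!r} not computed yet")
        return m

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionBundle":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return ExpressionBundle(
            list(sample_ids),
            list(self.gene_ids),
            self.observed[rows, :],
            None if self.grex is None else self.grex[rows, :],
            None if self.erex is None else self.erex[rows, :],
        )


@dataclass
class CovariateTable:
    """Covariates with per-column tags (clinical / expression_pc / genotype_pc)."""

    sample_ids: list[str]
    values: pd.DataFrame  # index = sample_ids, one column per covariate
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.sample_ids, "sample id")
        if list(self.values.index) != list(self.sample_ids):
            self.values = self.values.loc[list(self.sample_ids)]
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()][0]
            raise ValueError(f"missing values in covariate {bad!r}")
        for name in self.values.columns:
            tag = self.tags.get(name, "clinical")
            if tag not in COVARIATE_TAGS:
                raise ValueError(f"unknown covariate tag {tag!r} for {name!r}")
            self.tags[name] = tag

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)

    def matrix(self, tags: Optional[Iterable[str]] = None) -> np.ndarray:
        """Covariate design matrix restricted to the given tags (no intercept)."""
        if tags is None:
            cols = self.names
        else:
            wanted = set(tags)
            cols = [c for c in self.names if self.tags[c] in wanted]
        return self.values[cols].to_numpy(float)

    def with_columns(
        self, names: Sequence[str], values: np.ndarray, tag: str
    ) -> "CovariateTable":
        values = np.asarray(values, dtype=float)
        df = self.values.copy()
        for j, name in enumerate(names):
            if name in df.columns:
                raise ValueError(f"covariate {name!r} already present")
            df[name] = values[:, j]
        tags = dict(self.tags)
        tags.update({n: tag for n in names})
        return CovariateTable(list(self.sample_ids), df, tags)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CovariateTable":
        return CovariateTable(
            list(sample_ids), self.values.loc[list(sample_ids)], dict(self.tags)
        )


@dataclass
class Phenotype:
    """Binary case/control status (1 = case, 0 = control)."""

    sample_ids: list[str]
    status: np.ndarray

    def __post_init__(self) -> None:
        _check_unique(self.sample_ids, "sample id")
        self.status = np.asarray(self.status, dtype=int)
        if self.status.shape != (len(self.sample_ids),):
            raise ValueError("status length does not match sample ids")
        if not set(np.unique(self.status)) <= {0, 1}:
            raise ValueError("status must be binary 0/1")
        if self.status.sum() == 0 or self.status.sum() == len(self.status):
            raise ValueError("both cases and controls must be present")

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int(len(self.status) - self.status.sum())

    def subset_samples(self, sample_ids: Sequence[str]) -> "Phenotype":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return Phenotype(list(sample_ids), self.status[rows])


@dataclass
class GeneSet:
    """Named set of gene identifiers (e.g. a signalling pathway)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValueError("gene set must be non-empty")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members
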