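"""Readers and writers for the on-disk formats the pipeline touches.

Supported formats: VCF (GT and/or DS fields, biallelic records), dosage TSV,
expression TSV (either orientation), weight TSV, covariate TSV, phenotype
TSV and plain-text gene-set files.  All TSVs are tab-delimited UTF-8 with a
header row; round-trip write -> read is the identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CovariateTable,
    GeneSet,
    GenotypeMatrix,
    ExpressionBundle,
    Phenotype,
    WeightMatrix,
)

logger = logging.getLogger(__name__)

_META_COLS = ["chrom", "pos", "ref", "alt"]


# ---------------------------------------------------------------------------
# genotypes

def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read genotypes from a VCF (.vcf/.vcf.gz, GT or DS) or a dosage TSV.

    GT calls map hom-ref/het/hom-alt to dosages 0/1/2; when a DS FORMAT field
    is present it is used verbatim.  Missing genotypes are imputed to the
    variant's mean dosage.  Multi-allelic records are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"genotype file not found: {path}")
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        return _read_vcf(path)
    return _read_dosage_tsv(path)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"no samples in VCF {path}")
    variant_ids: list[str] = []
    meta_rows = []
    columns = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = np.asarray(rec.gt_types)
            col = np.where(gt == 3, 2.0, gt.astype(float))
            col[gt == 2] = np.nan
        miss = ~np.isfinite(col)
        if miss.all():
            logger.warning("variant %s has no called genotypes; skipped", vid)
            continue
        if miss.any():
            col[miss] = col[~miss].mean()
        variant_ids.append(vid)
        meta_rows.append((rec.CHROM, int(rec.POS), rec.REF, rec.ALT[0]))
        columns.append(col)
    if n_multi:
        logger.warning("skipped %d multi-allelic records in %s", n_multi, path)
    if not variant_ids:
        raise ValueError(f"no biallelic variants retained from {path}")
    dosages = np.column_stack(columns)
    meta = pd.DataFrame(meta_rows, columns=_META_COLS, index=variant_ids)
    return GenotypeMatrix(samples, variant_ids, dosages, meta)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    expected = ["variant_id"] + _META_COLS
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"dosage TSV {path} missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in expected]
    if not sample_cols:
        raise ValueError(f"dosage TSV {path} has no sample columns")
    if df.empty:
        raise ValueError(f"dosage TSV {path} has no variants")
    variant_ids = df["variant_id"].tolist()
    meta = df[_META_COLS].copy()
    meta.index = variant_ids
    dosages = df[sample_cols].to_numpy(float).T  # samples x variants
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        miss = ~np.isfinite(col)
        if miss.any():
            col[miss] = col[~miss].mean()
    return GenotypeMatrix(sample_cols, variant_ids, dosages, meta)


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a dosage TSV (variants as rows, samples as columns)."""
    df = gm.variant_meta.loc[gm.variant_ids, _META_COLS].copy()
    df.insert(0, "variant_id", gm.variant_ids)
    for i, s in enumerate(gm.sample_ids):
        df[s] = gm.dosages[i, :]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# expression

def read_expression(
    path: str | Path, orientation: str = "genes_by_samples"
) -> tuple[np.ndarray, list[str], list[str]]:
    """Read an expression TSV into ``(matrix, sample_ids, gene_ids)``.

    The on-disk table may be genes x samples (``orientation="genes_by_samples"``,
    the common convention) or samples x genes; the returned matrix is always
    samples x genes.
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_filter=False)
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df.index[df[col].apply(lambda v: not _is_number(v))][0]
            raise ValueError(
                f"non-numeric cell at row {bad!r}, column {col!r} in {path}"
            ) from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicated id {dup!r} in {path}")
    if orientation == "genes_by_samples":
        gene_ids = [str(g) for g in df.index]
        sample_ids = [str(s) for s in df.columns]
        matrix = df.to_numpy(float).T
    else:
        sample_ids = [str(s) for s in df.index]
        gene_ids = [str(g) for g in df.columns]
        matrix = df.to_numpy(float)
    return matrix, sample_ids, gene_ids


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_expression(
    matrix: np.ndarray,
    sample_ids: Sequence[str],
    gene_ids: Sequence[str],
    path: str | Path,
    orientation: str = "genes_by_samples",
) -> None:
    """Write a samples x genes matrix to TSV in the requested orientation."""
    matrix = np.asarray(matrix, dtype=float)
    if orientation == "genes_by_samples":
        df = pd.DataFrame(matrix.T, index=list(gene_ids), columns=list(sample_ids))
        df.index.name = "gene_id"
    elif orientation == "samples_by_genes":
        df = pd.DataFrame(matrix, index=list(sample_ids), columns=list(gene_ids))
        df.index.name = "sample_id"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep="\t", float_format="%.12g")


# ---------------------------------------------------------------------------
# weights

def read_weights(path: str | Path, tissue_label: str = "blood") -> WeightMatrix:
    """Read a weight TSV with columns gene, variant, weight, effect_allele."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "variant": str})
    required = ["gene", "variant", "weight", "effect_allele"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"weight table {path} missing columns {missing}")
    df = df[required].copy()
    df["weight"] = df["weight"].astype(float)
    return WeightMatrix(tissue_label, df)


def write_weights(wm: WeightMatrix, path: str | Path) -> None:
    wm.table.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# covariates / phenotype / gene sets

def read_covariates(path: str | Path) -> CovariateTable:
    """Read a covariate TSV (first column sample_id).

    Column tags are inferred from the name: ``expr_pc*`` -> expression_pc,
    ``geno_pc*`` -> genotype_pc, anything else -> clinical.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    tags = {}
    for c in df.columns:
        lc = c.lower()
        if lc.startswith("expr_pc"):
            tags[c] = "expression_pc"
        elif lc.startswith("geno_pc"):
            tags[c] = "genotype_pc"
        else:
            tags[c] = "clinical"
    return CovariateTable(list(df.index), df, tags)


def write_covariates(cov: CovariateTable, path: str | Path) -> None:
    df = cov.values.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_phenotype(path: str | Path) -> Phenotype:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "status" not in df.columns:
        raise ValueError(f"phenotype TSV {path} needs a 'status' column")
    return Phenotype([str(s) for s in df.index], df["status"].to_numpy(int))


def write_phenotype(ph: Phenotype, path: str | Path) -> None:
    df = pd.DataFrame({"status": ph.status}, index=ph.sample_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_gene_set(path: str | Path, name: Optional[str] = None) -> GeneSet:
    """Read a plain-text gene set: one symbol per line, optional '#name' header."""
    lines = Path(path).read_text().splitlines()
    members = []
    set_name = name
    for i, line in enumerate(lines):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if i == 0 and set_name is None:
                set_name = line.lstrip("#").strip()
            continue
        members.append(line)
    if set_name is None:
        set_name = Path(path).stem
    return GeneSet(set_name, frozenset(members))


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {gs.name}\n")
        for g in sorted(gs.members):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# cohort alignment

@dataclass
class AlignedCohort:
    genotypes: GenotypeMatrix
    expression: ExpressionBundle
    covariates: CovariateTable
    phenotype: Phenotype

    @property
    def sample_ids(self) -> list[str]:
        return list(self.genotypes.sample_ids)


def align_cohort(
    genotypes: GenotypeMatrix,
    expression: ExpressionBundle,
    covariates: CovariateTable,
    phenotype: Phenotype,
) -> AlignedCohort:
    """Subset all four inputs to their shared samples, in genotype-file order.

    Idempotent; raises on an empty intersection; logs per-source drop counts.
    """
    sets = {
        "expression": set(expression.sample_ids),
        "covariates": set(covariates.sample_ids),
        "phenotype": set(phenotype.sample_ids),
    }
    shared = [s for s in genotypes.sample_ids if all(s in v for v in sets.values())]
    if not shared:
        raise ValueError("no shared samples across genotypes/expression/covariates/phenotype")
    n_drop_geno = genotypes.n_samples - len(shared)
    if n_drop_geno:
        logger.info("align_cohort: dropped %d genotype samples", n_drop_geno)
    for name, ids in sets.items():
        dropped = len(ids) - len(shared)
        if dropped:
            logger.info("align_cohort: dropped %d %s samples", dropped, name)
    return AlignedCohort(
        genotypes.subset_samples(shared),
        expression.subset_samples(shared),
        covariates.subset_samples(shared),
        phenotype.subset_samples(shared),
    )
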