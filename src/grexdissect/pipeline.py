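"""End-to-end orchestration: simulate/load -> QC -> GReX -> EReX -> association -> enrichment.

A run is configured by a single :class:`RunConfig` (deserializable from
YAML), executes the stages in flowchart order, writes every intermediate
table to the output directory and records a manifest with content hashes so
identical configs and seeds yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .association import CovariatePolicy, run_association
from .datatypes import ExpressionBundle, GeneSet
from .enrichment import estimate_pi1, rank_genes, threshold_counts, top_n_enrichment
from .erex import compute_erex
from .grex import predict_grex, qc_filter
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "report_tables"]


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    out_dir: str
    seed: int = 0
    simulation: Optional[SimulationConfig] = None
    genotypes_path: Optional[str] = None
    expression_path: Optional[str] = None
    weights_path: Optional[str] = None
    covariates_path: Optional[str] = None
    phenotype_path: Optional[str] = None
    gene_set_paths: list[str] = field(default_factory=list)
    maf_threshold: float = 0.05
    hwe_threshold: float = 0.05
    alpha: float = 0.05
    B_initial: int = 8000
    B_max: int = 1_000_000
    n_expression_pcs: int = 10
    top_n: list[int] = field(default_factory=lambda: [30, 60, 100, 150, 200, 300])

    def __post_init__(self) -> None:
        if self.simulation is None:
            needed = [self.genotypes_path, self.expression_path, self.weights_path,
                      self.covariates_path, self.phenotype_path]
            if any(p is None for p in needed):
                raise ValueError(
                    "either a simulation block or all five input paths are required"
                )
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.B_initial <= 0 or self.B_max < self.B_initial:
            raise ValueError("need 0 < B_initial <= B_max")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = dataclasses.asdict(self.simulation)
            d["simulation"]["maf_range"] = list(self.simulation.maf_range)
            for k in ("env_effect_genes", "grex_effect_genes"):
                d["simulation"][k] = list(d["simulation"][k])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class RunManifest:
    seed: int
    stages: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    wall_clock_s: float = 0.0
    complete: bool = False

    def record(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[path.name] = digest

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _write(df: pd.DataFrame, path: Path, manifest: RunManifest, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", **kwargs)
    manifest.record(path)


def report_tables(assoc: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Wide per-gene report: observed/EReX/GReX p-values, oDEG rank, flags.

    The rank orders genes by the observed-expression permutation p-value with
    ties broken by larger LRT statistic then gene id, so ranks are a
    permutation of 1..G.
    """
    wide = {}
    stats = {}
    for comp in ("observed", "grex", "erex"):
        sub = assoc[assoc["component"] == comp]
        wide[comp] = dict(zip(sub["gene_id"], sub["perm_p"]))
        if comp == "observed":
            stats = dict(zip(sub["gene_id"], sub["lrt_stat"]))
    genes = sorted(wide["observed"])
    ranked = rank_genes(wide["observed"], stats)
    rank_of = {g: i + 1 for i, g in enumerate(ranked)}
    df = pd.DataFrame(
        {
            "gene": genes,
            "odeg_p": [wide["observed"][g] for g in genes],
            "erex_p": [wide["erex"].get(g, np.nan) for g in genes],
            "grex_p": [wide["grex"].get(g, np.nan) for g in genes],
            "odeg_rank": [rank_of[g] for g in genes],
        }
    )
    for comp in ("odeg", "erex", "grex"):
        df[f"{comp}_significant"] = df[f"{comp}_p"] < alpha
    return df.sort_values("odeg_rank").reset_index(drop=True)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages and write tables + manifest to ``config.out_dir``."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed)
    config.to_yaml(out / "run_config.yaml")
    manifest.record(out / "run_config.yaml")

    stage = "inputs"
    try:
        if config.simulation is not None:
            geno, bundle, covariates, phenotype, weights, truth = simulate_cohort(
                config.simulation
            )
            per_gene = pd.DataFrame(
                {"gene": truth.gene_ids, "true_h2": truth.true_h2, "label": truth.labels}
            )
            _write(per_gene, out / "ground_truth.tsv", manifest)
        else:
            geno = gio.read_genotypes(config.genotypes_path)
            matrix, sample_ids, gene_ids = gio.read_expression(config.expression_path)
            bundle = ExpressionBundle(sample_ids, gene_ids, matrix)
            covariates = gio.read_covariates(config.covariates_path)
            phenotype = gio.read_phenotype(config.phenotype_path)
            weights = gio.read_weights(config.weights_path)
            aligned = gio.align_cohort(geno, bundle, covariates, phenotype)
            geno, bundle = aligned.genotypes, aligned.expression
            covariates, phenotype = aligned.covariates, aligned.phenotype
        manifest.stages.append(stage)

        stage = "qc"
        geno_qc, qc_table = qc_filter(geno, config.maf_threshold, config.hwe_threshold)
        _write(qc_table, out / "variant_qc.tsv", manifest)
        manifest.stages.append(stage)

        stage = "grex"
        grex, kept_genes, coverage = predict_grex(geno_qc, weights)
        _write(coverage, out / "grex_coverage.tsv", manifest)
        shared = [g for g in bundle.gene_ids if g in set(kept_genes)]
        if not shared:
            raise RuntimeError("no genes with both observed expression and GReX")
        gidx_obs = [bundle.gene_ids.index(g) for g in shared]
        gidx_grex = [kept_genes.index(g) for g in shared]
        bundle = ExpressionBundle(
            bundle.sample_ids, shared, bundle.observed[:, gidx_obs], grex[:, gidx_grex]
        )
        gio.write_expression(bundle.grex, bundle.sample_ids, shared, out / "grex.tsv")
        manifest.record(out / "grex.tsv")
        manifest.stages.append(stage)

        stage = "erex"
        erex, fit_summary = compute_erex(bundle.observed, bundle.grex, shared)
        bundle.erex = erex
        gio.write_expression(erex, bundle.sample_ids, shared, out / "erex.tsv")
        manifest.record(out / "erex.tsv")
        _write(fit_summary, out / "erex_fit.tsv", manifest)
        manifest.stages.append(stage)

        stage = "association"
        assoc = run_association(
            bundle, phenotype, covariates,
            CovariatePolicy(),
            B_initial=config.B_initial, B_max=config.B_max, seed=config.seed,
            n_expression_pcs=config.n_expression_pcs,
        )
        _write(assoc, out / "association.tsv", manifest)
        report = report_tables(assoc, config.alpha)
        _write(report, out / "report.tsv", manifest)
        manifest.stages.append(stage)

        stage = "enrichment"
        counts, overlap, sig = threshold_counts(assoc, config.alpha)
        summary_rows = [{"component": c, "n_significant": int(counts[c])} for c in counts.index]
        _write(pd.DataFrame(summary_rows), out / "threshold_counts.tsv", manifest)
        overlap.to_csv(out / "component_overlap.tsv", sep="\t")
        manifest.record(out / "component_overlap.tsv")

        pi1_rows = []
        enr_rows = []
        hist_rows = []
        universe = list(bundle.gene_ids)
        for comp in ("observed", "grex", "erex"):
            sub = assoc[assoc["component"] == comp]
            pvals = dict(zip(sub["gene_id"], sub["perm_p"]))
            stats = dict(zip(sub["gene_id"], sub["lrt_stat"]))
            pi1 = estimate_pi1(list(pvals.values()))
            pi1_rows.append({"component": comp, "pi1": pi1.pi1, "lambda": pi1.lam, "m": pi1.m})
            hist, edges = np.histogram(list(pvals.values()), bins=20, range=(0, 1))
            for lo, hi, c in zip(edges[:-1], edges[1:], hist):
                hist_rows.append({"component": comp, "bin_low": lo, "bin_high": hi, "count": int(c)})
            ranked = rank_genes(pvals, stats)
            for gs_path in config.gene_set_paths:
                gs = gio.read_gene_set(gs_path)
                for res in top_n_enrichment(ranked, gs, universe, config.top_n):
                    enr_rows.append({
                        "component": comp, "set_name": res.set_name, "N_top": res.N_top,
                        "universe_size": res.universe_size,
                        "pathway_in_universe": res.pathway_in_universe,
                        "overlap": res.overlap, "p_value": res.p_value,
                    })
        _write(pd.DataFrame(pi1_rows), out / "pi1.tsv", manifest)
        _write(pd.DataFrame(hist_rows), out / "pvalue_histogram.tsv", manifest)
        if enr_rows:
            _write(pd.DataFrame(enr_rows), out / "enrichment.tsv", manifest)
        manifest.stages.append(stage)

        stage = "summary"
        manifest.stages.append(stage)
        manifest.complete = True
    except Exception:
        manifest.wall_clock_s = time.time() - t0
        manifest.write(out / "manifest.json")
        logger.error("pipeline failed at stage %r", stage)
        raise
    manifest.wall_clock_s = time.time() - t0
    manifest.write(out / "manifest.json")
    return manifest
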