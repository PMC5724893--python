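"""End-to-end orchestration: config validation, staged execution, reports.

Stage order follows the analysis: variant QC -> sample QC -> coverage
harmonization -> collapsing -> association -> permutation QQ -> known-gene
enrichment.  A run is driven either by a simulation block (the default way
to exercise the pipeline, since the real exomes are protected) or by paths
to VCF/TSV/BED inputs.  Every stage logs its input/output counts and the
run report records the config hash, seed and library versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    _FisherCache,
    bonferroni_threshold,
    firth_profile_test,
    gene_results,
)
from .cohort_io import (
    RegionSet,
    SampleManifest,
    read_coverage,
    read_variants,
    restrict_to_regions,
)
from .collapsing import CollapsingMatrix, QualifyingRule, build_matrix
from .coverage_harmonization import DEFAULT_MAX_DIFF, harmonize
from .enrichment import nominal_enrichment, rank_scan, rank_scan_table
from .permutation_qq import (
    expected_order_statistics,
    genomic_lambda,
    permute_simple,
    permute_weighted,
    qq_table,
    urn_weights,
)
from .sample_qc import (
    KINSHIP_CUTOFF,
    LD_R2_THRESHOLD,
    PCA_ITERATIONS,
    PCA_N_PCS,
    PCA_SIGMA,
    run_sample_qc,
)
from .synthetic_cohort import SimulatedCohort, SimulationConfig, simulate_cohort
from .variant_qc import QCThresholds, apply_variant_qc

logger = logging.getLogger("rarecollapse")


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    # either a simulation block ...
    simulate: dict | None = None
    # ... or explicit input paths
    vcf: str | None = None
    annotation: str | None = None
    flags: str | None = None
    manifest: str | None = None
    coverage: str | None = None
    regions: str | None = None
    snp_panel: str | None = None

    qc_thresholds: dict = field(default_factory=dict)
    kinship_cutoff: float = KINSHIP_CUTOFF
    ld_r2_threshold: float = LD_R2_THRESHOLD
    pca_sigma: float = PCA_SIGMA
    pca_n_pcs: int = PCA_N_PCS
    pca_iterations: int = PCA_ITERATIONS
    coverage_max_diff: float = DEFAULT_MAX_DIFF
    qualifying: dict = field(default_factory=dict)
    use_covariate: bool = True
    run_firth: bool = True
    n_genes_targeted: int | None = None  # Bonferroni denominator
    n_permutations: int = 1000
    qq_tests: tuple = ("fisher", "firth")
    known_genes: list | str | None = None
    skip_sample_qc: bool = False
    seed: int = 0


def validate_config(source) -> RunConfig:
    """Build a RunConfig from a YAML path or dict; report *all* violations."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})

    errors: list[str] = []
    known_fields = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known_fields
    for k in sorted(unknown):
        errors.append(f"unknown config field: {k}")
    raw = {k: v for k, v in raw.items() if k in known_fields}

    cfg = RunConfig(**raw)
    if cfg.simulate is None:
        for fld in ("vcf", "annotation", "manifest", "coverage"):
            if getattr(cfg, fld) is None:
                errors.append(f"missing required input path: {fld}")
            elif not Path(getattr(cfg, fld)).exists():
                errors.append(f"{fld} path does not exist: {getattr(cfg, fld)}")
    else:
        try:
            SimulationConfig(**cfg.simulate)
        except (TypeError, ValueError) as e:
            errors.append(f"invalid simulate block: {e}")
    if cfg.coverage_max_diff < 0:
        errors.append("coverage_max_diff must be non-negative")
    if cfg.n_permutations < 0:
        errors.append("n_permutations must be non-negative")
    if cfg.kinship_cutoff < 0:
        errors.append("kinship_cutoff must be non-negative")
    try:
        QCThresholds.from_dict(cfg.qc_thresholds)
    except ValueError as e:
        errors.append(str(e))
    try:
        QualifyingRule(**cfg.qualifying)
    except (TypeError, ValueError) as e:
        errors.append(f"invalid qualifying block: {e}")
    if errors:
        raise StageError("config", "invalid", "; ".join(errors))
    return cfg


def _load_known_genes(spec) -> list[str]:
    if spec is None:
        return []
    if isinstance(spec, (list, tuple)):
        return list(spec)
    with open(spec) as fh:
        return [line.strip() for line in fh if line.strip()]


@dataclass
class PipelineResult:
    gene_results: pd.DataFrame
    matrix: CollapsingMatrix
    report: dict
    enrichment: pd.DataFrame | None = None
    qq: dict = field(default_factory=dict)
    cohort: SimulatedCohort | None = None


def run_pipeline(config: RunConfig, outdir=None) -> PipelineResult:
    """Execute all stages; write TSV/JSON products if ``outdir`` is given."""
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "library_versions": {
            "numpy": np.__version__, "pandas": pd.__version__,
        },
        "stages": {},
    }

    # ---- inputs ----------------------------------------------------
    try:
        if config.simulate is not None:
            sim_cfg = SimulationConfig(**{**config.simulate,
                                          "seed": config.simulate.get(
                                              "seed", config.seed)})
            cohort = simulate_cohort(sim_cfg)
            variants = cohort.variants
            manifest = cohort.manifest
            coverage = cohort.coverage
            panel = cohort.snp_panel
            panel_ids = cohort.sample_ids
            gene_universe = [f"G{i + 1:05d}" for i in range(sim_cfg.n_genes)]
        else:
            cohort = None
            variants = read_variants(config.vcf, config.annotation, config.flags)
            manifest = SampleManifest.from_tsv(config.manifest)
            coverage = read_coverage(config.coverage, manifest)
            if config.snp_panel:
                dfp = pd.read_csv(config.snp_panel, sep="\t")
                panel = dfp.to_numpy().T.astype(np.int8)
                panel_ids = list(dfp.columns)
            else:
                panel, panel_ids = None, None
            gene_universe = sorted(
                {v.annotation.gene for v in variants if v.annotation.gene}
            )
        if config.regions:
            variants = restrict_to_regions(
                variants, RegionSet.from_bed(config.regions))
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError("inputs", "read_failure", str(e)) from e
    report["stages"]["inputs"] = {
        "n_variants": len(variants), "n_samples": len(manifest),
        "n_cases": manifest.n_cases, "n_controls": manifest.n_controls,
    }

    # ---- variant QC ------------------------------------------------
    try:
        thresholds = QCThresholds.from_dict(config.qc_thresholds)
        variants, qc_report = apply_variant_qc(variants, thresholds)
    except Exception as e:
        raise StageError("variant_qc", "filter_failure", str(e)) from e
    report["stages"]["variant_qc"] = {"n_variants_pass": len(variants)}

    # ---- sample QC -------------------------------------------------
    sampleqc_log = None
    if not config.skip_sample_qc and panel is not None:
        try:
            retained_ids, sampleqc_log = run_sample_qc(
                panel, panel_ids, manifest,
                kinship_cutoff=config.kinship_cutoff,
                r2_threshold=config.ld_r2_threshold,
                n_pcs=config.pca_n_pcs, sigma=config.pca_sigma,
                iterations=config.pca_iterations,
            )
        except Exception as e:
            raise StageError("sample_qc", "estimator_failure", str(e)) from e
        manifest = manifest.subset(retained_ids)
    report["stages"]["sample_qc"] = {
        "n_samples_retained": len(manifest),
        "n_cases": manifest.n_cases, "n_controls": manifest.n_controls,
    }

    # ---- coverage harmonization -----------------------------------
    try:
        sites = sorted({v.site for v in variants})
        retained_sites, summaries = harmonize(
            coverage, manifest, sites, max_diff=config.coverage_max_diff)
    except Exception as e:
        raise StageError("coverage", "harmonization_failure", str(e)) from e
    report["stages"]["coverage_harmonization"] = {
        "n_sites": len(sites),
        "n_pruned": len(sites) - len(retained_sites),
        "pruned_fraction": (len(sites) - len(retained_sites)) / max(len(sites), 1),
    }

    # ---- collapsing ------------------------------------------------
    try:
        rule = QualifyingRule(**config.qualifying)
        sample_ids = manifest.sample_ids
        matrix = build_matrix(variants, rule, sample_ids,
                              genes=gene_universe,
                              retained_sites=retained_sites)
    except Exception as e:
        raise StageError("collapsing", "matrix_failure", str(e)) from e
    y = manifest.phenotype_vector(sample_ids)
    report["stages"]["collapsing"] = {
        "n_genes": len(matrix.genes),
        "n_carrier_entries": int(matrix.indicator.nnz),
        "mean_syn_covariate": float(matrix.syn_covariate.mean()),
    }

    # ---- association -----------------------------------------------
    try:
        results = gene_results(matrix, y, use_covariate=config.use_covariate,
                               run_firth=config.run_firth)
        n_target = config.n_genes_targeted or len(matrix.genes)
        alpha = bonferroni_threshold(n_target)
        results["fisher_genomewide"] = results["fisher_p"] < alpha
        if config.run_firth:
            results["firth_genomewide"] = results["firth_p"] < alpha
            results["genomewide_significant"] = (
                results["fisher_genomewide"] & results["firth_genomewide"])
        else:
            results["genomewide_significant"] = results["fisher_genomewide"]
    except Exception as e:
        raise StageError("association", "test_failure", str(e)) from e
    report["stages"]["association"] = {
        "bonferroni_alpha": alpha,
        "n_genes_targeted": n_target,
        "n_genomewide_significant": int(results["genomewide_significant"].sum()),
        "significant_genes": results.loc[
            results["genomewide_significant"], "gene"].tolist(),
    }

    # ---- permutation QQ --------------------------------------------
    qq: dict = {}
    if config.n_permutations >= 2 and config.qq_tests:
        try:
            qq = _run_qq(matrix, y, config)
        except Exception as e:
            raise StageError("permutation_qq", "ensemble_failure", str(e)) from e
        report["stages"]["permutation_qq"] = {
            k: {"lambda": v["lambda"], "n_permutations": config.n_permutations}
            for k, v in qq.items()
        }

    # ---- enrichment ------------------------------------------------
    enrich_df = None
    known = _load_known_genes(config.known_genes)
    if known:
        try:
            scan = rank_scan(results, known)
            enrich_df = rank_scan_table(scan)
            pcol = "firth_p" if config.run_firth else "fisher_p"
            known_nominal = int((results.set_index("gene").loc[
                [g for g in known if g in set(results["gene"])], pcol] < 0.05
            ).sum())
            all_nominal = int((results[pcol] < 0.05).sum())
            report["stages"]["enrichment"] = {
                "known_genes": len(known),
                "known_nominal": known_nominal,
                "all_nominal": all_nominal,
                "nominal_enrichment_p": nominal_enrichment(
                    known_nominal, len(known), all_nominal, len(results)),
            }
        except Exception as e:
            raise StageError("enrichment", "scan_failure", str(e)) from e

    # ---- outputs ---------------------------------------------------
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "gene_results.tsv", sep="\t", index=False)
        qc_report.to_csv(out / "variant_qc_report.tsv", sep="\t", index=False)
        pruned = [s.site for s in summaries if s.pruned]
        with open(out / "pruned_sites.bed", "w") as fh:
            for chrom, pos in pruned:
                fh.write(f"{chrom}\t{pos - 1}\t{pos}\n")
        if sampleqc_log is not None:
            pd.DataFrame(sampleqc_log["related_removed"]).to_csv(
                out / "related_removed.tsv", sep="\t", index=False)
        for name, blob in qq.items():
            blob["table"].to_csv(out / f"qq_{name}.tsv", sep="\t", index=False)
        if enrich_df is not None:
            enrich_df.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=str)

    return PipelineResult(
        gene_results=results, matrix=matrix, report=report,
        enrichment=enrich_df, qq=qq, cohort=cohort,
    )


def _run_qq(matrix: CollapsingMatrix, y: np.ndarray, config: RunConfig) -> dict:
    """Permutation ensembles + lambda for the configured tests."""
    n = len(y)
    n_cases = int(np.asarray(y).sum())
    indicator = matrix.indicator
    out: dict = {}

    if "fisher" in config.qq_tests:
        cache = _FisherCache(n_cases, n - n_cases)
        totals = np.asarray(indicator.sum(axis=1)).ravel().astype(int)

        def fisher_pfun(labels):
            a = np.asarray(indicator @ labels).ravel().astype(int)
            return np.array([cache.p(ai, ti) for ai, ti in zip(a, totals)])

        ens = expected_order_statistics(
            fisher_pfun,
            lambda rng: permute_simple(n, n_cases, rng),
            n_perm=config.n_permutations,
            seed=config.seed,
        )
        obs = fisher_pfun(np.asarray(y))
        out["fisher"] = {
            "ensemble": ens,
            "table": qq_table(obs, ens),
            "lambda": genomic_lambda(np.clip(obs, 1e-300, 1.0)),
        }

    if "firth" in config.qq_tests:
        z = matrix.syn_covariate if config.use_covariate else None
        dense_rows = [
            np.asarray(indicator[gi].todense()).ravel().astype(float)
            for gi in range(indicator.shape[0])
        ]

        def firth_pfun(labels):
            labels = np.asarray(labels)
            ps = np.ones(len(dense_rows))
            for gi, x in enumerate(dense_rows):
                if x.max() > x.min():
                    ps[gi], _ = firth_profile_test(labels, x, z)
            return ps

        if z is not None and z.max() > z.min():
            weights = urn_weights(np.asarray(y), z).weights
            permuter = lambda rng: permute_weighted(weights, n_cases, rng)
        else:
            permuter = lambda rng: permute_simple(n, n_cases, rng)
        ens = expected_order_statistics(
            firth_pfun, permuter,
            n_perm=config.n_permutations,
            seed=None if config.seed is None else config.seed + 1,
        )
        obs = firth_pfun(np.asarray(y))
        out["firth"] = {
            "ensemble": ens,
            "table": qq_table(obs, ens),
            "lambda": genomic_lambda(np.clip(obs, 1e-300, 1.0)),
        }
    return out
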