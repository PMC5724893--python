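"""Synthetic case-control exome cohorts with the structure the analysis assumes.

The real study data (individual-level exomes) are protected, so every
stage is exercised on generated cohorts that emulate the analysis-relevant
structure: ~500 cases vs ~12,000 controls; per-gene ultra-rare qualifying
carriers at a background rate with designated risk genes enriched in
cases; a per-sample ultra-rare synonymous count (negative binomial,
optionally case-shifted, optionally driving the qualifying-carrier rate —
the batch confounder the covariate adjustment targets); capture-kit-style
coverage imbalance at a minority of sites; planted duplicate and
parent-offspring pairs; and two-subpopulation structure plus planted
outliers on a separate common-SNP panel used only by sample QC.

Simulation is carrier-level: a sample carries >=1 qualifying variant in a
gene with the configured probability, and carriers are grouped into
variants of 1-4 heterozygous carriers so every planted variant respects
the <=4-copy ultra-rarity rule.  The collapsing statistic only sees
carrier status, so this is its sufficient statistic; no site-frequency
spectrum or haplotype structure is modeled.

Everything is driven by one ``numpy`` generator seeded from
``SimulationConfig.seed``: identical configs give identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict

import numpy as np

from .cohort_io import (
    Annotation,
    CoverageTable,
    ExternalFlags,
    Genotype,
    HET,
    LOF_EFFECTS,
    SampleManifest,
    SiteStats,
    VariantRecord,
)

import pandas as pd

_LOF_LIST = sorted(LOF_EFFECTS)


@dataclass
class SimulationConfig:
    # cohort size (defaults mirror the post-QC analysis cohort)
    n_cases: int = 488
    n_controls: int = 12151
    n_genes: int = 2000

    # qualifying-variant architecture
    background_carrier_prob: float = 0.002
    risk_genes: dict = field(default_factory=dict)  # gene -> case carrier prob
    decoys_per_gene_mean: float = 1.0  # non-qualifying background mass

    # ultra-rare synonymous covariate (negative binomial per sample)
    syn_control_mean: float = 8.0
    syn_case_mean: float = 8.0
    syn_dispersion: float = 8.0  # NB size parameter; smaller = more overdispersed
    # when True, each sample's qualifying-carrier probability scales with
    # its synonymous count: the confounded regime the covariate corrects
    confound_carriers_with_covariate: bool = False

    # capture-kit coverage imbalance
    imbalanced_site_fraction: float = 0.1
    coverage_gap: float = 0.2  # case coverage deficit at imbalanced sites
    baseline_uncovered_rate: float = 0.01  # per group at imbalanced sites

    # relatedness and structure (common-SNP panel only)
    related_pairs: list = field(
        default_factory=lambda: [("duplicate", 1), ("parent_offspring", 3)]
    )
    genotype_error: float = 0.0
    # panel size keeps the null kinship noise (sd ~ 0.7/sqrt(L)) far below
    # the 0.1 cutoff even over millions of sample pairs
    n_panel_snps: int = 5000
    subpop2_fraction: float = 0.2
    fst: float = 0.05
    n_outliers: int = 1
    # divergence of planted ancestry outliers; chosen clear of the spiked-
    # covariance detection edge at the default panel size, so a 6-sigma PC
    # criterion flags them reliably
    outlier_fst: float = 0.3

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        for name in ("background_carrier_prob", "imbalanced_site_fraction",
                     "coverage_gap", "baseline_uncovered_rate",
                     "subpop2_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for g, p in self.risk_genes.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"risk gene {g} carrier prob {p} outside [0,1]")


@dataclass
class SimulatedCohort:
    variants: list[VariantRecord]
    coverage: CoverageTable
    manifest: SampleManifest
    snp_panel: np.ndarray  # (n_samples, n_panel_snps) int8
    truth: dict

    @property
    def sample_ids(self) -> list[str]:
        return self.manifest.sample_ids


def _gene_name(i: int) -> str:
    return f"G{i + 1:05d}"


def _make_genotype(rng: np.random.Generator) -> Genotype:
    depth = int(rng.integers(25, 60))
    return Genotype(HET, depth=depth, gq=99.0, alt_reads=depth // 2)


_CLEAN_STATS = dict(qual=250.0, qd=15.0, mq=60.0, rprs=0.5, mqrs=0.2, fs=1.0,
                    vqsr_pass=True, is_indel=False)


def _chunk_distinct(events: list[str], rng: np.random.Generator,
                    max_size: int = 4) -> list[list[str]]:
    """Group carrier events into variants of <= max_size distinct samples."""
    order = list(rng.permutation(len(events)))
    chunks: list[list[str]] = []
    current: list[str] = []
    target = int(rng.integers(1, max_size + 1))
    for k in order:
        s = events[k]
        if s in current or len(current) >= target:
            chunks.append(current)
            current = []
            target = int(rng.integers(1, max_size + 1))
        current.append(s)
    if current:
        chunks.append(current)
    return chunks


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full cohort; see the module docstring for the model."""
    for g in config.risk_genes:
        if g not in {_gene_name(i) for i in range(config.n_genes)}:
            raise ValueError(f"risk gene {g} not among the {config.n_genes} genes")

    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    case_ids = [f"CASE{i + 1:05d}" for i in range(config.n_cases)]
    ctrl_ids = [f"CTRL{i + 1:05d}" for i in range(config.n_controls)]
    sample_ids = case_ids + ctrl_ids
    is_case = np.zeros(n, dtype=bool)
    is_case[: config.n_cases] = True

    # manifest with mean CCDS coverage (used for relatedness tie-breaks)
    mean_cov = np.clip(
        np.where(is_case,
                 rng.normal(0.932, 0.01, n),
                 rng.normal(0.952, 0.01, n)),
        0.0, 1.0,
    )
    manifest = SampleManifest(pd.DataFrame({
        "sample_id": sample_ids,
        "phenotype": np.where(is_case, "case", "control"),
        "mean_ccds_coverage": mean_cov,
        "qc_flags": "",
    }))

    # per-sample synonymous counts (the covariate), negative binomial
    means = np.where(is_case, config.syn_case_mean, config.syn_control_mean)
    k = config.syn_dispersion
    syn_counts = rng.negative_binomial(k, k / (k + means), size=n)

    # per-sample qualifying-carrier rate multiplier (confounded regime)
    if config.confound_carriers_with_covariate:
        mean_syn = max(float(syn_counts.mean()), 1e-9)
        load = syn_counts / mean_syn
    else:
        load = np.ones(n)

    variants: list[VariantRecord] = []
    truth_carriers: dict[str, dict[str, list[str]]] = {}
    pos_counters: dict[int, int] = {}

    def next_pos(gene_idx: int) -> int:
        # each gene owns a disjoint 100 kb block; offsets never collide
        pos_counters[gene_idx] = pos_counters.get(gene_idx, 0) + 1
        return (gene_idx + 1) * 100_000 + pos_counters[gene_idx]

    # qualifying-candidate variants, gene by gene
    for gi in range(config.n_genes):
        gene = _gene_name(gi)
        p_case = config.risk_genes.get(gene, config.background_carrier_prob)
        p = np.where(is_case, p_case, config.background_carrier_prob) * load
        carriers = np.flatnonzero(rng.random(n) < np.clip(p, 0.0, 1.0))
        truth_carriers[gene] = {
            "cases": [sample_ids[i] for i in carriers if is_case[i]],
            "controls": [sample_ids[i] for i in carriers if not is_case[i]],
        }
        if len(carriers) == 0:
            continue
        for chunk in _chunk_distinct([sample_ids[i] for i in carriers], rng):
            if rng.random() < 0.5:
                ann = Annotation(gene=gene, effect="missense",
                                 polyphen_humdiv="probably_damaging")
            else:
                ann = Annotation(gene=gene,
                                 effect=_LOF_LIST[rng.integers(len(_LOF_LIST))])
            variants.append(VariantRecord(
                chrom="1", pos=next_pos(gi), ref="A", alt="T",
                site_stats=SiteStats(**_CLEAN_STATS),
                genotypes={s: _make_genotype(rng) for s in chunk},
                annotation=ann,
                external_flags=ExternalFlags(),
            ))

    # non-qualifying decoys: present in ExAC, benign missense, or artifacts
    n_decoys = rng.poisson(config.decoys_per_gene_mean, config.n_genes)
    for gi in range(config.n_genes):
        for _ in range(int(n_decoys[gi])):
            carriers = [sample_ids[i]
                        for i in rng.choice(n, size=int(rng.integers(1, 4)),
                                            replace=False)]
            kind = rng.integers(3)
            flags = ExternalFlags()
            if kind == 0:
                flags = ExternalFlags(in_exac=True)
                ann = Annotation(gene=_gene_name(gi), effect="missense",
                                 polyphen_humdiv="probably_damaging")
            elif kind == 1:
                ann = Annotation(gene=_gene_name(gi), effect="missense",
                                 polyphen_humdiv="benign")
            else:
                flags = ExternalFlags(on_artifact_list=True)
                ann = Annotation(gene=_gene_name(gi),
                                 effect=_LOF_LIST[rng.integers(len(_LOF_LIST))])
            variants.append(VariantRecord(
                chrom="1", pos=next_pos(gi), ref="G", alt="C",
                site_stats=SiteStats(**_CLEAN_STATS),
                genotypes={s: _make_genotype(rng) for s in carriers},
                annotation=ann, external_flags=flags,
            ))

    # ultra-rare synonymous variants realizing the covariate counts exactly
    syn_events: list[str] = []
    for i in range(n):
        syn_events.extend([sample_ids[i]] * int(syn_counts[i]))
    for chunk in _chunk_distinct(syn_events, rng):
        gi = int(rng.integers(config.n_genes))
        variants.append(VariantRecord(
            chrom="1", pos=next_pos(gi), ref="C", alt="G",
            site_stats=SiteStats(**_CLEAN_STATS),
            genotypes={s: _make_genotype(rng) for s in chunk},
            annotation=Annotation(gene=_gene_name(gi), effect="synonymous"),
            external_flags=ExternalFlags(),
        ))

    # coverage: imbalanced sites undercover cases by `coverage_gap`
    uncovered: dict[tuple[str, int], np.ndarray] = {}
    case_idx = np.flatnonzero(is_case)
    ctrl_idx = np.flatnonzero(~is_case)
    imbalanced_sites: list[tuple[str, int]] = []
    for v in variants:
        if rng.random() < config.imbalanced_site_fraction:
            r_case = config.baseline_uncovered_rate + config.coverage_gap
            r_ctrl = config.baseline_uncovered_rate
            unc_c = case_idx[rng.random(len(case_idx)) < r_case]
            unc_k = ctrl_idx[rng.random(len(ctrl_idx)) < r_ctrl]
            uncovered[v.site] = np.sort(np.concatenate([unc_c, unc_k]))
            imbalanced_sites.append(v.site)
        else:
            uncovered[v.site] = np.empty(0, dtype=np.int64)
    coverage = CoverageTable.from_uncovered_sets(uncovered, sample_ids)

    # common-SNP panel: two subpopulations + outliers + related pairs
    subpop = (rng.random(n) < config.subpop2_fraction).astype(np.int8)
    outlier_ids: list[str] = []
    if config.n_outliers > 0:
        out_idx = rng.choice(ctrl_idx, size=config.n_outliers, replace=False)
        outlier_ids = [sample_ids[i] for i in out_idx]
    p0 = rng.uniform(0.05, 0.5, config.n_panel_snps)

    def bn_freqs(p, f):
        if f <= 0:
            return p.copy()
        a = p * (1.0 - f) / f
        b = (1.0 - p) * (1.0 - f) / f
        return rng.beta(a, b)

    pop_freqs = np.vstack([bn_freqs(p0, config.fst),
                           bn_freqs(p0, config.fst),
                           bn_freqs(p0, config.outlier_fst)])
    pop_of = subpop.astype(np.int64).copy()
    for s in outlier_ids:
        pop_of[sample_ids.index(s)] = 2
    panel = rng.binomial(2, pop_freqs[pop_of]).astype(np.int8)

    related_truth: list[dict] = []
    avail = [i for i in ctrl_idx if sample_ids[i] not in outlier_ids]
    rng.shuffle(avail)
    cursor = 0
    for kind, count in config.related_pairs:
        for _ in range(int(count)):
            if cursor + 1 >= len(avail):
                raise ValueError("not enough controls to plant related pairs")
            i, j = avail[cursor], avail[cursor + 1]
            cursor += 2
            if kind == "duplicate":
                panel[j] = panel[i]
                if config.genotype_error > 0:
                    flips = rng.random(config.n_panel_snps) < config.genotype_error
                    panel[j, flips] = rng.integers(
                        0, 3, int(flips.sum())).astype(np.int8)
            elif kind == "parent_offspring":
                transmitted = np.where(
                    panel[i] == 1, rng.integers(0, 2, config.n_panel_snps),
                    (panel[i] // 2),
                )
                other = rng.binomial(1, pop_freqs[pop_of[j], :])
                panel[j] = (transmitted + other).astype(np.int8)
            else:
                raise ValueError(f"unknown related-pair kind {kind!r}")
            related_truth.append({
                "kind": kind,
                "pair": [sample_ids[i], sample_ids[j]],
            })

    truth = {
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "risk_genes": dict(config.risk_genes),
        "carriers_by_gene": truth_carriers,
        "syn_counts": {s: int(c) for s, c in zip(sample_ids, syn_counts)},
        "imbalanced_sites": [list(s) for s in imbalanced_sites],
        "related_pairs": related_truth,
        "subpop": {s: int(z) for s, z in zip(sample_ids, subpop)},
        "outliers": outlier_ids,
    }
    return SimulatedCohort(
        variants=variants, coverage=coverage, manifest=manifest,
        snp_panel=panel, truth=truth,
    )


def simulate_null_pvalue_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Null-effect cohort: no risk genes, but the synonymous covariate both
    differs between cases and controls (by the configured means) and drives
    the qualifying-carrier rate — the confounded regime where unadjusted
    tests inflate and covariate-adjusted tests should not."""
    return simulate_cohort(replace(
        config, risk_genes={}, confound_carriers_with_covariate=True,
    ))


def write_cohort(cohort: SimulatedCohort, outdir) -> dict:
    """Serialize a cohort to the formats the readers consume."""
    from pathlib import Path

    from .cohort_io import write_annotation, write_flags, write_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "annotation": outdir / "annotation.tsv",
        "flags": outdir / "flags.tsv",
        "manifest": outdir / "manifest.tsv",
        "coverage": outdir / "coverage.tsv",
        "panel": outdir / "snp_panel.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(cohort.variants, cohort.sample_ids, paths["vcf"])
    write_annotation(cohort.variants, paths["annotation"])
    write_flags(cohort.variants, paths["flags"])
    cohort.manifest.to_tsv(paths["manifest"])
    sites = sorted({v.site for v in cohort.variants}, key=lambda s: (s[0], s[1]))
    cohort.coverage.to_site_table(paths["coverage"], sites)
    pd.DataFrame(cohort.snp_panel.T, columns=cohort.sample_ids).to_csv(
        paths["panel"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
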