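"""Qualifying-variant determination and the gene x sample collapsing matrix.

A variant qualifies when it is ultra-rare (absent from EVS and ExAC and
carrying at most ``max_cohort_alt_copies`` alternate alleles across the
retained cohort, default 4) and predicted impactful (one of the six
loss-of-function classes, or missense called probably-damaging by
PolyPhen-2 HumDiv).  Each sample then gets a 0/1 indicator per gene for
carrying at least one qualifying variant — a dominant model.

The per-sample covariate is the count of ultra-rare *synonymous* variants
(same rarity rules, no impact filter): a proxy for batch- and
ancestry-driven background variant load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .cohort_io import HET, HOM_ALT, LOF_EFFECTS, VariantRecord

logger = logging.getLogger("rarecollapse")


@dataclass
class QualifyingRule:
    require_absent_evs: bool = True
    require_absent_exac: bool = True
    max_cohort_alt_copies: int = 4
    lof_effects: frozenset = field(default_factory=lambda: LOF_EFFECTS)
    missense_requires: str = "probably_damaging"

    def __post_init__(self) -> None:
        if self.max_cohort_alt_copies < 1:
            raise ValueError("max_cohort_alt_copies must be >= 1")


def cohort_alt_copies(v: VariantRecord, retained_samples: set[str]) -> int:
    """Alternate-allele copies over retained samples (het=1, hom_alt=2)."""
    copies = 0
    for s, g in v.genotypes.items():
        if s in retained_samples:
            if g.call == HET:
                copies += 1
            elif g.call == HOM_ALT:
                copies += 2
    return copies


def is_qualifying(v: VariantRecord, rule: QualifyingRule, copies: int) -> bool:
    """Rarity (external absence + cohort copies) and impact criteria."""
    f = v.external_flags
    if rule.require_absent_evs and f.in_evs:
        return False
    if rule.require_absent_exac and f.in_exac:
        return False
    if copies > rule.max_cohort_alt_copies:
        return False
    a = v.annotation
    if a.effect in rule.lof_effects:
        return True
    return a.effect == "missense" and a.polyphen_humdiv == rule.missense_requires


def _is_ultra_rare_synonymous(
    v: VariantRecord, rule: QualifyingRule, copies: int
) -> bool:
    f = v.external_flags
    if rule.require_absent_evs and f.in_evs:
        return False
    if rule.require_absent_exac and f.in_exac:
        return False
    if copies > rule.max_cohort_alt_copies:
        return False
    return v.annotation.effect == "synonymous"


@dataclass
class CollapsingMatrix:
    """Gene x sample carrier indicators plus the synonymous covariate."""

    genes: list[str]
    samples: list[str]
    indicator: sparse.csr_matrix  # genes x samples, 0/1
    syn_covariate: np.ndarray  # per-sample integer count

    def __post_init__(self) -> None:
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    def gene_row(self, gene: str) -> np.ndarray:
        return np.asarray(
            self.indicator[self._gene_index[gene]].todense()
        ).ravel()

    def carrier_counts(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(case carriers, control carriers) per gene for labels y (1=case)."""
        y = np.asarray(y, dtype=np.int64)
        cases = np.asarray(self.indicator @ y).ravel()
        totals = np.asarray(
            self.indicator.astype(np.int64).sum(axis=1)).ravel()
        return cases, totals - cases

    def to_tsv(self, path) -> None:
        """Sparse (gene, sample_id) pairs, one carrier per line."""
        coo = self.indicator.tocoo()
        with open(path, "w") as fh:
            fh.write("gene\tsample_id\n")
            for gi, si in zip(coo.row, coo.col):
                fh.write(f"{self.genes[gi]}\t{self.samples[si]}\n")


def build_matrix(
    variants: list[VariantRecord],
    rule: QualifyingRule,
    samples: list[str],
    genes: list[str] | None = None,
    retained_sites: set[tuple[str, int]] | None = None,
) -> CollapsingMatrix:
    """Assemble the dominant-model collapsing matrix and covariate.

    ``variants`` must already have passed variant QC (failing genotypes
    removed).  ``retained_sites``, when given, is the coverage-harmonized
    site set; variants outside it contribute to neither the indicator nor
    the covariate.  ``genes`` optionally fixes the tested gene universe so
    genes with zero qualifying variants appear as all-zero rows.
    """
    retained = set(samples)
    sample_index = {s: i for i, s in enumerate(samples)}

    usable: list[tuple[VariantRecord, int]] = []
    n_cov_dropped = 0
    for v in variants:
        if retained_sites is not None and v.site not in retained_sites:
            n_cov_dropped += 1
            continue
        usable.append((v, cohort_alt_copies(v, retained)))
    if retained_sites is not None:
        logger.info(
            "collapsing: %d variants dropped by coverage harmonization",
            n_cov_dropped,
        )

    gene_set = dict.fromkeys(genes) if genes is not None else {}
    rows, cols = [], []
    syn = np.zeros(len(samples), dtype=np.int64)
    gene_of: dict[str, int] = {g: i for i, g in enumerate(gene_set)}

    for v, copies in usable:
        if is_qualifying(v, rule, copies):
            g = v.annotation.gene
            if not g:
                logger.warning("qualifying variant %s:%d with empty gene; skipped",
                               v.chrom, v.pos)
                continue
            if g not in gene_of:
                if genes is not None:
                    logger.warning("gene %s not in provided universe; added", g)
                gene_of[g] = len(gene_of)
            gi = gene_of[g]
            for s in v.carriers():
                if s in sample_index:
                    rows.append(gi)
                    cols.append(sample_index[s])
        elif _is_ultra_rare_synonymous(v, rule, copies):
            for s in v.carriers():
                if s in sample_index:
                    syn[sample_index[s]] += 1

    gene_list = list(gene_of)
    data = np.ones(len(rows), dtype=np.int8)
    indicator = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(gene_list), len(samples))
    )
    indicator.sum_duplicates()
    indicator.data = np.ones_like(indicator.data)  # >=1 variant -> carrier
    return CollapsingMatrix(
        genes=gene_list, samples=list(samples), indicator=indicator,
        syn_covariate=syn,
    )


def synonymous_covariate(
    variants: list[VariantRecord],
    samples: list[str],
    rule: QualifyingRule | None = None,
    retained_sites: set[tuple[str, int]] | None = None,
) -> np.ndarray:
    """Per-sample count of distinct ultra-rare synonymous variants carried."""
    rule = rule or QualifyingRule()
    retained = set(samples)
    sample_index = {s: i for i, s in enumerate(samples)}
    counts = np.zeros(len(samples), dtype=np.int64)
    for v in variants:
        if retained_sites is not None and v.site not in retained_sites:
            continue
        copies = cohort_alt_copies(v, retained)
        if _is_ultra_rare_synonymous(v, rule, copies):
            for s in v.carriers():
                if s in sample_index:
                    counts[sample_index[s]] += 1
    return counts
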