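"""Hard site/genotype filters and artifact screening for called variants.

The defaults encode the usual GATK-style hard thresholds for exome
case-control work: QUAL>=30, QD>=2, MQ>=40, rank-sum bounds RPRS>-3 and
MQRS>-6, FS<=200 for indels only, a VQSR PASS flag, and per-genotype
DP>=10, GQ>=20 with an alternate-allele ratio >=25% for heterozygotes.

Missing site statistics pass their criterion: the rank-sum annotations are
undefined (not bad) at sites without the relevant genotype classes, and
excluding them would silently drop valid rare-variant sites.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace

import pandas as pd

from .cohort_io import HET, MISSING, Genotype, VariantRecord

logger = logging.getLogger("rarecollapse")


@dataclass
class QCThresholds:
    min_depth: int = 10
    min_qual: float = 30.0
    min_gq: float = 20.0
    min_qd: float = 2.0
    min_mq: float = 40.0
    min_rprs: float = -3.0  # strict: RPRS must be > this
    min_mqrs: float = -6.0  # strict: MQRS must be > this
    max_fs_indel: float = 200.0
    het_alt_ratio_min: float = 0.25
    require_vqsr_pass: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "QCThresholds":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown QC threshold(s): {sorted(unknown)}")
        return replace(cls(), **d)


def site_passes(v: VariantRecord, t: QCThresholds) -> tuple[bool, list[str]]:
    """Evaluate all site-level criteria; reasons list every failure."""
    st = v.site_stats
    reasons = []
    if st.qual is not None and st.qual < t.min_qual:
        reasons.append("qual")
    if st.qd is not None and st.qd < t.min_qd:
        reasons.append("qd")
    if st.mq is not None and st.mq < t.min_mq:
        reasons.append("mq")
    if st.rprs is not None and not st.rprs > t.min_rprs:
        reasons.append("rprs")
    if st.mqrs is not None and not st.mqrs > t.min_mqrs:
        reasons.append("mqrs")
    if st.is_indel and st.fs is not None and st.fs > t.max_fs_indel:
        reasons.append("fs")
    if t.require_vqsr_pass and not st.vqsr_pass:
        reasons.append("vqsr")
    return (not reasons, reasons)


def genotype_passes(g: Genotype, t: QCThresholds) -> bool:
    """DP/GQ filter plus the het-only alternate allele ratio rule."""
    if g.call == MISSING:
        return False
    if g.depth == 0:
        logger.debug("non-missing genotype with zero depth fails QC")
        return False
    if g.depth < t.min_depth or g.gq < t.min_gq:
        return False
    if g.call == HET and g.alt_reads / g.depth < t.het_alt_ratio_min:
        return False
    return True


def screen_external(v: VariantRecord) -> bool:
    """True iff the variant survives artifact/problem-list screening.

    Presence in EVS/ExAC is *not* screened here — that is a rarity
    criterion applied when deciding qualifying status; this screen only
    removes known sequencing artifacts and variants the external
    databases themselves flag as problematic.
    """
    f = v.external_flags
    return not (f.on_artifact_list or f.problematic)


def apply_variant_qc(
    variants: list[VariantRecord], t: QCThresholds | None = None
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Full variant-level QC pass.

    Site failures and artifact screening drop the whole record; genotype
    failures drop only the failing genotype (the sample becomes a
    non-carrier for that variant).  Returns the surviving records plus a
    per-variant report of failure reasons.
    """
    t = t or QCThresholds()
    kept: list[VariantRecord] = []
    report_rows = []
    reason_counts: Counter = Counter()
    for v in variants:
        ok, reasons = site_passes(v, t)
        if not screen_external(v):
            ok = False
            reasons = reasons + ["artifact"]
        n_geno_fail = 0
        if ok:
            passing = {
                s: g for s, g in v.genotypes.items() if genotype_passes(g, t)
            }
            n_geno_fail = len(v.genotypes) - len(passing)
            kept.append(replace(v, genotypes=passing))
        reason_counts.update(reasons)
        report_rows.append(
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "site_pass": ok,
                "failure_reasons": ",".join(reasons),
                "n_genotypes_failing": n_geno_fail,
            }
        )
    logger.info(
        "variant QC kept %d/%d variants (site failures by reason: %s)",
        len(kept), len(variants), dict(reason_counts),
    )
    return kept, pd.DataFrame(report_rows)
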