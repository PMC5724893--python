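"""Cohort input/output: manifests, regions, variants, coverage.

All genomic intervals are stored half-open, 0-based internally; VCF
positions stay 1-based on the `VariantRecord` (as printed in the file) and
are converted exactly once wherever an interval lookup happens.

Genotypes are stored sparsely: only non-hom-ref calls are kept per variant,
which matches the rare-variant regime where almost every sample is
homozygous reference.  Missing genotypes are non-carriers for collapsing;
sample-level coverage is tracked separately in :class:`CoverageTable`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger("rarecollapse")

# genotype call states
HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"

# closed effect vocabulary: six LoF classes, missense, synonymous, plus
# catch-all bins for annotations we do not act on
LOF_EFFECTS = frozenset(
    {
        "stop_gained",
        "frame_shift",
        "splice_site_acceptor",
        "splice_site_donor",
        "start_lost",
        "exon_deleted",
    }
)
KNOWN_EFFECTS = LOF_EFFECTS | {"missense", "synonymous", "other", "unknown"}

POLYPHEN_LEVELS = ("probably_damaging", "possibly_damaging", "benign", "unknown")


@dataclass
class Genotype:
    """One non-reference genotype call with the quality fields QC needs."""

    call: str
    depth: int = 0
    gq: float = 0.0
    alt_reads: int = 0

    def __post_init__(self) -> None:
        if self.alt_reads > self.depth:
            raise ValueError(
                f"alt_reads ({self.alt_reads}) exceeds depth ({self.depth})"
            )


_HOM_REF_GT = Genotype(HOM_REF, depth=0, gq=0.0, alt_reads=0)


@dataclass
class SiteStats:
    """Site-level calling annotations; None means the caller omitted it."""

    qual: float | None = None
    qd: float | None = None
    mq: float | None = None
    rprs: float | None = None
    mqrs: float | None = None
    fs: float | None = None
    vqsr_pass: bool = True
    is_indel: bool = False


@dataclass
class Annotation:
    gene: str = ""
    effect: str = "unknown"
    polyphen_humdiv: str = "unknown"


@dataclass
class ExternalFlags:
    in_evs: bool = False
    in_exac: bool = False
    on_artifact_list: bool = False
    problematic: bool = False  # flagged as problematic by EVS/ExAC


@dataclass
class VariantRecord:
    """One biallelic alt allele (multiallelics are decomposed upstream)."""

    chrom: str
    pos: int  # 1-based, as in the VCF
    ref: str
    alt: str
    site_stats: SiteStats = field(default_factory=SiteStats)
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    annotation: Annotation = field(default_factory=Annotation)
    external_flags: ExternalFlags = field(default_factory=ExternalFlags)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    def genotype(self, sample_id: str) -> Genotype:
        return self.genotypes.get(sample_id, _HOM_REF_GT)

    def carriers(self) -> list[str]:
        """Samples with at least one alternate allele."""
        return [s for s, g in self.genotypes.items() if g.call in (HET, HOM_ALT)]


class SampleManifest:
    """Sample IDs, case/control labels and mean CCDS coverage.

    Backed by a pandas DataFrame with columns
    ``sample_id, phenotype, mean_ccds_coverage, qc_flags``.
    """

    PHENOTYPES = ("case", "control")

    def __init__(self, frame: pd.DataFrame):
        required = {"sample_id", "phenotype"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        frame = frame.copy()
        if "mean_ccds_coverage" not in frame.columns:
            frame["mean_ccds_coverage"] = np.nan
        if "qc_flags" not in frame.columns:
            frame["qc_flags"] = ""
        if frame["sample_id"].duplicated().any():
            dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample_id(s): {sorted(set(dups))}")
        bad = ~frame["phenotype"].isin(self.PHENOTYPES)
        if bad.any():
            raise ValueError(
                f"phenotype must be case/control, got {set(frame.loc[bad, 'phenotype'])}"
            )
        self.frame = frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def case_ids(self) -> list[str]:
        f = self.frame
        return f.loc[f["phenotype"] == "case", "sample_id"].tolist()

    @property
    def control_ids(self) -> list[str]:
        f = self.frame
        return f.loc[f["phenotype"] == "control", "sample_id"].tolist()

    @property
    def n_cases(self) -> int:
        return int((self.frame["phenotype"] == "case").sum())

    @property
    def n_controls(self) -> int:
        return int((self.frame["phenotype"] == "control").sum())

    def phenotype_vector(self, sample_ids: list[str] | None = None) -> np.ndarray:
        """Binary labels (1 = case) in the order of ``sample_ids``."""
        ids = sample_ids if sample_ids is not None else self.sample_ids
        lut = dict(zip(self.frame["sample_id"], self.frame["phenotype"]))
        return np.array([1 if lut[s] == "case" else 0 for s in ids], dtype=np.int8)

    def subset(self, sample_ids) -> "SampleManifest":
        keep = self.frame["sample_id"].isin(set(sample_ids))
        return SampleManifest(self.frame.loc[keep])

    def coverage_of(self, sample_id: str) -> float:
        f = self.frame
        return float(
            f.loc[f["sample_id"] == sample_id, "mean_ccds_coverage"].iloc[0]
        )

    @classmethod
    def from_tsv(cls, path) -> "SampleManifest":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.frame)


class RegionSet:
    """Sorted, merged half-open 0-based intervals with fast point lookup."""

    def __init__(self, intervals):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self.intervals: list[tuple[str, int, int]] = []
        for chrom in sorted(by_chrom):
            merged: list[list[int]] = []
            for s, e in sorted(by_chrom[chrom]):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = np.array([m[0] for m in merged])
            self._ends[chrom] = np.array([m[1] for m in merged])
            self.intervals.extend((chrom, m[0], m[1]) for m in merged)

    def contains(self, chrom: str, pos_1based: int) -> bool:
        starts = self._starts.get(chrom)
        if starts is None:
            return False
        p = pos_1based - 1
        i = int(np.searchsorted(starts, p, side="right")) - 1
        return i >= 0 and p < self._ends[chrom][i]

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                rows.append((chrom, int(start), int(end)))
        return cls(rows)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# variant reading


def _site_stats_from_cyvcf2(v, alt_idx: int) -> SiteStats:
    def info(tag):
        val = v.INFO.get(tag)
        if val is None:
            return None
        if isinstance(val, tuple):
            val = val[alt_idx] if alt_idx < len(val) else val[0]
        try:
            return float(val)
        except (TypeError, ValueError):
            return None

    alt = v.ALT[alt_idx]
    return SiteStats(
        qual=None if v.QUAL is None else float(v.QUAL),
        qd=info("QD"),
        mq=info("MQ"),
        rprs=info("ReadPosRankSum"),
        mqrs=info("MQRankSum"),
        fs=info("FS"),
        vqsr_pass=v.FILTER is None or v.FILTER == "PASS",
        is_indel=len(v.REF) != len(alt),
    )


def read_variants(
    vcf_path,
    annotation_path=None,
    flags_path=None,
) -> list[VariantRecord]:
    """Read a VCF plus annotation/flag side tables into `VariantRecord`s.

    Multiallelic sites are decomposed into one record per alt allele;
    genotypes not involving that alt count as hom_ref.  The annotation and
    flags tables are keyed by (chrom, pos, ref, alt); rows for variants
    absent from the VCF are reported as unmatched.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)

    ann = _read_annotation(annotation_path) if annotation_path else {}
    flags = _read_flags(flags_path) if flags_path else {}

    records: list[VariantRecord] = []
    for v in vcf:
        fmt_fields = set(v.FORMAT)
        for req in ("GT", "DP", "GQ", "AD"):
            if req not in fmt_fields:
                raise ValueError(
                    f"required FORMAT field {req} missing at {v.CHROM}:{v.POS}"
                )
        depth = np.asarray(v.format("DP")).reshape(len(samples), -1)[:, 0]
        gq = np.asarray(v.format("GQ")).reshape(len(samples), -1)[:, 0]
        ad = np.asarray(v.format("AD")).reshape(len(samples), -1)
        gt = v.genotypes  # [allele_a, allele_b, phased] per sample
        for alt_idx, alt in enumerate(v.ALT):
            alt_code = alt_idx + 1
            genos: dict[str, Genotype] = {}
            for si, sample in enumerate(samples):
                a, b = gt[si][0], gt[si][1]
                if a < 0 or b < 0:
                    genos[sample] = Genotype(MISSING)
                    continue
                n_alt = int(a == alt_code) + int(b == alt_code)
                if n_alt == 0:
                    continue  # hom_ref w.r.t. this alt: sparse default
                call = HET if n_alt == 1 else HOM_ALT
                dp = int(depth[si]) if depth[si] >= 0 else 0
                alt_reads = int(ad[si][alt_code]) if ad[si][alt_code] >= 0 else 0
                genos[sample] = Genotype(
                    call,
                    depth=max(dp, alt_reads),
                    gq=float(gq[si]) if gq[si] >= 0 else 0.0,
                    alt_reads=alt_reads,
                )
            key = (v.CHROM, v.POS, v.REF, alt)
            record = VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=alt,
                site_stats=_site_stats_from_cyvcf2(v, alt_idx),
                genotypes=genos,
                annotation=ann.pop(key, Annotation()),
                external_flags=flags.pop(key, ExternalFlags()),
            )
            if record.annotation.effect == "unknown" and annotation_path:
                logger.warning("no annotation for %s:%s %s>%s", *key)
            records.append(record)

    for key in ann:
        logger.warning("annotation row with no VCF variant: %s", key)
    return records


def _read_annotation(path) -> dict[tuple, Annotation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = {}
    for row in df.itertuples(index=False):
        effect = str(row.effect)
        if effect not in KNOWN_EFFECTS:
            logger.warning("unknown effect %r at %s:%s; set to unknown",
                           effect, row.chrom, row.pos)
            effect = "unknown"
        polyphen = getattr(row, "polyphen", "unknown")
        if pd.isna(polyphen) or polyphen not in POLYPHEN_LEVELS:
            polyphen = "unknown"
        out[(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))] = Annotation(
            gene=str(row.gene), effect=effect, polyphen_humdiv=str(polyphen)
        )
    return out


def _read_flags(path) -> dict[tuple, ExternalFlags]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = {}
    for row in df.itertuples(index=False):
        out[(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))] = ExternalFlags(
            in_evs=bool(row.in_evs),
            in_exac=bool(row.in_exac),
            on_artifact_list=bool(row.artifact),
            problematic=bool(getattr(row, "problematic", False)),
        )
    return out


def restrict_to_regions(
    variants: list[VariantRecord], regions: RegionSet
) -> list[VariantRecord]:
    """Keep only variants whose position falls inside the region set."""
    if len(regions) == 0:
        raise ValueError("empty region set")
    kept = [v for v in variants if regions.contains(v.chrom, v.pos)]
    logger.info("region restriction removed %d of %d variants",
                len(variants) - len(kept), len(variants))
    return kept


# ---------------------------------------------------------------------------
# coverage


class CoverageTable:
    """Answers whether a sample reached >=10x at a site.

    Two backends: per-sample BED intervals of covered regions, or an
    explicit per-site record of which samples are *not* covered (used for
    dense tables and by the simulator, where most samples are covered at
    most sites).  Sites unknown to a site-backed table are uncovered.
    """

    def __init__(self, sample_ids: list[str]):
        self.sample_ids = list(sample_ids)
        self._index = {s: i for i, s in enumerate(self.sample_ids)}
        self._trees: dict[tuple[str, str], IntervalTree] | None = None
        self._uncovered: dict[tuple[str, int], np.ndarray] | None = None

    # -- constructors -------------------------------------------------
    @classmethod
    def from_bed(cls, path, sample_ids: list[str]) -> "CoverageTable":
        """BED with a 4th column naming the sample the interval belongs to."""
        table = cls(sample_ids)
        table._trees = {}
        known = set(sample_ids)
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                chrom, start, end, sample = line.split("\t")[:4]
                if sample not in known:
                    raise ValueError(f"coverage sample {sample!r} not in manifest")
                tree = table._trees.setdefault((sample, chrom), IntervalTree())
                tree.addi(int(start), int(end))
        return table

    @classmethod
    def from_site_table(cls, path, sample_ids: list[str]) -> "CoverageTable":
        """Dense TSV: chrom, pos, then one 0/1 column per sample."""
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        file_samples = [c for c in df.columns if c not in ("chrom", "pos")]
        unknown = set(file_samples) - set(sample_ids)
        if unknown:
            raise ValueError(f"coverage sample(s) {sorted(unknown)} not in manifest")
        table = cls(sample_ids)
        table._uncovered = {}
        vals = df[file_samples].to_numpy()
        # samples absent from the file are uncovered everywhere
        absent = np.array(
            [table._index[s] for s in sample_ids if s not in set(file_samples)],
            dtype=np.int64,
        )
        col_idx = np.array([table._index[s] for s in file_samples], dtype=np.int64)
        for i, row in enumerate(df.itertuples(index=False)):
            zero = col_idx[vals[i] == 0]
            table._uncovered[(str(row.chrom), int(row.pos))] = np.sort(
                np.concatenate([zero, absent])
            )
        return table

    @classmethod
    def from_uncovered_sets(
        cls, uncovered: dict[tuple[str, int], np.ndarray], sample_ids: list[str]
    ) -> "CoverageTable":
        table = cls(sample_ids)
        table._uncovered = {
            k: np.asarray(v, dtype=np.int64) for k, v in uncovered.items()
        }
        return table

    # -- queries ------------------------------------------------------
    def covered(self, chrom: str, pos_1based: int, sample_id: str) -> bool:
        if self._trees is not None:
            tree = self._trees.get((sample_id, chrom))
            return bool(tree is not None and tree.overlaps_point(pos_1based - 1))
        unc = self._uncovered.get((chrom, pos_1based))
        if unc is None:
            return False  # site not recorded: uncovered
        return self._index[sample_id] not in unc

    def covered_count(self, chrom: str, pos_1based: int, sample_ids) -> int:
        """How many of ``sample_ids`` reached >=10x at this site."""
        if self._trees is not None:
            return sum(
                self.covered(chrom, pos_1based, s) for s in sample_ids
            )
        unc = self._uncovered.get((chrom, pos_1based))
        if unc is None:
            return 0
        unc_set = unc if isinstance(unc, set) else set(unc.tolist())
        return sum(self._index[s] not in unc_set for s in sample_ids)

    def to_site_table(self, path, sites) -> None:
        rows = []
        for chrom, pos in sites:
            flags = [int(self.covered(chrom, pos, s)) for s in self.sample_ids]
            rows.append([chrom, pos] + flags)
        pd.DataFrame(rows, columns=["chrom", "pos"] + self.sample_ids).to_csv(
            path, sep="\t", index=False
        )


def read_coverage(coverage_path, manifest: SampleManifest) -> CoverageTable:
    """Auto-detect the coverage dialect (BED vs dense site table)."""
    path = Path(coverage_path)
    with open(path) as fh:
        header = fh.readline()
    if header.startswith("chrom\tpos"):
        return CoverageTable.from_site_table(path, manifest.sample_ids)
    return CoverageTable.from_bed(path, manifest.sample_ids)


# ---------------------------------------------------------------------------
# writers (round-trip serialization of pipeline inputs)


def write_vcf(variants: list[VariantRecord], sample_ids: list[str], path) -> None:
    """Serialize records to a minimal VCF 4.2 with GT:DP:GQ:AD genotypes."""
    chrom_order = {c: i for i, c in enumerate(
        dict.fromkeys(v.chrom for v in variants))}
    variants = sorted(variants, key=lambda v: (chrom_order[v.chrom], v.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chrom_order:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="QualByDepth">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="MappingQuality">\n')
        fh.write('##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="RPRS">\n')
        fh.write('##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="MQRS">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="FisherStrand">\n')
        fh.write('##FILTER=<ID=VQSRTrancheFail,Description="failed VQSR">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GenotypeQual">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AlleleDepths">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for v in variants:
            st = v.site_stats
            info = []
            for tag, val in (
                ("QD", st.qd), ("MQ", st.mq), ("ReadPosRankSum", st.rprs),
                ("MQRankSum", st.mqrs), ("FS", st.fs),
            ):
                if val is not None:
                    info.append(f"{tag}={val:g}")
            cols = [
                v.chrom, str(v.pos), ".", v.ref, v.alt,
                "." if st.qual is None else f"{st.qual:g}",
                "PASS" if st.vqsr_pass else "VQSRTrancheFail",
                ";".join(info) or ".",
                "GT:DP:GQ:AD",
            ]
            for s in sample_ids:
                g = v.genotype(s)
                if g.call == MISSING:
                    cols.append("./.:.:.:.")
                    continue
                gt = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1"}[g.call]
                ref_reads = max(g.depth - g.alt_reads, 0)
                cols.append(
                    f"{gt}:{g.depth}:{int(g.gq)}:{ref_reads},{g.alt_reads}"
                )
            fh.write("\t".join(cols) + "\n")


def write_annotation(variants: list[VariantRecord], path) -> None:
    rows = [
        {
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "gene": v.annotation.gene, "effect": v.annotation.effect,
            "polyphen": v.annotation.polyphen_humdiv,
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_flags(variants: list[VariantRecord], path) -> None:
    rows = [
        {
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "in_evs": int(v.external_flags.in_evs),
            "in_exac": int(v.external_flags.in_exac),
            "artifact": int(v.external_flags.on_artifact_list),
            "problematic": int(v.external_flags.problematic),
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
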