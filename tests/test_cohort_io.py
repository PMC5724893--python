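"""Readers, writers and coordinate conventions for the cohort inputs."""

import numpy as np
import pandas as pd
import pytest

from rarecollapse import (
    RegionSet,
    SampleManifest,
    read_coverage,
    read_variants,
    restrict_to_regions,
)
from rarecollapse.cohort_io import (
    CoverageTable,
    VariantRecord,
    write_annotation,
    write_flags,
    write_vcf,
)
from rarecollapse.synthetic_cohort import write_cohort


class TestSampleManifest:
    def test_roundtrip(self, tmp_path):
        m = SampleManifest(pd.DataFrame({
            "sample_id": ["A", "B"],
            "phenotype": ["case", "control"],
            "mean_ccds_coverage": [0.93, 0.95],
        }))
        m.to_tsv(tmp_path / "m.tsv")
        back = SampleManifest.from_tsv(tmp_path / "m.tsv")
        assert back.case_ids == ["A"]
        assert back.n_controls == 1
        assert np.array_equal(back.phenotype_vector(), [1, 0])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SampleManifest(pd.DataFrame({
                "sample_id": ["A", "A"], "phenotype": ["case", "control"],
            }))

    def test_bad_phenotype_rejected(self):
        with pytest.raises(ValueError, match="phenotype"):
            SampleManifest(pd.DataFrame({
                "sample_id": ["A"], "phenotype": ["affected"],
            }))


class TestRegionSet:
    def test_point_membership_is_half_open(self):
        rs = RegionSet([("1", 95, 105)])
        assert rs.contains("1", 100)  # inside
        assert rs.contains("1", 96)  # first covered base (0-based start 95)
        assert rs.contains("1", 105)  # last covered base
        assert not rs.contains("1", 106)  # half-open end
        assert not rs.contains("2", 100)

    def test_merge_overlapping(self):
        rs = RegionSet([("1", 10, 20), ("1", 15, 30), ("1", 40, 50)])
        assert rs.intervals == [("1", 10, 30), ("1", 40, 50)]

    def test_restriction_boundary_and_idempotence(self):
        # exon [100, 200) with 2 bp extensions -> [98, 202)
        rs = RegionSet([("1", 98, 202)])
        inside = VariantRecord("1", 100, "A", "T")
        edge = VariantRecord("1", 202, "A", "T")  # last included base
        outside = VariantRecord("1", 205, "A", "T")  # 3 bp past the exon
        kept = restrict_to_regions([inside, edge, outside], rs)
        assert [v.pos for v in kept] == [100, 202]
        assert restrict_to_regions(kept, rs) == kept  # idempotent

    def test_identity_when_all_inside(self):
        rs = RegionSet([("1", 0, 10_000)])
        vs = [VariantRecord("1", p, "A", "T") for p in (5, 50, 500)]
        assert restrict_to_regions(vs, rs) == vs

    def test_empty_region_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            restrict_to_regions([VariantRecord("1", 1, "A", "T")], RegionSet([]))


class TestVcfReading:
    def _write(self, tmp_path, body, samples=("S1", "S2")):
        path = tmp_path / "t.vcf"
        header = (
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##INFO=<ID=QD,Number=1,Type=Float,Description="x">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">\n'
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="x">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="x">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        path.write_text(header + body)
        return path

    def test_field_mapping(self, tmp_path):
        path = self._write(
            tmp_path,
            "1\t100\t.\tA\tT\t50\tPASS\tQD=12\tGT:DP:GQ:AD\t"
            "0/1:10:99:3,7\t0/0:20:99:20,0\n",
        )
        (rec,) = read_variants(path)
        g = rec.genotype("S1")
        assert (g.call, g.depth, g.alt_reads, g.gq) == ("het", 10, 7, 99.0)
        assert rec.genotype("S2").call == "hom_ref"
        assert rec.site_stats.qd == 12.0
        assert rec.site_stats.vqsr_pass

    def test_multiallelic_decomposition(self, tmp_path):
        path = self._write(
            tmp_path,
            "1\t100\t.\tA\tC,T\t50\tPASS\t.\tGT:DP:GQ:AD\t"
            "0/1:12:99:6,6,0\t1/2:14:99:0,7,7\n",
        )
        recs = read_variants(path)
        assert [(r.pos, r.alt) for r in recs] == [(100, "C"), (100, "T")]
        r_c, r_t = recs
        # S1 carries the C allele only; counts as hom_ref for the T record
        assert r_c.genotype("S1").call == "het"
        assert r_t.genotype("S1").call == "hom_ref"
        # S2 is het for both alts
        assert r_c.genotype("S2").call == "het"
        assert r_t.genotype("S2").call == "het"
        assert r_t.genotype("S2").alt_reads == 7

    def test_missing_format_field_is_hard_error(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\t.\tA\tT\t50\tPASS\t.\tGT\t0/1\n"
        )
        with pytest.raises(ValueError, match="DP"):
            read_variants(path)

    def test_unannotated_variant_kept_with_unknown_effect(self, tmp_path):
        vcf = self._write(
            tmp_path,
            "1\t100\t.\tA\tT\t50\tPASS\t.\tGT:DP:GQ:AD\t"
            "0/1:10:99:3,7\t0/0:20:99:20,0\n",
        )
        ann = tmp_path / "ann.tsv"
        ann.write_text("chrom\tpos\tref\talt\tgene\teffect\tpolyphen\n"
                       "1\t999\tG\tC\tGENE1\tmissense\tbenign\n")
        (rec,) = read_variants(vcf, annotation_path=ann)
        assert rec.annotation.effect == "unknown"


class TestRoundTrip:
    def test_vcf_roundtrip_preserves_calls_and_stats(self, tmp_path, small_cohort):
        variants = small_cohort.variants[:40]
        ids = small_cohort.sample_ids
        write_vcf(variants, ids, tmp_path / "c.vcf")
        write_annotation(variants, tmp_path / "ann.tsv")
        write_flags(variants, tmp_path / "fl.tsv")
        back = read_variants(tmp_path / "c.vcf", tmp_path / "ann.tsv",
                             tmp_path / "fl.tsv")
        assert len(back) == len(variants)
        orig = {v.key: v for v in variants}
        for v in back:
            o = orig[v.key]
            assert sorted(v.carriers()) == sorted(o.carriers())
            for s in o.carriers():
                assert v.genotype(s).call == o.genotype(s).call
            assert v.site_stats.qual == pytest.approx(o.site_stats.qual)
            assert v.site_stats.mq == pytest.approx(o.site_stats.mq)
            assert v.annotation.effect == o.annotation.effect
            assert v.external_flags.in_exac == o.external_flags.in_exac


class TestCoverage:
    def test_bed_interval_semantics(self, tmp_path):
        bed = tmp_path / "cov.bed"
        bed.write_text("chr1\t100\t200\tS1\n")
        m = SampleManifest(pd.DataFrame({
            "sample_id": ["S1", "S2"], "phenotype": ["case", "control"],
        }))
        cov = read_coverage(bed, m)
        assert cov.covered("chr1", 150, "S1")
        assert cov.covered("chr1", 101, "S1")  # first base of [100,200)
        assert not cov.covered("chr1", 250, "S1")  # outside all intervals
        assert not cov.covered("chr1", 150, "S2")  # no intervals for S2

    def test_bed_and_dense_dialects_agree(self, tmp_path, rng):
        samples = [f"S{i}" for i in range(6)]
        sites = [("1", p) for p in range(10, 40, 3)]
        covered = rng.random((len(sites), len(samples))) < 0.7
        # dense dialect
        dense = tmp_path / "dense.tsv"
        pd.DataFrame(
            [[c, p] + list(covered[i].astype(int))
             for i, (c, p) in enumerate(sites)],
            columns=["chrom", "pos"] + samples,
        ).to_csv(dense, sep="\t", index=False)
        # BED dialect: one single-base interval per covered (site, sample)
        bed = tmp_path / "cov.bed"
        with open(bed, "w") as fh:
            for i, (c, p) in enumerate(sites):
                for j, s in enumerate(samples):
                    if covered[i, j]:
                        fh.write(f"{c}\t{p - 1}\t{p}\t{s}\n")
        m = SampleManifest(pd.DataFrame({
            "sample_id": samples,
            "phenotype": ["case"] * 3 + ["control"] * 3,
        }))
        cov_a = read_coverage(dense, m)
        cov_b = read_coverage(bed, m)
        for c, p in sites:
            for s in samples:
                assert cov_a.covered(c, p, s) == cov_b.covered(c, p, s)

    def test_unknown_sample_in_coverage_is_hard_error(self, tmp_path):
        bed = tmp_path / "cov.bed"
        bed.write_text("chr1\t100\t200\tGHOST\n")
        m = SampleManifest(pd.DataFrame({
            "sample_id": ["S1"], "phenotype": ["case"],
        }))
        with pytest.raises(ValueError, match="GHOST"):
            read_coverage(bed, m)


def test_full_cohort_serialization_roundtrip(tmp_path):
    """The simulator writes exactly the formats the readers consume."""
    from rarecollapse import SimulationConfig, simulate_cohort

    cohort = simulate_cohort(SimulationConfig(
        n_cases=10, n_controls=30, n_genes=5, n_panel_snps=50,
        related_pairs=[], n_outliers=0, seed=1,
    ))
    paths = write_cohort(cohort, tmp_path)
    variants = read_variants(paths["vcf"], paths["annotation"], paths["flags"])
    manifest = SampleManifest.from_tsv(paths["manifest"])
    coverage = read_coverage(paths["coverage"], manifest)
    assert len(variants) == len(cohort.variants)
    assert manifest.sample_ids == cohort.sample_ids
    for v in cohort.variants[:20]:
        for s in cohort.sample_ids[:10]:
            assert (coverage.covered(v.chrom, v.pos, s)
                    == cohort.coverage.covered(v.chrom, v.pos, s))
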