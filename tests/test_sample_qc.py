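"""Kinship, relatedness pruning, LD pruning, and iterative PCA."""

import numpy as np
import pandas as pd
import pytest

from rarecollapse import (
    SampleManifest,
    kinship_estimate,
    ld_prune,
    pca_outlier_removal,
    prune_related,
    run_sample_qc,
)


def manifest_of(ids, phenos, coverage=None):
    return SampleManifest(pd.DataFrame({
        "sample_id": ids,
        "phenotype": phenos,
        "mean_ccds_coverage": coverage if coverage is not None
        else [0.9] * len(ids),
    }))


class TestKinshipEstimate:
    def test_duplicate_pair_is_half(self, rng):
        g = rng.binomial(2, rng.uniform(0.1, 0.5, 400), size=(1, 400))
        G = np.vstack([g, g])
        kin = kinship_estimate(G, ["A", "B"])
        assert kin.phi[0, 1] == pytest.approx(0.5)
        assert kin.phi[0, 0] == pytest.approx(0.5)  # self-kinship

    def test_parent_offspring_and_unrelated_by_mendelian_oracle(self, rng):
        """Independent gamete-transmission simulation: parent-offspring
        pairs average phi ~ 0.25, unrelated pairs ~ 0, both within 0.02."""
        n_snps, n_pairs = 10_000, 20
        maf = rng.uniform(0.05, 0.5, n_snps)
        po, unrel = [], []
        for _ in range(n_pairs):
            parent = rng.binomial(2, maf)
            # transmit one allele: from a het parent a fair coin, else the
            # homozygous allele; the other gamete comes from the population
            transmitted = np.where(parent == 1,
                                   rng.integers(0, 2, n_snps), parent // 2)
            child = transmitted + rng.binomial(1, maf)
            stranger = rng.binomial(2, maf)
            kin = kinship_estimate(
                np.vstack([parent, child, stranger]), ["P", "C", "S"])
            po.append(kin.phi[0, 1])
            unrel.append(kin.phi[0, 2])
        assert np.mean(po) == pytest.approx(0.25, abs=0.02)
        assert np.mean(unrel) == pytest.approx(0.0, abs=0.02)

    def test_undefined_pair_reported_missing(self):
        # no heterozygous site in either sample: denominator zero
        G = np.array([[0, 0, 2], [0, 2, 2]])
        kin = kinship_estimate(G, ["A", "B"])
        assert np.isnan(kin.phi[0, 1])
        assert kin.pairs_above(0.1) == []  # treated as unrelated


class TestPruneRelated:
    def kin(self, ids, pairs):
        phi = np.zeros((len(ids), len(ids)))
        for a, b, v in pairs:
            i, j = ids.index(a), ids.index(b)
            phi[i, j] = phi[j, i] = v
        from rarecollapse.sample_qc import KinshipMatrix

        return KinshipMatrix(ids, phi)

    def test_case_preferred_over_control(self):
        ids = ["CASE1", "CTRL1"]
        kin = self.kin(ids, [("CASE1", "CTRL1", 0.3)])
        retained, removed = prune_related(
            kin, manifest_of(ids, ["case", "control"]))
        assert retained == ["CASE1"]
        assert removed[0]["sample_id"] == "CTRL1"

    def test_coverage_breaks_ties(self):
        ids = ["CTRL1", "CTRL2"]
        kin = self.kin(ids, [("CTRL1", "CTRL2", 0.3)])
        retained, _ = prune_related(
            kin, manifest_of(ids, ["control", "control"], [0.95, 0.90]))
        assert retained == ["CTRL1"]  # higher coverage retained

    def test_no_pairs_above_cutoff_is_identity(self):
        ids = ["A", "B", "C"]
        kin = self.kin(ids, [("A", "B", 0.05)])
        retained, removed = prune_related(
            kin, manifest_of(ids, ["case", "control", "control"]))
        assert retained == ids and removed == []

    def test_no_retained_edge_above_cutoff_exhaustive(self, rng):
        """Random relatedness graphs: the retained set never contains an
        edge above the cutoff (checked pair-exhaustively)."""
        for trial in range(10):
            n = 12
            ids = [f"S{i}" for i in range(n)]
            phi = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.2:
                        phi[i, j] = phi[j, i] = rng.uniform(0.05, 0.5)
            from rarecollapse.sample_qc import KinshipMatrix

            kin = KinshipMatrix(ids, phi.copy())
            phenos = ["case" if rng.random() < 0.3 else "control"
                      for _ in ids]
            retained, _ = prune_related(kin, manifest_of(ids, phenos))
            idx = [ids.index(s) for s in retained]
            sub = phi[np.ix_(idx, idx)]
            assert (sub <= 0.1 + 1e-12).all()


class TestLdPrune:
    def test_perfectly_correlated_pair_keeps_one(self, rng):
        a = rng.binomial(2, 0.4, 200).astype(float)
        G = np.column_stack([a, a, rng.binomial(2, 0.4, 200)])
        kept = ld_prune(G)
        assert 0 in kept and 1 not in kept  # earlier-position SNP retained

    def test_independent_snps_mostly_retained(self, rng):
        G = rng.binomial(2, rng.uniform(0.1, 0.5, 300), size=(400, 300))
        kept = ld_prune(G)
        assert len(kept) >= 0.95 * 300

    def test_monomorphic_dropped_and_deterministic(self, rng):
        G = rng.binomial(2, 0.3, size=(100, 50)).astype(float)
        G[:, 7] = 2.0  # monomorphic
        kept1, kept2 = ld_prune(G), ld_prune(G)
        assert 7 not in kept1
        assert np.array_equal(kept1, kept2)


class TestPcaOutlierRemoval:
    def _population(self, rng, n, n_snps=400, freqs=None):
        freqs = rng.uniform(0.1, 0.5, n_snps) if freqs is None else freqs
        return rng.binomial(2, freqs, size=(n, len(freqs))).astype(np.int8), freqs

    def test_homogeneous_population_no_removals(self, rng):
        G, _ = self._population(rng, 300)
        res = pca_outlier_removal(G, [f"S{i}" for i in range(300)])
        assert len(res.sample_ids) == 300
        assert all(len(r) == 0 for r in res.removed_per_iteration)

    def test_planted_diverged_sample_removed_first_iteration(self, rng):
        # two mildly diverged subpopulations plus one sample from a
        # strongly diverged population; only the latter crosses 6 sigma
        n, n_snps, f_out = 300, 5000, 0.3
        p0 = rng.uniform(0.05, 0.5, n_snps)

        def bn(p, f):
            return rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f)

        pops = np.vstack([bn(p0, 0.05), bn(p0, 0.05), bn(p0, f_out)])
        labels = (rng.random(n) < 0.2).astype(int)
        labels[0] = 2
        G = rng.binomial(2, pops[labels]).astype(np.int8)
        ids = [f"S{i}" for i in range(n)]
        res = pca_outlier_removal(G, ids)
        assert "S0" in res.removed_per_iteration[0]
        removed_all = [s for it in res.removed_per_iteration for s in it]
        assert removed_all == ["S0"]

    def test_zero_iterations_is_identity(self, rng):
        G, _ = self._population(rng, 50, 100)
        ids = [f"S{i}" for i in range(50)]
        res = pca_outlier_removal(G, ids, iterations=0)
        assert res.sample_ids == ids

    def test_sign_convention_reproducible(self, rng):
        G, _ = self._population(rng, 100, 200)
        ids = [f"S{i}" for i in range(100)]
        a = pca_outlier_removal(G, ids)
        b = pca_outlier_removal(G.copy(), ids)
        assert np.allclose(a.coordinates, b.coordinates)
        # largest-magnitude loading positive on every PC
        for k in range(a.coordinates.shape[1]):
            j = np.argmax(np.abs(a.coordinates[:, k]))
            assert a.coordinates[j, k] > 0


def test_full_sample_qc_recovers_planted_removals(small_cohort):
    """Duplicates/parent-offspring pairs lose one member each, the planted
    PCA outlier is removed, and nobody else is touched."""
    retained, log = run_sample_qc(
        small_cohort.snp_panel, small_cohort.sample_ids, small_cohort.manifest)
    removed = set(small_cohort.sample_ids) - set(retained)
    expected_pairs = small_cohort.truth["related_pairs"]
    outliers = set(small_cohort.truth["outliers"])
    # exactly one member of each planted pair removed
    pair_removed = set()
    for pair in expected_pairs:
        inter = removed & set(pair["pair"])
        assert len(inter) == 1
        pair_removed |= inter
    assert removed == pair_removed | outliers
    # duplicate pairs show phi = 0.5 within tolerance
    kin = log["kinship"]
    ids = kin.sample_ids
    for pair in expected_pairs:
        i, j = ids.index(pair["pair"][0]), ids.index(pair["pair"][1])
        expect = 0.5 if pair["kind"] == "duplicate" else 0.25
        assert kin.phi[i, j] == pytest.approx(expect, abs=0.02)
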