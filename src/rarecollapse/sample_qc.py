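"""Sample-level QC: relatedness pruning and iterative PCA outlier removal.

Operates on a panel of common biallelic SNPs coded 0/1/2 (missing = -1),
kept separate from the rare qualifying variants used for association.

Kinship uses the within-pair robust estimator
``phi = (N_het,het - 2 N_AA,aa) / (N_het(i) + N_het(j))`` over sites
jointly typed in both samples: 0.5 for duplicates, ~0.25 for
parent-offspring, ~0 for unrelated pairs.  Relatedness above the cutoff
(default 0.1) is resolved greedily, deleting the sample with the most
remaining relatedness edges and preferring to keep cases, then the sample
with higher mean CCDS coverage, then the lexicographically smaller ID.

PCA standardizes each SNP by its allele frequency, eigendecomposes the
sample covariance, and for up to 5 iterations removes any sample lying
more than 6 standard deviations from the mean on any of the top 10
principal components, recomputing everything on the survivors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort_io import SampleManifest

logger = logging.getLogger("rarecollapse")

KINSHIP_CUTOFF = 0.1
PCA_SIGMA = 6.0
PCA_N_PCS = 10
PCA_ITERATIONS = 5
LD_R2_THRESHOLD = 0.1


@dataclass
class KinshipMatrix:
    sample_ids: list[str]
    phi: np.ndarray  # symmetric; nan where undefined

    def pairs_above(self, cutoff: float) -> list[tuple[str, str, float]]:
        n = len(self.sample_ids)
        iu = np.triu_indices(n, k=1)
        out = []
        for i, j in zip(*iu):
            v = self.phi[i, j]
            if np.isfinite(v) and v > cutoff:
                out.append((self.sample_ids[i], self.sample_ids[j], float(v)))
        return out


def kinship_estimate(
    genotypes: np.ndarray, sample_ids: list[str]
) -> KinshipMatrix:
    """Pairwise robust kinship from an (n_samples, n_snps) 0/1/2 matrix.

    Missing genotypes (< 0) are excluded pairwise.  Pairs with no jointly
    typed heterozygous site have undefined kinship: reported as NaN and
    treated as unrelated downstream (with a warning).
    """
    G = np.asarray(genotypes)
    if G.ndim != 2 or G.shape[0] != len(sample_ids):
        raise ValueError("genotypes must be (n_samples, n_snps)")
    het = (G == 1).astype(np.float64)
    hom0 = (G == 0).astype(np.float64)
    hom2 = (G == 2).astype(np.float64)
    valid = (G >= 0).astype(np.float64)

    n_hethet = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    # het count of i over sites typed in both i and j
    het_joint = het @ valid.T
    denom = het_joint + het_joint.T

    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n_hethet - 2.0 * n_opp) / denom
    undefined = denom == 0
    if undefined[np.triu_indices_from(undefined, k=1)].any():
        logger.warning(
            "kinship undefined for %d pair(s) (no joint het sites); "
            "treated as unrelated",
            int(undefined[np.triu_indices_from(undefined, k=1)].sum()),
        )
    phi[undefined] = np.nan
    np.clip(phi, -0.5, 0.5, out=phi)
    return KinshipMatrix(sample_ids=list(sample_ids), phi=phi)


def prune_related(
    kinship: KinshipMatrix,
    manifest: SampleManifest,
    cutoff: float = KINSHIP_CUTOFF,
) -> tuple[list[str], list[dict]]:
    """Greedy deletion until no retained pair has kinship above cutoff.

    Returns (retained sample IDs in original order, removal log).
    """
    ids = kinship.sample_ids
    pheno = dict(zip(manifest.frame["sample_id"], manifest.frame["phenotype"]))
    cov = dict(
        zip(manifest.frame["sample_id"], manifest.frame["mean_ccds_coverage"])
    )
    edges: dict[str, set[str]] = {s: set() for s in ids}
    for a, b, _ in kinship.pairs_above(cutoff):
        edges[a].add(b)
        edges[b].add(a)

    removed: list[dict] = []
    while True:
        active = {s: nb for s, nb in edges.items() if nb}
        if not active:
            break

        def removal_priority(s: str):
            # higher tuple = removed first
            c = cov.get(s)
            c = float(c) if c is not None and np.isfinite(float(c)) else np.nan
            return (
                len(active[s]),
                1 if pheno.get(s) == "control" else 0,
                -c if np.isfinite(c) else 0.0,
                s,
            )

        victim = max(active, key=removal_priority)
        removed.append(
            {
                "sample_id": victim,
                "phenotype": pheno.get(victim, ""),
                "n_edges": len(active[victim]),
                "partners": ",".join(sorted(active[victim])),
            }
        )
        for nb in edges.pop(victim):
            edges[nb].discard(victim)

    removed_ids = {r["sample_id"] for r in removed}
    retained = [s for s in ids if s not in removed_ids]
    logger.info("relatedness pruning removed %d of %d samples",
                len(removed), len(ids))
    return retained, removed


def ld_prune(
    genotypes: np.ndarray,
    r2_threshold: float = LD_R2_THRESHOLD,
    window: int = 50,
    step: int = 5,
) -> np.ndarray:
    """PLINK-style sliding-window LD pruning; returns retained SNP indices.

    Within each window, for every pair with genotype correlation
    r^2 > threshold the later-position SNP is dropped.  Monomorphic SNPs
    (undefined r^2) are dropped up front.
    """
    G = np.asarray(genotypes, dtype=float)
    G = np.where(G < 0, np.nan, G)
    n_snps = G.shape[1]
    col_mean = np.nanmean(G, axis=0)
    filled = np.where(np.isnan(G), col_mean, G)
    sd = filled.std(axis=0)
    keep = np.ones(n_snps, dtype=bool)
    keep[sd == 0] = False  # monomorphic

    start = 0
    while start < n_snps:
        idx = np.flatnonzero(keep[start:start + window]) + start
        if len(idx) > 1:
            block = filled[:, idx]
            r = np.corrcoef(block.T)
            r2 = r * r
            for a in range(len(idx)):
                if not keep[idx[a]]:
                    continue
                for b in range(a + 1, len(idx)):
                    if keep[idx[b]] and r2[a, b] > r2_threshold:
                        keep[idx[b]] = False  # drop the later SNP
        if start + window >= n_snps:
            break
        start += step
    return np.flatnonzero(keep)


@dataclass
class PcaResult:
    sample_ids: list[str]  # retained samples after outlier removal
    coordinates: np.ndarray  # (n_retained, n_pcs)
    eigenvalues: np.ndarray
    removed_per_iteration: list[list[str]] = field(default_factory=list)


def _pca_once(G: np.ndarray, n_pcs: int) -> tuple[np.ndarray, np.ndarray]:
    Gf = np.asarray(G, dtype=float)
    Gf = np.where(Gf < 0, np.nan, Gf)
    p_hat = np.nanmean(Gf, axis=0) / 2.0
    usable = (p_hat > 0) & (p_hat < 1)
    Gf = Gf[:, usable]
    p_hat = p_hat[usable]
    Z = (Gf - 2.0 * p_hat) / np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    Z = np.where(np.isnan(Z), 0.0, Z)
    cov = (Z @ Z.T) / Z.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:n_pcs]
    vals = vals[order]
    vecs = vecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for k in range(vecs.shape[1]):
        j = np.argmax(np.abs(vecs[:, k]))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    return vecs, vals


def pca_outlier_removal(
    genotypes: np.ndarray,
    sample_ids: list[str],
    n_pcs: int = PCA_N_PCS,
    sigma: float = PCA_SIGMA,
    iterations: int = PCA_ITERATIONS,
) -> PcaResult:
    """EIGENSTRAT-style iterative outlier removal on the top PCs."""
    G = np.asarray(genotypes)
    retained = np.arange(G.shape[0])
    removed_log: list[list[str]] = []
    vecs = np.zeros((G.shape[0], 0))
    vals = np.zeros(0)
    for _ in range(iterations):
        if len(retained) <= n_pcs + 1:
            break
        vecs, vals = _pca_once(G[retained], n_pcs)
        k_eff = vecs.shape[1]
        mean = vecs.mean(axis=0)
        sd = vecs.std(axis=0)
        sd[sd == 0] = np.inf
        z = np.abs(vecs - mean) / sd
        outlier = (z > sigma).any(axis=1)
        if not outlier.any():
            removed_log.append([])
            break
        removed_log.append([sample_ids[i] for i in retained[outlier]])
        retained = retained[~outlier]
    if iterations > 0 and len(retained) > n_pcs + 1:
        vecs, vals = _pca_once(G[retained], n_pcs)
    elif iterations == 0:
        vecs, vals = _pca_once(G[retained], n_pcs)
    return PcaResult(
        sample_ids=[sample_ids[i] for i in retained],
        coordinates=vecs,
        eigenvalues=vals,
        removed_per_iteration=removed_log,
    )


def run_sample_qc(
    genotypes: np.ndarray,
    sample_ids: list[str],
    manifest: SampleManifest,
    kinship_cutoff: float = KINSHIP_CUTOFF,
    r2_threshold: float = LD_R2_THRESHOLD,
    n_pcs: int = PCA_N_PCS,
    sigma: float = PCA_SIGMA,
    iterations: int = PCA_ITERATIONS,
) -> tuple[list[str], dict]:
    """Kinship pruning then LD-pruned iterative PCA; returns retained IDs.

    The second element is a log dict with the kinship matrix, removal
    records and the final `PcaResult`.
    """
    kin = kinship_estimate(genotypes, sample_ids)
    retained_ids, removal_log = prune_related(kin, manifest, kinship_cutoff)
    idx = [sample_ids.index(s) for s in retained_ids]
    G = np.asarray(genotypes)[idx]
    snp_idx = ld_prune(G, r2_threshold=r2_threshold)
    logger.info("LD pruning retained %d of %d panel SNPs",
                len(snp_idx), G.shape[1])
    pca = pca_outlier_removal(
        G[:, snp_idx], retained_ids, n_pcs=n_pcs, sigma=sigma,
        iterations=iterations,
    )
    return pca.sample_ids, {
        "kinship": kin,
        "related_removed": removal_log,
        "ld_retained_snps": snp_idx,
        "pca": pca,
    }
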