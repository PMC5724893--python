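"""Known-gene rank enrichment.

Given the genome-wide ranking of genes by association p-value and a fixed
set of K known disease genes among the N genes tested, the question "are
there surprisingly many known genes at or above rank r?" is answered by
the upper tail of the hypergeometric distribution: the number of known
genes among r draws without replacement from an urn with K known and
N - K other genes.

A second, coarser summary tests whether the fraction of known genes that
reach nominal significance (p < 0.05) exceeds the genome-wide fraction,
by a two-tailed Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .association import fisher_two_tailed

logger = logging.getLogger("rarecollapse")


def hypergeom_upper_tail(x: int, r: int, K: int, N: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N population, K marked, r draws).

    Evaluated by log-space summation of point masses for stability at the
    very small tail probabilities a genome-wide ranking produces.
    """
    if not (0 <= x <= min(r, K) <= N) or r > N or K > N:
        raise ValueError(f"invalid hypergeometric bounds x={x} r={r} K={K} N={N}")
    if x == 0:
        return 1.0
    ks = np.arange(x, min(r, K) + 1)
    logp = stats.hypergeom.logpmf(ks, N, K, r)
    return min(1.0, float(np.exp(logsumexp(logp))))


@dataclass
class RankEnrichment:
    gene: str
    rank: int
    n_known_at_or_above: int
    hypergeom_p: float


def rank_scan(
    results: pd.DataFrame,
    known_genes,
    N: int | None = None,
    K: int | None = None,
) -> list[RankEnrichment]:
    """Hypergeometric tail at each known gene's observed ranking.

    ``results`` must contain ``gene`` and the ranking p-value column
    ``firth_p`` (falling back to ``fisher_p``).  Ties share the best
    (smallest) rank among the tied genes.  Known genes absent from the
    results are logged and skipped.
    """
    pcol = "firth_p" if "firth_p" in results.columns else "fisher_p"
    df = results[["gene", pcol]].copy()
    present = set(df["gene"])
    known = [g for g in known_genes if g in present]
    absent = [g for g in known_genes if g not in present]
    for g in absent:
        logger.warning("known gene %s absent from results; excluded from scan", g)

    N = N if N is not None else len(df)
    K = K if K is not None else len(known)
    p = df.set_index("gene")[pcol]
    # best rank among ties: 1 + number of genes with strictly smaller p
    sorted_p = np.sort(p.to_numpy())
    out = []
    known_ranks = sorted(
        (int(np.searchsorted(sorted_p, p[g], side="left")) + 1, g)
        for g in known
    )
    for j, (rank, gene) in enumerate(known_ranks, start=1):
        out.append(
            RankEnrichment(
                gene=gene,
                rank=rank,
                n_known_at_or_above=j,
                hypergeom_p=hypergeom_upper_tail(j, rank, K, N),
            )
        )
    return out


def rank_scan_table(scan: list[RankEnrichment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": e.gene,
                "rank": e.rank,
                "n_known_at_or_above": e.n_known_at_or_above,
                "hypergeom_p": e.hypergeom_p,
            }
            for e in scan
        ]
    )


def nominal_enrichment(
    known_nominal: int,
    known_total: int,
    all_nominal: int,
    all_total: int,
) -> float:
    """Fisher p: nominal-significance rate in the known set vs the rest."""
    a = known_nominal
    b = known_total - known_nominal
    c = all_nominal - known_nominal
    d = (all_total - known_total) - c
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent counts for nominal enrichment")
    return fisher_two_tailed(a, b, c, d)
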