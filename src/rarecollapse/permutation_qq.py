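"""Permutation-based expected p-value distributions, QQ bands, and lambda.

Simple permutation reshuffles case/control labels uniformly with the case
count fixed.  When the association test adjusts for a confounder (the
ultra-rare synonymous count), uniform reshuffling would destroy the
confounding structure that motivates the adjustment; instead, permuted
case sets are drawn from the multivariate Fisher noncentral hypergeometric
distribution — a weighted urn whose per-sample odds come from a logistic
fit of phenotype on the covariate.  This keeps the covariate's
relationship with the (permuted) phenotype while breaking any
genotype-phenotype association.

For each of ``n_perm`` permutations the gene-wise p-values are recomputed
and sorted; the per-rank mean across permutations gives the expected
order statistics and the per-rank 2.5/97.5 percentiles a 95% band.

The genomic inflation factor is the median-based 1-df definition:
lambda = median(qchisq(1 - p, 1)) / qchisq(0.5, 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .association import logistic_fit

logger = logging.getLogger("rarecollapse")

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))  # 0.4549...


def permute_simple(
    n_samples: int, n_cases: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniformly random case labeling with the case count fixed."""
    if not 0 < n_cases < n_samples:
        raise ValueError("need 0 < n_cases < n_samples")
    y = np.zeros(n_samples, dtype=np.int8)
    y[rng.choice(n_samples, size=n_cases, replace=False)] = 1
    return y


@dataclass
class UrnWeights:
    weights: np.ndarray  # per-sample odds, geometric mean 1
    gamma: float  # fitted covariate coefficient
    used_firth: bool = False


def urn_weights(y: np.ndarray, z: np.ndarray) -> UrnWeights:
    """Per-sample urn odds from a logistic fit of phenotype on covariate.

    w_i = exp(alpha + gamma z_i), rescaled to geometric mean 1.  If the
    plain fit fails (separation in the confounder), a Firth fit supplies
    the weights instead.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    X = np.column_stack([np.ones_like(z), z])
    used_firth = False
    if z.min() == z.max():
        return UrnWeights(weights=np.ones_like(z), gamma=0.0)
    model = logistic_fit(X, y, penalized=False)
    if not model.converged or not np.all(np.isfinite(model.coefficients)):
        logger.warning("confounder fit separated; falling back to Firth weights")
        model = logistic_fit(X, y, penalized=True)
        used_firth = True
    eta = X @ model.coefficients
    w = np.exp(eta - np.mean(eta))  # rescale: geometric mean 1
    return UrnWeights(weights=w, gamma=float(model.coefficients[1]),
                      used_firth=used_firth)


def permute_weighted(
    weights: np.ndarray, n_cases: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw a case set from the multivariate Fisher noncentral
    hypergeometric distribution with the given odds.

    Sampling is exact: the target law equals independent Bernoulli draws
    with odds proportional to the weights, conditioned on the number of
    successes; we tilt the Bernoulli probabilities so the expected case
    count matches ``n_cases`` and accept-reject on the exact count.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    n = len(w)
    if not 0 < n_cases < n:
        raise ValueError("need 0 < n_cases < n_samples")

    def expected(log_alpha: float) -> float:
        p = 1.0 / (1.0 + np.exp(-(log_alpha + np.log(w))))
        return float(p.sum()) - n_cases

    lo, hi = -50.0, 50.0
    log_alpha = optimize.brentq(expected, lo, hi)
    p = 1.0 / (1.0 + np.exp(-(log_alpha + np.log(w))))
    for _ in range(200_000):
        draws = rng.random(n) < p
        if int(draws.sum()) == n_cases:
            y = np.zeros(n, dtype=np.int8)
            y[draws] = 1
            return y
    raise RuntimeError("weighted permutation did not hit the case count")


@dataclass
class PermutationEnsemble:
    n_permutations: int
    sorted_p: np.ndarray  # (n_perm, n_genes), ascending per row
    mean_order_stats: np.ndarray  # (n_genes,)
    lower: np.ndarray  # per-rank 2.5th percentile of p
    upper: np.ndarray  # per-rank 97.5th percentile of p
    seed: int | None = None

    @property
    def expected_neglog10(self) -> np.ndarray:
        return -np.log10(self.mean_order_stats)


def expected_order_statistics(
    pvalue_fn,
    permuter,
    n_perm: int = 1000,
    seed: int | None = None,
) -> PermutationEnsemble:
    """Mean rank-ordered p-values across label permutations.

    ``pvalue_fn(labels) -> array of gene p-values``;
    ``permuter(rng) -> label vector``.
    """
    if n_perm < 2:
        raise ValueError("need at least 2 permutations")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_perm):
        y = permuter(rng)
        rows.append(np.sort(np.asarray(pvalue_fn(y), dtype=float)))
    mat = np.vstack(rows)
    return PermutationEnsemble(
        n_permutations=n_perm,
        sorted_p=mat,
        mean_order_stats=mat.mean(axis=0),
        lower=np.percentile(mat, 2.5, axis=0),
        upper=np.percentile(mat, 97.5, axis=0),
        seed=seed,
    )


def qq_table(observed_p: np.ndarray, ensemble: PermutationEnsemble) -> pd.DataFrame:
    """Rank-aligned observed vs permutation-expected -log10 p, with band."""
    obs = np.sort(np.asarray(observed_p, dtype=float))
    if len(obs) != ensemble.sorted_p.shape[1]:
        raise ValueError("observed p count differs from ensemble gene count")
    with np.errstate(divide="ignore"):
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(obs) + 1),
                "observed_neglog10": -np.log10(obs),
                "expected_neglog10": -np.log10(ensemble.mean_order_stats),
                "band_lower_neglog10": -np.log10(ensemble.upper),
                "band_upper_neglog10": -np.log10(ensemble.lower),
            }
        )


def genomic_lambda(observed_p: np.ndarray) -> float:
    """Median-based genomic inflation factor on 1-df chi-square scale."""
    p = np.asarray(observed_p, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / CHI2_MEDIAN_1DF)
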