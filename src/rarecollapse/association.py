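"""Per-gene association statistics.

Two tests per gene on the dominant-model carrier indicator:

* two-tailed Fisher's exact test on the 2x2 carrier table
  [[qualifying cases, other cases], [qualifying controls, other controls]];
* Firth penalized logistic regression of case status on the gene indicator
  with the per-sample ultra-rare synonymous count as covariate, tested by
  the penalized profile likelihood ratio referred to chi-square(1).

Firth's correction maximizes l(b) + 1/2 log|I(b)| (a Jeffreys prior
penalty), which keeps estimates finite under complete separation — the
norm rather than the exception when carrier counts are in the single
digits.  Newton iterations use the standard hat-value-adjusted score
U*(b) = X'(y - p + h(1/2 - p)) with step-halving on the penalized
log-likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .collapsing import CollapsingMatrix

logger = logging.getLogger("rarecollapse")


# ---------------------------------------------------------------------------
# Fisher's exact test


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for [[a, b], [c, d]].

    Two-sidedness is the usual "sum of small p" rule: sum the
    probabilities of all tables with the margins fixed whose point
    probability does not exceed the observed one.  A table with an empty
    margin carries no information: p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


class _FisherCache:
    """Memoized Fisher p for fixed group sizes, keyed by the carrier split.

    Under label permutation the margins (n_cases, n_controls) are fixed,
    so the p-value depends only on (case carriers, total carriers); with
    rare carriers the number of distinct keys is tiny compared to
    genes x permutations.
    """

    def __init__(self, n_cases: int, n_controls: int):
        self.n_cases = n_cases
        self.n_controls = n_controls
        self._cache: dict[tuple[int, int], float] = {}

    def p(self, case_carriers: int, total_carriers: int) -> float:
        key = (case_carriers, total_carriers)
        hit = self._cache.get(key)
        if hit is None:
            a = case_carriers
            c = total_carriers - case_carriers
            hit = fisher_two_tailed(
                a, self.n_cases - a, c, self.n_controls - c
            )
            self._cache[key] = hit
        return hit


def fisher_pvalues(
    case_carriers: np.ndarray,
    control_carriers: np.ndarray,
    n_cases: int,
    n_controls: int,
    cache: _FisherCache | None = None,
) -> np.ndarray:
    cache = cache or _FisherCache(n_cases, n_controls)
    a = np.asarray(case_carriers)
    t = a + np.asarray(control_carriers)
    return np.array([cache.p(int(ai), int(ti)) for ai, ti in zip(a, t)])


# ---------------------------------------------------------------------------
# Firth penalized logistic regression


@dataclass
class FirthModel:
    coefficients: np.ndarray  # intercept first, then model terms
    loglik_penalized: float
    converged: bool
    n_iter: int
    term_names: list[str] = field(default_factory=list)

    @property
    def beta_gene(self) -> float:
        """Coefficient of the gene-indicator term, if present."""
        return float(self.coefficients[self.term_names.index("gene")])


def _penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                      penalized: bool) -> float:
    """Log-likelihood, plus the Jeffreys penalty 1/2 log|X'WX| if asked.

    The penalty always uses the *full* design matrix, also when some
    coefficients are held fixed (profile likelihood evaluation).
    """
    eta = X @ beta
    # numerically stable log-likelihood: -sum log(1 + exp(-(2y-1) eta))
    ll = -np.sum(np.logaddexp(0.0, -np.where(y == 1, eta, -eta)))
    if not penalized:
        return float(ll)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    Xw = X * w[:, None]
    sign, logdet = np.linalg.slogdet(X.T @ Xw)
    if sign <= 0:
        return -np.inf
    return float(ll + 0.5 * logdet)


def _firth_gradient(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Exact gradient of the penalized log-likelihood: the adjusted score
    U*(b) = X'(y - p + h(1/2 - p)) with h the hat values of W^1/2 X."""
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(p * (1.0 - p), 1e-12, None)
    Xw = X * w[:, None]
    info = X.T @ Xw
    try:
        solve = np.linalg.solve(info, Xw.T)
    except np.linalg.LinAlgError:
        return X.T @ (y - p)
    h = np.einsum("ij,ji->i", X, solve)
    return X.T @ (y - p + h * (0.5 - p))


def logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    penalized: bool = True,
    max_iter: int = 100,
    tol: float = 1e-6,
    term_names: list[str] | None = None,
    free: np.ndarray | None = None,
) -> FirthModel:
    """Newton fit of (optionally Firth-penalized) logistic regression.

    ``X`` must include the intercept column.  ``free`` marks the
    coefficients allowed to move; fixed coefficients stay at zero, and the
    Jeffreys penalty keeps using the full design — this is the profile
    penalized likelihood needed by the Firth likelihood-ratio test.  With
    ``penalized=False`` this is ordinary maximum likelihood (used for the
    permutation urn's confounder fit).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    free = np.ones(k, dtype=bool) if free is None else np.asarray(free, bool)
    beta = np.zeros(k)
    if free[0]:
        beta[0] = np.log(max(y.mean(), 1e-12) / max(1.0 - y.mean(), 1e-12))
    ll = _penalized_loglik(X, y, beta, penalized)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1.0 - p), 1e-12, None)
        info = X.T @ (X * w[:, None])
        score = (_firth_gradient(X, y, beta) if penalized
                 else X.T @ (y - p))[free]
        try:
            delta = np.linalg.solve(info[np.ix_(free, free)], score)
        except np.linalg.LinAlgError:
            break
        # step-halving on the (penalized) log-likelihood
        step = 1.0
        full_delta = np.zeros(k)
        full_delta[free] = delta
        for _ in range(25):
            ll_new = _penalized_loglik(X, y, beta + step * full_delta, penalized)
            if ll_new >= ll - 1e-10:
                break
            step *= 0.5
        beta = beta + step * full_delta
        ll_prev, ll = ll, ll_new
        if np.max(np.abs(score)) < tol and np.max(np.abs(step * delta)) < tol:
            converged = True
            break
        if abs(ll - ll_prev) < 1e-12 and it > 3:
            break  # stalled short of tol; the BFGS polish takes over
    if not converged and penalized:
        # Newton uses the unpenalized information as Hessian, which can
        # oscillate near the optimum for near-degenerate gene columns;
        # polish with BFGS on the exact penalized objective (the adjusted
        # score is its exact gradient).
        from scipy import optimize

        def neg_obj(b_free):
            b = np.zeros(k)
            b[free] = b_free
            return -_penalized_loglik(X, y, b, True)

        def neg_grad(b_free):
            b = np.zeros(k)
            b[free] = b_free
            return -_firth_gradient(X, y, b)[free]

        res = optimize.minimize(neg_obj, beta[free], jac=neg_grad,
                                method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 200})
        if -res.fun >= ll:
            beta = np.zeros(k)
            beta[free] = res.x
            ll = -res.fun
        converged = bool(res.success or np.max(np.abs(res.jac)) < 1e-5)
        if not converged:
            logger.warning("Firth fit did not converge after %d iterations", it)
    return FirthModel(
        coefficients=beta,
        loglik_penalized=ll,
        converged=converged,
        n_iter=it,
        term_names=term_names or [f"x{i}" for i in range(k)],
    )


def firth_fit(
    y: np.ndarray,
    x_gene: np.ndarray,
    z_covariate: np.ndarray | None = None,
    **kwargs,
) -> FirthModel:
    """Firth fit of case status on the gene indicator (+ covariate)."""
    y = np.asarray(y)
    if y.min() == y.max():
        raise ValueError("need at least one case and one control")
    cols = [np.ones_like(y, dtype=float), np.asarray(x_gene, dtype=float)]
    names = ["intercept", "gene"]
    if z_covariate is not None:
        z = np.asarray(z_covariate, dtype=float)
        if z.min() != z.max():  # constant covariate: collinear, drop
            cols.append(z)
            names.append("syn_covariate")
    X = np.column_stack(cols)
    return logistic_fit(X, y, penalized=True, term_names=names, **kwargs)


def firth_profile_test(
    y: np.ndarray,
    x_gene: np.ndarray,
    z_covariate: np.ndarray | None = None,
) -> tuple[float, FirthModel]:
    """Penalized profile likelihood-ratio p-value for the gene term.

    The statistic is 2 (pl(b_hat) - pl_0), where pl_0 maximizes the *same*
    full-design penalized likelihood under the constraint beta_gene = 0 —
    the penalty keeps its dimension, so the ratio is chi-square(1) under
    the null.  Genes with no carriers (or all carriers) carry no
    information: p = 1.  A constant covariate is dropped (it would be
    collinear with the intercept).
    """
    x_gene = np.asarray(x_gene, dtype=float)
    if z_covariate is not None:
        z_covariate = np.asarray(z_covariate, dtype=float)
        if z_covariate.min() == z_covariate.max():
            z_covariate = None
    if x_gene.min() == x_gene.max():
        model = FirthModel(
            coefficients=np.zeros(2 if z_covariate is None else 3),
            loglik_penalized=np.nan,
            converged=True, n_iter=0,
            term_names=["intercept", "gene"]
            + ([] if z_covariate is None else ["syn_covariate"]),
        )
        return 1.0, model
    y = np.asarray(y, dtype=float)
    cols = [np.ones_like(y), x_gene]
    names = ["intercept", "gene"]
    if z_covariate is not None:
        cols.append(z_covariate)
        names.append("syn_covariate")
    X = np.column_stack(cols)
    full = logistic_fit(X, y, penalized=True, term_names=names)
    free = np.ones(X.shape[1], dtype=bool)
    free[1] = False
    null = logistic_fit(X, y, penalized=True, term_names=names, free=free)
    lr = 2.0 * (full.loglik_penalized - null.loglik_penalized)
    p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return p, full


# ---------------------------------------------------------------------------
# gene-level driver


def bonferroni_threshold(n_genes_targeted: int) -> float:
    """Genome-wide significance level 0.05 / number of genes targeted."""
    if n_genes_targeted < 1:
        raise ValueError("need at least one gene")
    return 0.05 / n_genes_targeted


def gene_results(
    matrix: CollapsingMatrix,
    y: np.ndarray,
    use_covariate: bool = True,
    run_firth: bool = True,
) -> pd.DataFrame:
    """Fisher and Firth statistics for every gene in the matrix.

    Returns a DataFrame sorted by Firth p (ties: Fisher p, then gene
    name), with 1-based ``rank_by_firth``.  Genes with zero carriers get
    p = 1 under both tests.
    """
    y = np.asarray(y)
    n_cases = int(y.sum())
    n_controls = int(len(y) - n_cases)
    a, c = matrix.carrier_counts(y)
    fisher = fisher_pvalues(a, c, n_cases, n_controls)

    z = matrix.syn_covariate if use_covariate else None
    firth_p = np.ones(len(matrix.genes))
    firth_beta = np.zeros(len(matrix.genes))
    if run_firth:
        dense = matrix.indicator
        for gi in range(len(matrix.genes)):
            x = np.asarray(dense[gi].todense()).ravel().astype(float)
            if x.max() == x.min():
                continue
            p, model = firth_profile_test(y, x, z)
            firth_p[gi] = p
            firth_beta[gi] = model.beta_gene
    else:
        firth_p = fisher.copy()

    df = pd.DataFrame(
        {
            "gene": matrix.genes,
            "qualifying_cases": a.astype(int),
            "qualifying_controls": c.astype(int),
            "case_freq": a / n_cases,
            "control_freq": c / n_controls,
            "fisher_p": fisher,
            "firth_p": firth_p if run_firth else np.nan,
            "firth_beta": firth_beta if run_firth else np.nan,
        }
    )
    sort_key = "firth_p" if run_firth else "fisher_p"
    df = df.sort_values(
        [sort_key, "fisher_p", "gene"], kind="mergesort"
    ).reset_index(drop=True)
    df["rank_by_firth"] = np.arange(1, len(df) + 1)
    return df


def aggregate_burden(
    gene_set,
    matrix: CollapsingMatrix,
    y: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Carrier burden across a gene set (union semantics) + Fisher p.

    A sample counts once if it carries a qualifying variant in *any* gene
    of the set.  Returns ([[case carriers, other cases],
    [control carriers, other controls]], two-tailed Fisher p).
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    missing = [g for g in gene_set if g not in matrix._gene_index]
    if missing:
        raise ValueError(f"gene(s) not in matrix: {missing}")
    idx = [matrix._gene_index[g] for g in gene_set]
    union = np.asarray(
        matrix.indicator[idx].max(axis=0).todense()
    ).ravel()
    y = np.asarray(y)
    a = int(union[y == 1].sum())
    c = int(union[y == 0].sum())
    n_cases = int(y.sum())
    n_controls = len(y) - n_cases
    table = np.array([[a, n_cases - a], [c, n_controls - c]])
    return table, fisher_two_tailed(a, n_cases - a, c, n_controls - c)
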