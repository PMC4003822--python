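"""Per-SNP Bayesian cluster regression: EM over a 3-component mixture
of linear regressions with a conjugate-style prior on the coefficients.

Model, per SNP with n samples: each sample i belongs to an unobserved
genotype cluster C_i in {AA, AB, BB} with mixing proportions pi, and

    y_i | C_i = k  ~  Normal(beta_k0 + beta_k1 x_i (+ CN_i beta_kCN),
                             (c_k sigma)^2)

where x_i, y_i are the centered A/B log-intensities, CN_i an optional
fixed copy-number covariate, sigma a single base error scale and
c = (2, 1, 2) the cluster error multipliers: homozygote clouds spread
about twice as wide as the heterozygote cloud.

Each cluster's coefficient vector carries a normal prior
N(beta_prior_k, sigma^2 V), V diagonal, giving the closed-form
posterior-mean update

    beta_k = (V^-1 + X'WX)^-1 (V^-1 beta_prior_k + X'Wy),

with observation weights W = diag(resp_k / c_k^2); sigma^2 is estimated
frequentist (no prior).  EM alternates responsibilities (E) and the
updates above (M), stopping when the largest parameter change drops
below ``tol`` or after 30 iterations.  A sample is genotyped by the
cluster with maximal responsibility, or NoCall when that responsibility
is below the confidence threshold (default 99.9%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .data_io import CALL_CODES, NOCALL, GenotypeCalls, IntensityDataset
from .prior_builder import PriorSpec

__all__ = [
    "EngineConfig",
    "ClusterFit",
    "bayes_posterior_mean",
    "e_step",
    "m_step",
    "em_fit",
    "call_genotypes",
    "call_dataset",
    "penalized_loglik",
]

#: cluster error multipliers c_k: homozygote spread = 2x heterozygote
SCALE_FACTORS = np.array([2.0, 1.0, 2.0])

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class EngineConfig:
    """Tunables of the EM caller.

    threshold
        Minimum posterior probability for a genotype call; below it the
        sample is NoCall.  ``0.0`` forces a 100% call rate.
    ab_weight
        Relative weight of the heterozygote cluster in the mixing-
        proportion update; < 1 counteracts the engine's tendency to
        over-assign borderline points to the (narrower) AB cluster.
    tol
        Convergence tolerance on the max absolute change of any
        parameter (beta, pi, sigma) between iterations.
    max_iter
        Hard EM iteration cap.
    min_samples_em
        Below this many samples the SNP skips EM and is classified by
        the prior lines directly.
    """

    threshold: float = 0.999
    ab_weight: float = 0.5
    tol: float = 1e-6
    max_iter: int = 30
    min_samples_em: int = 4
    hemizygous_notation: bool = False


@dataclass
class ClusterFit:
    """Fitted per-SNP mixture state."""

    beta: np.ndarray  # (3, p) coefficients, rows in prior cluster order
    sigma: float  # base error scale (AB cluster scale)
    pi: np.ndarray  # (3,) mixing proportions
    resp: np.ndarray  # (n, 3) responsibilities
    scale_factors: np.ndarray = field(default_factory=lambda: SCALE_FACTORS.copy())
    n_iter: int = 0
    converged: bool = False
    n_underflow: int = 0


def bayes_posterior_mean(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    beta_prior: np.ndarray,
    v_diag: np.ndarray,
) -> np.ndarray:
    """Posterior mean (V^-1 + X'WX)^-1 (V^-1 beta_prior + X'Wy).

    With all weights equal to one this is the textbook conjugate
    posterior mean for the prior N(beta_prior, sigma^2 V); as V^-1 -> 0
    it degenerates to (weighted) OLS, and when beta_prior equals the OLS
    solution the output is the OLS solution for any V.
    """
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any():
        raise ValueError("weights must be non-negative")
    if (weights > 0).sum() < 2:
        raise ValueError("need at least two strictly positive weights")
    if (np.asarray(v_diag) <= 0).any():
        raise ValueError("prior variances must be positive")
    Xw = X * weights[:, None]
    A = np.diag(1.0 / np.asarray(v_diag, dtype=float)) + X.T @ Xw
    b = beta_prior / v_diag + Xw.T @ y
    return np.linalg.solve(A, b)


def _design(x: np.ndarray, cn: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(x), x]
    if cn is not None:
        cols.append(cn)
    return np.column_stack(cols)


def _log_densities(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, sigma: float,
    scale_factors: np.ndarray,
) -> np.ndarray:
    """(n, 3) log Normal(y_i; X_i beta_k, (c_k sigma)^2)."""
    mu = X @ beta.T  # (n, 3)
    sd = scale_factors * sigma
    z = (y[:, None] - mu) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


def e_step(
    x: np.ndarray,
    y: np.ndarray,
    cn: np.ndarray | None,
    beta: np.ndarray,
    sigma: float,
    pi: np.ndarray,
    scale_factors: np.ndarray = SCALE_FACTORS,
) -> tuple[np.ndarray, int]:
    """Responsibilities resp_ik = E(C_ik | y, beta, sigma^2), in log space.

    Returns (resp, n_underflow); samples whose three densities all
    underflow to -inf get uniform responsibilities.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    X = _design(x, cn)
    logd = _log_densities(X, y, beta, sigma, scale_factors) + np.log(pi)
    norm_const = logsumexp(logd, axis=1, keepdims=True)
    bad = ~np.isfinite(norm_const[:, 0])
    resp = np.exp(logd - np.where(np.isfinite(norm_const), norm_const, 0.0))
    n_underflow = int(bad.sum())
    if n_underflow:
        resp[bad] = 1.0 / 3.0
    return resp, n_underflow


def m_step(
    x: np.ndarray,
    y: np.ndarray,
    cn: np.ndarray | None,
    resp: np.ndarray,
    prior: PriorSpec,
    ab_weight: float = 0.5,
    scale_factors: np.ndarray = SCALE_FACTORS,
) -> tuple[np.ndarray, float, np.ndarray]:
    """One maximization step: returns (beta, sigma, pi).

    Per cluster the coefficients come from :func:`bayes_posterior_mean`
    with observation weights resp_k / c_k^2; sigma^2 pools de-scaled
    squared residuals over all clusters; the pi update applies the
    heterozygote weight (1, ab_weight, 1).
    """
    X = _design(x, cn)
    n, p = X.shape
    beta = np.empty((3, p))
    for k in range(3):
        w = resp[:, k] / scale_factors[k] ** 2
        if resp[:, k].sum() < 1e-8 or (w > 0).sum() < 2:
            beta[k] = prior.beta_mean[k]  # empty cluster: prior dominates
        else:
            beta[k] = bayes_posterior_mean(X, y, w, prior.beta_mean[k], prior.v_diag)
    residual = y[:, None] - X @ beta.T
    sigma2 = float(np.sum(resp * residual**2 / scale_factors**2) / np.sum(resp))
    sigma = max(np.sqrt(sigma2), 1e-8)
    w_k = np.array([1.0, ab_weight, 1.0])
    pi = resp.sum(axis=0) * w_k
    pi = np.maximum(pi / pi.sum(), 1e-12)
    pi = pi / pi.sum()
    return beta, sigma, pi


def _init_sigma(x, y, cn, prior: PriorSpec) -> float:
    X = _design(x, cn)
    resid = np.abs(y[:, None] - X @ prior.beta_mean.T).min(axis=1)
    return max(1.4826 * float(np.median(resid)), 1e-3)


def em_fit(
    x: np.ndarray,
    y: np.ndarray,
    cn: np.ndarray | None,
    prior: PriorSpec,
    config: EngineConfig | None = None,
) -> ClusterFit:
    """Fit the per-SNP mixture by EM from the prior means.

    Initialization: beta at the prior means, pi at the prior
    proportions, sigma at 1.4826 x the median absolute residual from
    the nearest prior line (a robust normal-consistent scale).  The
    parameter values of the last iteration are the final estimates.
    """
    config = config or EngineConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples per SNP")
    if prior.v_diag is None:
        raise ValueError("prior variances are required for EM")
    expected_p = 3 if cn is not None else 2
    if prior.n_coef != expected_p:
        raise ValueError(
            f"prior has {prior.n_coef} coefficients but design has {expected_p}"
        )
    beta = prior.beta_mean.copy()
    pi = prior.pi.copy()
    sigma = _init_sigma(x, y, cn, prior)

    resp = np.full((len(x), 3), 1.0 / 3.0)
    n_underflow = 0
    n_iter = 0
    converged = False
    for n_iter in range(1, config.max_iter + 1):
        resp, n_uf = e_step(x, y, cn, beta, sigma, pi)
        n_underflow += n_uf
        new_beta, new_sigma, new_pi = m_step(
            x, y, cn, resp, prior, ab_weight=config.ab_weight
        )
        delta = max(
            np.abs(new_beta - beta).max(),
            np.abs(new_pi - pi).max(),
            abs(new_sigma - sigma),
        )
        beta, sigma, pi = new_beta, new_sigma, new_pi
        if not (np.isfinite(beta).all() and np.isfinite(sigma) and np.isfinite(pi).all()):
            raise FloatingPointError("non-finite parameters during EM")
        if delta < config.tol:
            converged = True
            break
    resp, n_uf = e_step(x, y, cn, beta, sigma, pi)
    n_underflow += n_uf
    return ClusterFit(
        beta=beta,
        sigma=sigma,
        pi=pi,
        resp=resp,
        n_iter=n_iter,
        converged=converged,
        n_underflow=n_underflow,
    )


def penalized_loglik(
    x: np.ndarray,
    y: np.ndarray,
    cn: np.ndarray | None,
    beta: np.ndarray,
    sigma: float,
    pi: np.ndarray,
    prior: PriorSpec,
    scale_factors: np.ndarray = SCALE_FACTORS,
) -> float:
    """Observed-data log-likelihood plus the log prior density of beta.

    The quantity EM ascends (at ab_weight=1): sum_i log sum_k pi_k
    N(y_i; X_i beta_k, (c_k sigma)^2) + sum_k log N(beta_k; beta_prior_k,
    sigma^2 V).
    """
    X = _design(x, cn)
    logd = _log_densities(X, y, beta, sigma, scale_factors) + np.log(pi)
    ll = float(logsumexp(logd, axis=1).sum())
    var = sigma**2 * prior.v_diag
    dev = beta - prior.beta_mean
    lp = float(np.sum(-0.5 * dev**2 / var - 0.5 * np.log(2 * np.pi * var)))
    return ll + lp


def call_genotypes(
    fit: ClusterFit, threshold: float = 0.999
) -> tuple[np.ndarray, np.ndarray]:
    """Map responsibilities to calls for one SNP.

    Clusters are relabeled by fitted intercept order (lowest intercept
    -> AA) so the output is invariant to cluster permutations upstream.
    Returns (calls, max_posterior) arrays over samples.
    """
    order = np.argsort(fit.beta[:, 0])
    resp = fit.resp[:, order]
    best = resp.argmax(axis=1)
    post = resp[np.arange(len(best)), best]
    calls = np.array(CALL_CODES, dtype=object)[best]
    calls[post < threshold] = NOCALL
    return calls, post


_HEMI = {"AA": "A", "BB": "B", "AB": "0", NOCALL: NOCALL}


def _classify_by_prior(x, y, cn, prior: PriorSpec) -> ClusterFit:
    """Fallback for degenerate SNPs: nearest prior line, no EM."""
    sigma = _init_sigma(x, y, cn, prior)
    resp, n_uf = e_step(x, y, cn, prior.beta_mean, sigma, prior.pi)
    return ClusterFit(
        beta=prior.beta_mean.copy(),
        sigma=sigma,
        pi=prior.pi.copy(),
        resp=resp,
        n_iter=0,
        converged=True,
        n_underflow=n_uf,
    )


def call_dataset(
    dataset: IntensityDataset,
    prior,
    cna=None,
    config: EngineConfig | None = None,
    return_fits: bool = False,
):
    """Genotype every SNP of a centered dataset.

    Parameters
    ----------
    dataset
        Centered :class:`IntensityDataset`.
    prior
        A generic :class:`PriorSpec`, or a mapping snp_id -> PriorSpec
        (per-SNP trained priors; missing SNPs are an error).
    cna
        Optional :class:`~bcrgt.cna_covariate.CNAMatrix` with
        ``cn_value`` filled; adds the CN covariate to every fit.
    """
    from .cna_covariate import extend_prior_with_cn

    config = config or EngineConfig()
    if not dataset.centered:
        raise ValueError("call_dataset expects a centered dataset")
    per_snp = isinstance(prior, dict)
    if cna is not None and cna.cn_value is None:
        raise ValueError("CNA matrix lacks cn_value; run assign_cn_covariate first")

    def _prepared(p: PriorSpec) -> PriorSpec:
        return extend_prior_with_cn(p) if (cna is not None and not p.has_cn) else p

    if not per_snp:
        generic_prepared = _prepared(prior)

    n_snps, n_samples = dataset.a_log.shape
    calls = np.empty((n_snps, n_samples), dtype=object)
    post = np.zeros((n_snps, n_samples))
    fits: list[ClusterFit | None] = []
    n_failed = 0
    for i in range(n_snps):
        p = _prepared(prior[dataset.snp_ids[i]]) if per_snp else generic_prepared
        x = dataset.a_log[i]
        y = dataset.b_log[i]
        cn = cna.cn_value[i] if cna is not None else None
        try:
            if n_samples < config.min_samples_em:
                fit = _classify_by_prior(x, y, cn, p)
            else:
                fit = em_fit(x, y, cn, p, config)
            calls[i], post[i] = call_genotypes(fit, config.threshold)
        except FloatingPointError:
            n_failed += 1
            calls[i] = NOCALL
            post[i] = 0.0
            fit = None
        fits.append(fit)
    if n_failed:
        warnings.warn(f"{n_failed} SNP(s) failed EM and were set to NoCall", stacklevel=2)

    if config.hemizygous_notation and cna is not None:
        loss = cna.status == -1
        for i, j in zip(*np.nonzero(loss)):
            calls[i, j] = _HEMI[calls[i, j]]

    result = GenotypeCalls(
        snp_ids=dataset.snp_ids,
        sample_ids=dataset.sample_ids,
        calls=calls,
        max_posterior=post,
    )
    return (result, fits) if return_fits else result
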