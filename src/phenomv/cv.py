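"""Cross-validation splits and Bayesian model averaging.

The hyperparameters are fitted on C independent random train/test
partitions; each line's posterior is a model average of the posteriors
from the folds in which it was a test line, weighted by the fold's
marginal likelihood for that line.  A pooled covariance summarises the
fold-specific collapsed covariances for downstream factor analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .mixture import (
    EMState,
    MixtureParams,
    PosteriorMixture,
    em_fit,
    marginal_loglik_table,
    mv_estimates,
)
from .tables import RunConfig, UVResultTable

logger = logging.getLogger("phenomv")


@dataclass
class CVPlan:
    """Fold assignments with independent knockout/null partitions."""

    C: int
    N_tra: int
    train_ko: list[np.ndarray]
    test_ko: list[np.ndarray]
    train_null: list[np.ndarray]
    test_null: list[np.ndarray]

    def test_folds_of_line(self, g: int) -> list[int]:
        return [c for c in range(self.C)
                if g in self.test_ko[c] or g in self.test_null[c]]


def make_cv_plan(
    is_null_line: np.ndarray,
    config: RunConfig,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> CVPlan:
    """C random train/test partitions of knockout and null lines.

    Knockout and null partitions are drawn independently; the null
    training fraction matches the knockout one.  Plans are resampled
    (with logged retries) until every line lands in at least one test
    set.
    """
    is_null_line = np.asarray(is_null_line, dtype=bool)
    ko_idx = np.flatnonzero(~is_null_line)
    null_idx = np.flatnonzero(is_null_line)
    n_ko = ko_idx.size
    if config.N_tra >= n_ko:
        raise ValueError("N_tra must be below the number of knockout lines")
    frac = config.N_tra / n_ko
    n_tra_null = int(round(frac * null_idx.size))
    for attempt in range(max_retries + 1):
        train_ko, test_ko, train_null, test_null = [], [], [], []
        for _ in range(config.C):
            perm = rng.permutation(ko_idx)
            train_ko.append(np.sort(perm[: config.N_tra]))
            test_ko.append(np.sort(perm[config.N_tra:]))
            permn = rng.permutation(null_idx)
            train_null.append(np.sort(permn[:n_tra_null]))
            test_null.append(np.sort(permn[n_tra_null:]))
        in_test = np.zeros(is_null_line.size, dtype=bool)
        for c in range(config.C):
            in_test[test_ko[c]] = True
            in_test[test_null[c]] = True
        if in_test.all():
            if attempt:
                logger.info("CV plan accepted after %d retries", attempt)
            break
    else:
        import warnings

        warnings.warn(
            f"{int((~in_test).sum())} line(s) appear in no test set after "
            f"{max_retries} retries; they will have no model-averaged "
            "posterior", RuntimeWarning)
    return CVPlan(C=config.C, N_tra=config.N_tra,
                  train_ko=train_ko, test_ko=test_ko,
                  train_null=train_null, test_null=test_null)


def bma_posterior(
    fold_posteriors: list[PosteriorMixture],
    fold_logliks: list[float],
) -> PosteriorMixture:
    """Model-average one line's posteriors across its eligible folds.

    Fold weights are proportional to exp(fold marginal log likelihood),
    normalised in log space; the result is the enlarged mixture with
    component weights scaled accordingly.
    """
    if not fold_posteriors:
        raise ValueError("need at least one eligible fold")
    logw = np.asarray(fold_logliks, dtype=float)
    w = np.exp(logw - logsumexp(logw))
    weights, means, covs = [], [], []
    for wc, post in zip(w, fold_posteriors):
        r, mu, V = post.flat_components()
        weights.append(wc * r)
        means.append(mu)
        covs.append(V)
    return PosteriorMixture(
        r=np.concatenate(weights),
        mu=np.concatenate(means, axis=0),
        V=np.concatenate(covs, axis=0),
        log_evidence=float(logsumexp(logw) - np.log(len(fold_posteriors))),
    )


@dataclass
class PooledCovariance:
    """Likelihood-weighted average of fold collapsed covariances."""

    sigma_pooled: np.ndarray
    log_fold_weights: np.ndarray

    @property
    def fold_weights(self) -> np.ndarray:
        return np.exp(self.log_fold_weights)


def collapse_sigma(params: MixtureParams) -> np.ndarray:
    """Collapsed covariance sum_{m,s} pi_ms omega_m Sigma_s of one fold."""
    return params.prior_cov()


def pool_sigma(
    fold_params: list[MixtureParams],
    fold_test_logliks: list[float],
) -> PooledCovariance:
    """Pool fold covariances with product-of-test-likelihood weights.

    Weights are the normalised exponentials of each fold's summed
    test-set log likelihood (computed in log space; with many test
    lines one fold typically dominates, which is the formula's printed
    behaviour).
    """
    logw = np.asarray(fold_test_logliks, dtype=float)
    logw = logw - logsumexp(logw)
    sigmas = np.stack([collapse_sigma(p) for p in fold_params])
    pooled = np.einsum("c,cpq->pq", np.exp(logw), sigmas)
    return PooledCovariance(sigma_pooled=pooled, log_fold_weights=logw)


def cv_loglik(test_uv: UVResultTable, params: MixtureParams) -> float:
    """Per-sample mean test-set marginal log likelihood of one fold."""
    return float(np.mean(marginal_loglik_table(test_uv, params)))


@dataclass
class CVResult:
    plan: CVPlan
    fold_params: list[MixtureParams]
    fold_states: list[EMState]
    theta_mv: np.ndarray
    sd_mv: np.ndarray
    posteriors: list[PosteriorMixture]
    pooled: PooledCovariance
    cv_logliks: list[float]


def run_cv(
    uv: UVResultTable,
    config: RunConfig,
    R: np.ndarray,
    rng: np.random.Generator,
) -> CVResult:
    """Full cross-validated pipeline: fit folds, model-average test
    posteriors, and pool the fold covariances.

    Hyperparameters are trained on each fold's knockout training lines;
    every line's final posterior averages the folds in which it was a
    test line (knockout or null), weighted by those folds' evidence for
    the line.
    """
    plan = make_cv_plan(uv.is_null_line, config, rng)
    fold_params: list[MixtureParams] = []
    fold_states: list[EMState] = []
    per_line_posts: list[list[PosteriorMixture]] = [[] for _ in uv.lines]
    per_line_logliks: list[list[float]] = [[] for _ in uv.lines]
    test_logliks: list[float] = []
    cv_logliks: list[float] = []
    for c in range(plan.C):
        train = uv.subset_lines(plan.train_ko[c])
        params, state = em_fit(train, config, R)
        fold_params.append(params)
        fold_states.append(state)
        test_idx = np.sort(np.concatenate(
            [plan.test_ko[c], plan.test_null[c]]))
        test = uv.subset_lines(test_idx)
        _, _, posts = mv_estimates(test, params, return_posteriors=True)
        l_g = marginal_loglik_table(test, params)
        for i, g in enumerate(test_idx):
            per_line_posts[g].append(posts[i])
            per_line_logliks[g].append(float(l_g[i]))
        ko_test = uv.subset_lines(plan.test_ko[c])
        ko_l = marginal_loglik_table(ko_test, params)
        test_logliks.append(float(ko_l.sum()))
        cv_logliks.append(float(ko_l.mean()))
    P, G = uv.n_phenotypes, uv.n_lines
    theta_mv = np.zeros((P, G))
    sd_mv = np.zeros((P, G))
    posteriors: list[PosteriorMixture] = []
    for g in range(G):
        post = bma_posterior(per_line_posts[g], per_line_logliks[g])
        posteriors.append(post)
        theta_mv[:, g] = post.mean
        sd_mv[:, g] = post.sd
    pooled = pool_sigma(fold_params, test_logliks)
    logger.info("CV pipeline: %d folds, mean CV loglik %.4f",
                plan.C, float(np.mean(cv_logliks)))
    return CVResult(plan=plan, fold_params=fold_params,
                    fold_states=fold_states, theta_mv=theta_mv, sd_mv=sd_mv,
                    posteriors=posteriors, pooled=pooled,
                    cv_logliks=cv_logliks)
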