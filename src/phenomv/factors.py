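"""Factor-space interpretation of the pooled covariance.

The correlation matrix underlying the pooled covariance is
eigendecomposed; the leading eigenvectors, scaled by the square roots
of their eigenvalues, are varimax-rotated (with Kaiser normalisation)
into sparse interpretable loadings.  Projecting each line's posterior
onto a loadings vector gives a factor score with a closed-form standard
deviation, tested against synthetic-null factor scores with the same
permutation threshold machinery as phenotype-level calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import bh_adjust, fisher_2x2, select_tau
from .mixture import PosteriorMixture


@dataclass
class FactorModel:
    """Eigenstructure and (optionally) rotated loadings."""

    D_sigma: np.ndarray  # diagonal of the pooled covariance
    Q: np.ndarray  # orthonormal eigenvectors, columns by descending Delta
    Delta: np.ndarray  # eigenvalues, descending
    L: int = 0
    Lambda: np.ndarray | None = None  # (P, L) rotated, max-|.|-scaled
    Lambda_raw: np.ndarray | None = None  # rotated, pre-scaling
    signs: np.ndarray | None = None

    @property
    def cumulative_fraction(self) -> np.ndarray:
        return np.cumsum(self.Delta) / self.Delta.sum()


def eigen_corr(sigma_pooled: np.ndarray) -> FactorModel:
    """Eigendecomposition of the correlation underlying a covariance."""
    sigma_pooled = np.asarray(sigma_pooled, dtype=float)
    d = np.diag(sigma_pooled)
    if np.any(d <= 0):
        raise ValueError("pooled covariance must have positive diagonal")
    corr = sigma_pooled / np.sqrt(np.outer(d, d))
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    return FactorModel(D_sigma=d, Q=evecs[:, order],
                       Delta=np.maximum(evals[order], 0.0))


def varimax(A: np.ndarray, normalize: bool = True, max_iter: int = 1000,
            tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation with Kaiser row normalisation.

    Returns the rotated loadings and the orthogonal rotation matrix.
    The varimax criterion is nondecreasing across sweeps.
    """
    A = np.asarray(A, dtype=float)
    P, L = A.shape
    if L < 2:
        return A.copy(), np.eye(L)
    if normalize:
        h = np.sqrt(np.sum(A * A, axis=1))
        h = np.where(h > 0, h, 1.0)
        A = A / h[:, None]
    T = np.eye(L)
    d_old = 0.0
    for _ in range(max_iter):
        B = A @ T
        U, s, Vt = np.linalg.svd(
            A.T @ (B ** 3 - B @ np.diag(np.sum(B * B, axis=0)) / P))
        T = U @ Vt
        d = s.sum()
        if d_old != 0 and (d - d_old) < tol * d_old:
            break
        d_old = d
    rotated = A @ T
    if normalize:
        rotated = rotated * h[:, None]
    return rotated, T


def varimax_criterion(A: np.ndarray) -> float:
    """The raw varimax objective: sum of column variances of squared
    loadings."""
    sq = A ** 2
    return float(np.sum(sq.var(axis=0)))


def varimax_loadings(model: FactorModel, L: int = 20) -> FactorModel:
    """Rotate the leading L scaled eigenvectors to sparse loadings.

    Eigenvectors are scaled by sqrt(eigenvalue) before rotation (the
    principal-axis convention), varimax-rotated, and each factor is
    rescaled so its largest-magnitude loading is 1.  Signs are resolved
    later against significant factor-score calls.
    """
    if L > model.Q.shape[0]:
        raise ValueError("cannot retain more factors than phenotypes")
    A = model.Q[:, :L] * np.sqrt(model.Delta[:L])[None, :]
    rotated, _ = varimax(A)
    scale = np.abs(rotated).max(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return FactorModel(
        D_sigma=model.D_sigma, Q=model.Q, Delta=model.Delta, L=L,
        Lambda=rotated / scale[None, :], Lambda_raw=rotated,
        signs=np.ones(L, dtype=int),
    )


@dataclass
class FactorScoreTable:
    """Per-(factor, line) score estimates, SDs, z and signed calls."""

    u_hat: np.ndarray
    s_hat: np.ndarray
    z: np.ndarray
    calls: np.ndarray
    tau: float = np.nan


def factor_scores(
    posteriors: list[PosteriorMixture], Lambda: np.ndarray
) -> FactorScoreTable:
    """Project posterior moments onto the loadings.

    u_hat = Lambda^T posterior-mean and s_hat the square root of the
    quadratic form Lambda^T posterior-covariance Lambda, so z = u/s is
    scale-correct.  Calls start at 0 and are filled by the threshold
    machinery once null-line scores exist.
    """
    Lambda = np.asarray(Lambda, dtype=float)
    L = Lambda.shape[1]
    G = len(posteriors)
    u = np.empty((L, G))
    s = np.empty((L, G))
    for g, post in enumerate(posteriors):
        u[:, g] = Lambda.T @ post.mean
        s[:, g] = np.sqrt(np.einsum("pl,pq,ql->l", Lambda, post.cov, Lambda))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(s > 0, u / np.where(s > 0, s, 1.0), 0.0)
    return FactorScoreTable(u_hat=u, s_hat=s, z=z,
                            calls=np.zeros((L, G), dtype=int))


def call_factor_scores(
    scores_ko: FactorScoreTable,
    scores_null: FactorScoreTable,
    alpha: float = 0.05,
    prior_H0: float = 1.0,
) -> tuple[FactorScoreTable, FactorScoreTable]:
    """Select a factor-level threshold on null scores and fill calls."""
    tau = select_tau(scores_ko.z, scores_null.z, alpha, prior_H0)
    for table in (scores_ko, scores_null):
        calls = np.zeros(table.z.shape, dtype=int)
        fire = np.abs(table.z) > tau
        calls[fire] = np.sign(table.z[fire]).astype(int)
        table.calls = calls
        table.tau = tau
    return scores_ko, scores_null


def resolve_signs(model: FactorModel, scores: FactorScoreTable
                  ) -> tuple[FactorModel, FactorScoreTable]:
    """Fix each factor's sign so most significant perturbations are
    positive; flips loadings, scores and calls coherently."""
    signs = np.ones(model.L, dtype=int)
    for l in range(model.L):
        called = scores.calls[l] != 0
        if called.any() and np.mean(scores.calls[l][called] > 0) < 0.5:
            signs[l] = -1
    model.signs = signs
    model.Lambda = model.Lambda * signs[None, :]
    model.Lambda_raw = model.Lambda_raw * signs[None, :]
    flipped = FactorScoreTable(
        u_hat=scores.u_hat * signs[:, None],
        s_hat=scores.s_hat,
        z=scores.z * signs[:, None],
        calls=scores.calls * signs[:, None],
        tau=scores.tau,
    )
    return model, flipped


def factor_cooccurrence(calls: np.ndarray) -> pd.DataFrame:
    """Pairwise co-perturbation tests across factors.

    For each factor pair, a 2x2 table of binary significance counts is
    tested with the Fisher exact test; sample odds ratios and BH-adjusted
    p-values across the L(L-1)/2 family are returned.  Degenerate
    margins give a missing odds ratio.
    """
    calls = np.asarray(calls)
    L = calls.shape[0]
    if L < 2:
        raise ValueError("need at least 2 factors")
    sig = calls != 0
    rows = []
    for a in range(L):
        for b in range(a + 1, L):
            t = np.array([
                [np.sum(sig[a] & sig[b]), np.sum(sig[a] & ~sig[b])],
                [np.sum(~sig[a] & sig[b]), np.sum(~sig[a] & ~sig[b])],
            ])
            res = fisher_2x2(t)
            rows.append((a, b, int(t[0, 0]), res["odds_ratio"],
                         res["p_value"]))
    out = pd.DataFrame(
        rows, columns=["factor_a", "factor_b", "n_both", "odds_ratio",
                       "p_value"])
    out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    # infinite sample OR (empty off-diagonal cell) flagged as undefined
    out["or_defined"] = np.isfinite(out["odds_ratio"])
    out.loc[~out["or_defined"], "odds_ratio"] = np.nan
    return out
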