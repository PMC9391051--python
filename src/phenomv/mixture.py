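"""Multivariate empirical-Bayes mixture model over a scale ladder.

The latent perturbation vector theta_g of a knockout line is modelled as
a zero-mean Gaussian mixture over a fixed ladder of scales omega_1:M and
S learned covariance shapes, each constrained to factor form
Sigma_s = W_s W_s^T + Psi_s.  The observed univariate estimates are the
latent vector plus correlated heteroscedastic noise S_g R S_g, with S_g
the diagonal matrix of standard errors and R the experimental noise
correlation fixed in advance.  Hyperparameters (Sigma_1:S, pi) are fitted
by EM; the posterior of theta_g given the observed subvector is a
closed-form Gaussian mixture, including at missing phenotypes.

All linear algebra on the restricted covariances goes through Cholesky
factorisations, batched across lines sharing a missingness pattern.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import invwishart

from .tables import RunConfig, UVResultTable

logger = logging.getLogger("phenomv")

_LOG_2PI = np.log(2.0 * np.pi)
PSI_FLOOR = 1e-6
PI_FLOOR = 1e-12


@dataclass
class FactorCovariance:
    """Low-rank-plus-diagonal covariance W W^T + diag(psi)."""

    W: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.psi = np.asarray(self.psi, dtype=float)
        if self.psi.ndim != 1 or self.W.shape[0] != self.psi.shape[0]:
            raise ValueError("W and psi dimensions inconsistent")
        if np.any(self.psi < 0):
            raise ValueError("psi entries must be nonnegative")

    @property
    def P(self) -> int:
        return self.W.shape[0]

    @property
    def K(self) -> int:
        return self.W.shape[1]

    def full(self) -> np.ndarray:
        return self.W @ self.W.T + np.diag(self.psi)


@dataclass
class MixtureParams:
    """Fitted hyperparameters of the MV mixture model."""

    sigmas: list[FactorCovariance]
    pi: np.ndarray  # (M, S), sums to 1
    omega: np.ndarray  # (M,) strictly increasing scales
    R: np.ndarray  # (P, P) noise correlation

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        M, S = self.pi.shape
        if len(self.sigmas) != S or len(self.omega) != M:
            raise ValueError("pi shape inconsistent with sigmas/omega")
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("pi must sum to 1")
        if np.any(np.diff(self.omega) <= 0):
            raise ValueError("omega must be strictly increasing")

    @property
    def M(self) -> int:
        return self.pi.shape[0]

    @property
    def S(self) -> int:
        return self.pi.shape[1]

    @property
    def P(self) -> int:
        return self.sigmas[0].P

    def sigma_full(self) -> np.ndarray:
        """Stack of the S dense covariance shapes, (S, P, P)."""
        return np.stack([s.full() for s in self.sigmas])

    def prior_cov(self) -> np.ndarray:
        """Marginal prior covariance sum_{m,s} pi_ms omega_m Sigma_s."""
        sig = self.sigma_full()
        return np.einsum("ms,m,spq->pq", self.pi, self.omega, sig)


@dataclass
class PosteriorMixture:
    """Closed-form Gaussian-mixture posterior for one line.

    ``r`` holds component weights (shape (M, S) from a single fit, flat
    after model averaging); ``mu`` and ``V`` the matching component
    means/covariances.  ``mean``/``sd``/``cov`` are the mixture moments.
    """

    r: np.ndarray
    mu: np.ndarray
    V: np.ndarray
    log_evidence: float = np.nan
    mean: np.ndarray = field(init=False)
    sd: np.ndarray = field(init=False)
    cov: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        P = self.mu.shape[-1]
        w = r.reshape(-1)
        mu = self.mu.reshape(-1, P)
        V = self.V.reshape(-1, P, P)
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("responsibilities must sum to 1")
        self.mean = w @ mu
        second = np.einsum("c,cpq->pq", w, V + np.einsum("cp,cq->cpq", mu, mu))
        self.cov = second - np.outer(self.mean, self.mean)
        self.sd = np.sqrt(np.maximum(np.diag(self.cov), 0.0))

    def flat_components(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        P = self.mu.shape[-1]
        return (self.r.reshape(-1), self.mu.reshape(-1, P),
                self.V.reshape(-1, P, P))


@dataclass
class EMState:
    """Trace of an EM run: last moment matrices, per-line log-likelihood
    contributions and the objective history."""

    C: list[np.ndarray]
    loglik_contributions: np.ndarray
    iteration: int
    objective_trace: list[float]
    converged: bool


# ---------------------------------------------------------------------------
# batched per-pattern linear algebra


def _pattern_groups(mask: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group line indices by missingness pattern.

    ``mask`` is (P, G) observed-mask; returns (obs_idx, line_idx) pairs.
    Lines with no observed cells are returned with an empty obs_idx.
    """
    G = mask.shape[1]
    codes = {}
    for g in range(G):
        key = mask[:, g].tobytes()
        codes.setdefault(key, []).append(g)
    groups = []
    for key, gs in codes.items():
        obs = np.flatnonzero(np.frombuffer(key, dtype=bool))
        groups.append((obs, np.asarray(gs)))
    return groups


def _component_logliks_and_moments(
    theta: np.ndarray,
    se: np.ndarray,
    obs: np.ndarray,
    params_sig: np.ndarray,
    omega: np.ndarray,
    R: np.ndarray,
    want_moments: bool,
):
    """Batched per-component evidence and conditional moments.

    theta, se: (n, P*) observed values for n lines sharing the pattern.
    Returns log N(theta | 0, omega_m Sigma_s** + S R** S) with shape
    (n, M, S) and, when requested, the full-P conditional moments
    mu (n, M, S, P) and V (n, M, S, P, P).
    """
    n, Pobs = theta.shape
    M, S = len(omega), params_sig.shape[0]
    P = params_sig.shape[1]
    R_oo = R[np.ix_(obs, obs)]
    noise = se[:, :, None] * R_oo[None] * se[:, None, :]  # (n, P*, P*)
    loglik = np.empty((n, M, S))
    mu = np.empty((n, M, S, P)) if want_moments else None
    V = np.empty((n, M, S, P, P)) if want_moments else None
    for s in range(S):
        sig_oo = params_sig[s][np.ix_(obs, obs)]
        sig_all_o = params_sig[s][:, obs]  # (P, P*)
        for m in range(M):
            K = omega[m] * sig_oo[None] + noise  # (n, P*, P*)
            try:
                L = np.linalg.cholesky(K)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    f"restricted covariance not positive definite at "
                    f"(m={m}, s={s})"
                ) from exc
            logdet = 2.0 * np.log(
                np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
            alpha = np.linalg.solve(K, theta[:, :, None])[:, :, 0]
            quad = np.einsum("np,np->n", theta, alpha)
            loglik[:, m, s] = -0.5 * (Pobs * _LOG_2PI + logdet + quad)
            if want_moments:
                A = omega[m] * sig_all_o  # (P, P*)
                mu[:, m, s, :] = alpha @ A.T
                B = np.broadcast_to(A.T[None], (n, Pobs, P))
                X = np.linalg.solve(K, np.ascontiguousarray(B))
                V[:, m, s] = omega[m] * params_sig[s][None] - np.einsum(
                    "pq,nqr->npr", A, X)
    return loglik, mu, V


def _restricted_obs(estimate_row: np.ndarray, se_row: np.ndarray):
    estimate_row = np.asarray(estimate_row, dtype=float)
    se_row = np.asarray(se_row, dtype=float)
    obs = np.flatnonzero(~np.isnan(estimate_row))
    if obs.size == 0:
        raise ValueError("line has no observed phenotypes")
    return estimate_row[obs], se_row[obs], obs


def marginal_loglik(
    estimate_row: np.ndarray, se_row: np.ndarray, params: MixtureParams
) -> float:
    """Log marginal likelihood of one line's observed subvector.

    log sum_{m,s} pi_ms N(theta_hat | 0, omega_m Sigma_s** + S R** S),
    evaluated with log-sum-exp over the component evidences.
    """
    th, se, obs = _restricted_obs(estimate_row, se_row)
    loglik, _, _ = _component_logliks_and_moments(
        th[None], se[None], obs, params.sigma_full(), params.omega,
        params.R, want_moments=False)
    with np.errstate(divide="ignore"):
        return float(logsumexp(loglik[0] + np.log(params.pi)))


def posterior(
    estimate_row: np.ndarray, se_row: np.ndarray, params: MixtureParams
) -> PosteriorMixture:
    """Closed-form Gaussian-mixture posterior for one line.

    Component means use the cross-covariance Sigma_{s,.*} so rows for
    missing phenotypes are imputed coherently from the observed ones.
    """
    th, se, obs = _restricted_obs(estimate_row, se_row)
    loglik, mu, V = _component_logliks_and_moments(
        th[None], se[None], obs, params.sigma_full(), params.omega,
        params.R, want_moments=True)
    with np.errstate(divide="ignore"):
        log_w = loglik[0] + np.log(params.pi)
    log_ev = logsumexp(log_w)
    r = np.exp(log_w - log_ev)
    return PosteriorMixture(r=r, mu=mu[0], V=V[0], log_evidence=float(log_ev))


def marginal_loglik_table(uv: UVResultTable, params: MixtureParams
                          ) -> np.ndarray:
    """Marginal log likelihood l_g for every line of a table."""
    G = uv.n_lines
    out = np.full(G, np.nan)
    sig = params.sigma_full()
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi)
    for obs, gs in _pattern_groups(uv.observed_mask):
        if obs.size == 0:
            raise ValueError("line has no observed phenotypes")
        th = uv.estimate[np.ix_(obs, gs)].T
        se = uv.se[np.ix_(obs, gs)].T
        ll, _, _ = _component_logliks_and_moments(
            th, se, obs, sig, params.omega, params.R, want_moments=False)
        out[gs] = logsumexp((ll + log_pi[None]).reshape(len(gs), -1), axis=1)
    return out


# ---------------------------------------------------------------------------
# initialisation


def initialize_sigma(
    train_uv: UVResultTable,
    S: int,
    eps_jitter: float = 0.05,
    seed: int = 0,
) -> list[np.ndarray]:
    """Empirical covariance initialisation for the S mixture shapes.

    Missing cells are zero-filled only for this computation.  For S = 1
    the single subset is the whole training set; for S > 1 subsets come
    from model-based (Gaussian-mixture) clustering of the zero-filled
    matrix.  eps_jitter * I is added whenever the smallest eigenvalue is
    not strictly positive.
    """
    if train_uv.n_lines == 0:
        raise ValueError("training set is empty")
    X = np.nan_to_num(train_uv.estimate, nan=0.0).T  # lines x phenotypes
    if S == 1:
        subsets = [np.arange(X.shape[0])]
    else:
        from sklearn.mixture import GaussianMixture

        gm = GaussianMixture(
            n_components=S, covariance_type="diag",
            init_params="k-means++", random_state=seed, n_init=1)
        labels = gm.fit_predict(X)
        subsets = [np.flatnonzero(labels == s) for s in range(S)]
    out = []
    for s, idx in enumerate(subsets):
        if idx.size < 2:
            raise ValueError(f"initialisation subset {s} has fewer than 2 lines")
        C = np.cov(X[idx], rowvar=False, ddof=1)
        C = np.atleast_2d(C)
        if np.linalg.eigvalsh(C).min() <= 0:
            C = C + eps_jitter * np.eye(C.shape[0])
        out.append(C)
    return out


def random_init_sigma(P: int, rng: np.random.Generator) -> np.ndarray:
    """Vanilla random initialisation: one Inverse-Wishart(I, 2000) draw."""
    if P >= 2000:
        raise ValueError("P must be below the Inverse-Wishart degrees of freedom")
    return np.atleast_2d(
        invwishart.rvs(df=2000, scale=np.eye(P), random_state=rng))


# ---------------------------------------------------------------------------
# factor-constrained M-step


def fa_objective(sigma: np.ndarray, C: np.ndarray) -> float:
    """Gaussian KL objective log|Sigma| + tr(Sigma^-1 C)."""
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    return float(logdet + np.trace(np.linalg.solve(sigma, C)))


def fit_factor_covariance(
    C: np.ndarray,
    K: int,
    max_iter: int = 500,
    rtol: float = 1e-8,
    warm_start: FactorCovariance | None = None,
) -> FactorCovariance:
    """Maximum-likelihood factor fit of a covariance matrix.

    Minimises log|Sigma| + tr(Sigma^-1 C) over Sigma = W W^T + diag(psi)
    by the factor-analysis EM recursion on the second-moment matrix C,
    with principal-axis initialisation (or a warm start, which preserves
    the outer EM's monotonicity) and psi floored at 1e-6.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("C must be square")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("C must be symmetric")
    P = C.shape[0]
    if K >= P:
        raise ValueError("factor rank K must be below the dimension P")
    if warm_start is not None:
        W = warm_start.W.copy()
        psi = np.maximum(warm_start.psi, PSI_FLOOR)
    else:
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1][:K]
        W = evecs[:, order] * np.sqrt(np.maximum(evals[order], PSI_FLOOR))
        psi = np.maximum(np.diag(C) - np.sum(W * W, axis=1), PSI_FLOOR)
    obj = fa_objective(W @ W.T + np.diag(psi), C)
    for _ in range(max_iter):
        sigma = W @ W.T + np.diag(psi)
        beta = np.linalg.solve(sigma, W).T  # (K, P)
        Ezz = np.eye(K) - beta @ W + beta @ C @ beta.T
        W = C @ beta.T @ np.linalg.inv(Ezz)
        psi = np.maximum(np.diag(C - W @ (beta @ C)), PSI_FLOOR)
        new_obj = fa_objective(W @ W.T + np.diag(psi), C)
        if abs(new_obj - obj) <= rtol * max(1.0, abs(obj)):
            obj = new_obj
            break
        obj = new_obj
    return FactorCovariance(W=W, psi=psi)


# ---------------------------------------------------------------------------
# EM


def em_fit(
    train_uv: UVResultTable,
    config: RunConfig,
    R: np.ndarray,
    init: list[np.ndarray] | None = None,
    max_iter: int = 1000,
) -> tuple[MixtureParams, EMState]:
    """Fit (Sigma_1:S, pi) by EM on a training UV table.

    The E-step computes component responsibilities from the marginal
    evidences; the M-step updates pi and the responsibility-weighted
    second-moment matrices C_s (built from full-P conditional moments,
    rescaled by 1/omega_m) and then re-fits each Sigma_s in factor form.
    Convergence when the change in total log likelihood falls below
    eps_tol * N_tra * MAD(l_g); a decrease beyond numerical tolerance is
    a hard error.
    """
    M, S, K = config.M, config.S, config.K
    omega = np.asarray(config.omega_ladder, dtype=float)
    P, G = train_uv.n_phenotypes, train_uv.n_lines
    if init is None:
        init = initialize_sigma(train_uv, S, config.eps_jitter, config.seed)
    # project the initial covariances into factor form so the whole EM
    # path stays inside the constraint set (keeps the objective monotone)
    sigmas = [fit_factor_covariance(np.asarray(c, dtype=float), K)
              for c in init]
    sig = np.stack([fc.full() for fc in sigmas])
    pi = np.full((M, S), 1.0 / (M * S))
    groups = _pattern_groups(train_uv.observed_mask)

    trace: list[float] = []
    converged = False
    l_g = np.empty(G)
    C_list: list[np.ndarray] = [sig[s].copy() for s in range(S)]
    it = 0
    for it in range(1, max_iter + 1):
        log_ev = np.empty((G, M, S))
        mu_acc = [np.zeros((P, P)) for _ in range(S)]  # responsibility-weighted
        r_tot = np.zeros((M, S))
        # first pass: evidences for responsibilities
        pattern_cache = []
        for obs, gs in groups:
            th = train_uv.estimate[np.ix_(obs, gs)].T
            se = train_uv.se[np.ix_(obs, gs)].T
            ll, _, _ = _component_logliks_and_moments(
                th, se, obs, sig, omega, R, want_moments=False)
            log_ev[gs] = ll
            pattern_cache.append((obs, gs, th, se))
        with np.errstate(divide="ignore"):
            log_w = log_ev + np.log(pi)[None]
        l_g = logsumexp(log_w.reshape(G, -1), axis=1)
        resp = np.exp(log_w - l_g[:, None, None])
        objective = float(l_g.sum())
        if trace and objective < trace[-1] - 1e-6 * max(1.0, abs(trace[-1])):
            raise RuntimeError(
                f"EM objective decreased at iteration {it}: "
                f"{trace[-1]:.8g} -> {objective:.8g}")
        trace.append(objective)
        # convergence check on the objective history
        if len(trace) >= 2:
            mad = float(np.median(np.abs(l_g - np.median(l_g))))
            if config.tol_scale_mode == "multiply":
                tol = config.eps_tol * G * mad
            else:
                tol = config.eps_tol * mad / G
            if abs(trace[-1] - trace[-2]) < max(tol, 1e-12):
                converged = True
                break
        # M-step: pi
        pi_new = resp.sum(axis=0)
        pi_new = pi_new / pi_new.sum()
        collapsed = pi_new < PI_FLOOR
        if collapsed.any():
            warnings.warn(
                "mixture weight collapsed to ~0; floored at 1e-12",
                RuntimeWarning)
            pi_new = np.maximum(pi_new, PI_FLOOR)
            pi_new = pi_new / pi_new.sum()
        pi = pi_new
        # M-step: C_s from full-P conditional moments
        C_num = [np.zeros((P, P)) for _ in range(S)]
        C_den = np.zeros(S)
        for obs, gs, th, se in pattern_cache:
            _, mu, V = _component_logliks_and_moments(
                th, se, obs, sig, omega, R, want_moments=True)
            r = resp[gs]  # (n, M, S)
            for s in range(S):
                w = r[:, :, s] / omega[None, :]  # (n, M)
                second = V[:, :, s] + np.einsum(
                    "nmp,nmq->nmpq", mu[:, :, s], mu[:, :, s])
                C_num[s] += np.einsum("nm,nmpq->pq", w, second)
                C_den[s] += r[:, :, s].sum()
        for s in range(S):
            C_list[s] = C_num[s] / C_den[s]
            sigmas[s] = fit_factor_covariance(C_list[s], K,
                                              warm_start=sigmas[s])
            sig[s] = sigmas[s].full()
    else:
        logger.warning("EM hit the iteration cap (%d) without converging",
                       max_iter)
    params = MixtureParams(sigmas=sigmas, pi=pi, omega=omega, R=np.asarray(R))
    state = EMState(C=C_list, loglik_contributions=l_g, iteration=it,
                    objective_trace=trace, converged=converged)
    logger.info("EM finished after %d iterations (objective %.6g)",
                it, trace[-1])
    return params, state


# ---------------------------------------------------------------------------
# posterior estimates for a whole table


def mv_estimates(
    uv: UVResultTable,
    params: MixtureParams,
    return_posteriors: bool = False,
):
    """Posterior mixture moments for every line at all P phenotypes.

    Returns dense (P, G) matrices of posterior means and SDs; cells
    missing in the input are imputed through the cross-phenotype
    covariance.  Lines with no observed phenotype get prior moments.
    """
    P, G = uv.n_phenotypes, uv.n_lines
    theta_mv = np.zeros((P, G))
    sd_mv = np.zeros((P, G))
    posteriors: list[PosteriorMixture | None] = [None] * G
    sig = params.sigma_full()
    prior_cov = params.prior_cov()
    prior_sd = np.sqrt(np.diag(prior_cov))
    for obs, gs in _pattern_groups(uv.observed_mask):
        if obs.size == 0:
            warnings.warn(
                f"{len(gs)} line(s) with no observed phenotypes: "
                "returning prior moments", RuntimeWarning)
            prior_V = np.einsum("m,spq->mspq", params.omega, sig)
            for g in gs:
                theta_mv[:, g] = 0.0
                sd_mv[:, g] = prior_sd
                if return_posteriors:
                    posteriors[g] = PosteriorMixture(
                        r=params.pi,
                        mu=np.zeros((params.M, params.S, P)),
                        V=prior_V)
            continue
        th = uv.estimate[np.ix_(obs, gs)].T
        se = uv.se[np.ix_(obs, gs)].T
        ll, mu, V = _component_logliks_and_moments(
            th, se, obs, sig, params.omega, params.R, want_moments=True)
        with np.errstate(divide="ignore"):
            log_w = ll + np.log(params.pi)[None]
        log_ev = logsumexp(log_w.reshape(len(gs), -1), axis=1)
        r = np.exp(log_w - log_ev[:, None, None])
        mean = np.einsum("nms,nmsp->np", r, mu)
        second = np.einsum(
            "nms,nmspq->npq", r,
            V + np.einsum("nmsp,nmsq->nmspq", mu, mu))
        cov = second - np.einsum("np,nq->npq", mean, mean)
        theta_mv[:, gs] = mean.T
        sd_mv[:, gs] = np.sqrt(np.maximum(
            np.diagonal(cov, axis1=1, axis2=2), 0.0)).T
        if return_posteriors:
            for i, g in enumerate(gs):
                posteriors[g] = PosteriorMixture(
                    r=r[i], mu=mu[i], V=V[i], log_evidence=float(log_ev[i]))
    if return_posteriors:
        return theta_mv, sd_mv, posteriors
    return theta_mv, sd_mv


# ---------------------------------------------------------------------------
# serialization


def save_params(params: MixtureParams, outdir) -> None:
    """Serialise fitted parameters: W/psi per component as TSV, pi and
    omega as JSON, R as a TSV matrix."""
    import json
    from pathlib import Path

    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s, fc in enumerate(params.sigmas):
        pd.DataFrame(fc.W).to_csv(outdir / f"W_{s}.tsv", sep="\t",
                                  index=False, float_format="%.17g")
        pd.DataFrame({"psi": fc.psi}).to_csv(
            outdir / f"psi_{s}.tsv", sep="\t", index=False,
            float_format="%.17g")
    with open(outdir / "mixture.json", "w") as fh:
        json.dump({"pi": params.pi.tolist(),
                   "omega": params.omega.tolist()}, fh, indent=2)
    pd.DataFrame(params.R).to_csv(outdir / "R.tsv", sep="\t", index=False,
                                  float_format="%.17g")


def load_params(indir) -> MixtureParams:
    import json
    from pathlib import Path

    import pandas as pd

    indir = Path(indir)
    with open(indir / "mixture.json") as fh:
        meta = json.load(fh)
    pi = np.asarray(meta["pi"], dtype=float)
    S = pi.shape[1]
    sigmas = [
        FactorCovariance(
            W=pd.read_csv(indir / f"W_{s}.tsv", sep="\t").to_numpy(),
            psi=pd.read_csv(indir / f"psi_{s}.tsv", sep="\t")["psi"]
            .to_numpy())
        for s in range(S)
    ]
    R = pd.read_csv(indir / "R.tsv", sep="\t").to_numpy()
    return MixtureParams(sigmas=sigmas, pi=pi,
                         omega=np.asarray(meta["omega"]), R=R)
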