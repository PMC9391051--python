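"""Hit calling and error-rate control.

z statistics, permutation-calibrated Fdr estimation against synthetic
null lines (Westfall-Young style threshold selection), local false sign
rates, signed annotation calls, replicability cross-tabulations with the
replicate-based false-sign-rate estimator, gene-set construction and
2x2 contingency testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mixture import PosteriorMixture


@dataclass
class ZTable:
    """z and threshold-scaled z matrices for one model's output."""

    z: np.ndarray
    z_scaled: np.ndarray
    source: str = "MV"


def z_table(theta_hat: np.ndarray, sd: np.ndarray, tau: float,
            source: str = "MV") -> ZTable:
    """Elementwise z = theta_hat / sd and z_scaled = z / tau.

    |z_scaled| >= 1 exactly when |z| >= tau, so scaled statistics put
    every phenotype on a common significance scale.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    sd = np.asarray(sd, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(sd <= 0):
            raise ValueError("posterior SDs must be positive")
    z = theta_hat / sd
    z_scaled = z / tau if np.isfinite(tau) and tau > 0 else np.zeros_like(z)
    return ZTable(z=z, z_scaled=z_scaled, source=source)


@dataclass
class FdrEstimate:
    tau: float
    fdr_single: float
    fdr_complete: float
    prior_H0: float
    no_ko_exceedance: bool = False


def _line_max_abs(z: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmax(np.abs(z), axis=0)


def fdr_hats(z_ko: np.ndarray, z_null: np.ndarray, tau: float,
             prior_H0: float = 1.0) -> FdrEstimate:
    """Permutation Fdr estimators at threshold tau.

    The single-test estimator compares per-cell exceedance fractions of
    synthetic-null and knockout z statistics; the complete-null variant
    uses max_p |z_pg| per line.  No knockout exceedances returns 0 by
    convention, flagged.  Estimates are clipped to [0, 1].
    """
    z_null = np.asarray(z_null, dtype=float)
    z_ko = np.asarray(z_ko, dtype=float)
    if z_null.size == 0:
        raise ValueError("null set is empty")
    obs_null = ~np.isnan(z_null)
    obs_ko = ~np.isnan(z_ko)
    frac_null = np.mean(np.abs(z_null[obs_null]) >= tau)
    frac_ko = np.mean(np.abs(z_ko[obs_ko]) >= tau)
    flag = False
    if frac_ko == 0:
        single, flag = 0.0, True
    else:
        single = prior_H0 * frac_null / frac_ko
    max_null = _line_max_abs(z_null)
    max_ko = _line_max_abs(z_ko)
    cfrac_null = np.mean(max_null >= tau)
    cfrac_ko = np.mean(max_ko >= tau)
    if cfrac_ko == 0:
        complete, flag = 0.0, True
    else:
        complete = prior_H0 * cfrac_null / cfrac_ko
    return FdrEstimate(
        tau=tau,
        fdr_single=float(np.clip(single, 0.0, 1.0)),
        fdr_complete=float(np.clip(complete, 0.0, 1.0)),
        prior_H0=prior_H0,
        no_ko_exceedance=flag,
    )


def select_tau(z_ko: np.ndarray, z_null: np.ndarray, alpha: float,
               prior_H0: float = 1.0) -> float:
    """Smallest threshold controlling the complete-null Fdr at alpha.

    Candidates are the observed per-line max |z| over knockout and null
    lines; returns +inf when no candidate with at least one knockout
    exceedance satisfies the bound (no callable hits).
    """
    max_ko = np.sort(_line_max_abs(np.asarray(z_ko, dtype=float)))
    max_null = np.sort(_line_max_abs(np.asarray(z_null, dtype=float)))
    if max_null.size == 0:
        raise ValueError("null set is empty")
    cand = np.unique(np.concatenate([max_ko, max_null]))
    n_ko, n_null = max_ko.size, max_null.size
    # exceedance fractions at each candidate (>= tau)
    frac_ko = 1.0 - np.searchsorted(max_ko, cand, side="left") / n_ko
    frac_null = 1.0 - np.searchsorted(max_null, cand, side="left") / n_null
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = prior_H0 * frac_null / frac_ko
    ok = (frac_ko > 0) & (fdr <= alpha)
    if not ok.any():
        return float("inf")
    return float(cand[ok][0])


def lfsr(post: PosteriorMixture, phenotype: int) -> float:
    """Local false sign rate for one phenotype of a posterior mixture.

    Minimum of the two signed tail probabilities P(theta >= 0) and
    P(theta <= 0) under the marginal Gaussian mixture.
    """
    w, mu, V = post.flat_components()
    m = mu[:, phenotype]
    s = np.sqrt(np.maximum(V[:, phenotype, phenotype], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        zc = np.where(s > 0, m / np.where(s > 0, s, 1.0), np.inf * np.sign(m))
    zc = np.where((s == 0) & (m == 0), 0.0, zc)
    p_le0 = float(w @ stats.norm.sf(zc))  # P(theta <= 0)
    p_ge0 = float(w @ stats.norm.cdf(zc))  # P(theta >= 0)
    return float(min(p_le0, p_ge0))


def lfsr_matrix(posteriors: list[PosteriorMixture]) -> np.ndarray:
    """lfsr for every (phenotype, line) pair, columns indexing lines."""
    P = posteriors[0].mean.shape[0]
    out = np.empty((P, len(posteriors)))
    for j, post in enumerate(posteriors):
        for p in range(P):
            out[p, j] = lfsr(post, p)
    return out


def call_annotations(stat: np.ndarray, tau: float, mode: str = "z",
                     signs: np.ndarray | None = None) -> np.ndarray:
    """Signed annotation calls in {-1, 0, +1}.

    In ``z`` mode a call fires when |stat| > tau with the statistic's
    sign; in ``lfsr`` mode when stat < tau, signed by the accompanying
    posterior-mean ``signs`` matrix.  NaN statistics never fire.
    """
    stat = np.asarray(stat, dtype=float)
    calls = np.zeros(stat.shape, dtype=int)
    if mode == "z":
        with np.errstate(invalid="ignore"):
            fire = np.abs(stat) > tau
        calls[fire] = np.sign(stat[fire]).astype(int)
    elif mode == "lfsr":
        if signs is None:
            raise ValueError("lfsr mode requires a signs matrix")
        signs = np.asarray(signs, dtype=float)
        with np.errstate(invalid="ignore"):
            fire = stat < tau
        calls[fire] = np.sign(signs[fire]).astype(int)
    else:
        raise ValueError("mode must be 'z' or 'lfsr'")
    return calls


@dataclass
class ReplicabilityTable:
    """3x3 cross-tabulation of signed calls from two contexts.

    counts[i, j] counts pairs with call i-1 in context A and j-1 in B.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3):
            raise ValueError("counts must be 3x3")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_counts(cls, n_concordant: int, n_discordant: int
                    ) -> "ReplicabilityTable":
        """Table carrying only the both-significant cells (all that the
        false-sign-rate estimator uses)."""
        counts = np.zeros((3, 3), dtype=int)
        counts[2, 2] = n_concordant  # split is immaterial to the estimator
        counts[2, 0] = n_discordant
        return cls(counts)

    @property
    def n_concordant(self) -> int:
        return int(self.counts[0, 0] + self.counts[2, 2])

    @property
    def n_discordant(self) -> int:
        return int(self.counts[0, 2] + self.counts[2, 0])


def replicability_table(calls_a: np.ndarray, calls_b: np.ndarray
                        ) -> ReplicabilityTable:
    """Cross-tabulate signed calls over shared (phenotype, line) pairs."""
    calls_a = np.asarray(calls_a)
    calls_b = np.asarray(calls_b)
    if calls_a.shape != calls_b.shape:
        raise ValueError("call matrices are misaligned")
    counts = np.zeros((3, 3), dtype=int)
    for a in (-1, 0, 1):
        for b in (-1, 0, 1):
            counts[a + 1, b + 1] = int(
                np.sum((calls_a == a) & (calls_b == b)))
    return ReplicabilityTable(counts)


@dataclass
class FsrEstimate:
    q_hat: float
    fsr: float
    ci_low: float
    ci_high: float
    psi_assumed: float = 0.0


def _fsr_map(q: float) -> float:
    """Fsr = (1 - sqrt(1 - 2q)) / 2, the inverse of q = 2 Fsr (1-Fsr)."""
    return 0.5 * (1.0 - np.sqrt(max(1.0 - 2.0 * q, 0.0)))


def fsr_replicate(table: ReplicabilityTable) -> FsrEstimate:
    """Replicate-based false-sign-rate estimate with 95% CI.

    q_hat is the discordant fraction among both-significant pairs;
    Fsr = (1 - sqrt(1 - 2 q_hat)) / 2 under the conservative assumption
    that the double-false-discovery probability psi is 0.  The CI maps
    Clopper-Pearson exact binomial bounds for q through the same
    transform.
    """
    disc, conc = table.n_discordant, table.n_concordant
    n = disc + conc
    if n < 1:
        raise ValueError("no information: no both-significant pairs")
    q_hat = disc / n
    if q_hat > 0.5:
        raise ValueError(
            "discordance above 1/2: false-sign rate not identifiable")
    lo, hi = _clopper_pearson(disc, n)
    return FsrEstimate(
        q_hat=q_hat,
        fsr=_fsr_map(q_hat),
        ci_low=_fsr_map(lo),
        ci_high=_fsr_map(min(hi, 0.5)),
    )


def _clopper_pearson(k: int, n: int, level: float = 0.95
                     ) -> tuple[float, float]:
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - a, k + 1, n - k))
    return lo, hi


def impc_gene_set(calls: np.ndarray, theta_mv: np.ndarray,
                  line_filter: np.ndarray | None = None
                  ) -> list[np.ndarray]:
    """Per-phenotype hit gene sets with a 2-SD effect-size filter.

    A line enters phenotype p's set when it is called significant and
    |theta_mv[p, g]| exceeds twice the sample SD of theta_mv[p, :]
    across lines.  ``line_filter`` optionally restricts eligibility
    (e.g. homozygotes only).
    """
    calls = np.asarray(calls)
    theta_mv = np.asarray(theta_mv, dtype=float)
    P, G = theta_mv.shape
    eligible = np.ones(G, dtype=bool) if line_filter is None \
        else np.asarray(line_filter, dtype=bool)
    out = []
    for p in range(P):
        sd_p = float(np.std(theta_mv[p], ddof=1))
        if sd_p == 0:
            warnings.warn(f"phenotype {p}: zero effect-size SD, empty set",
                          RuntimeWarning)
            out.append(np.array([], dtype=int))
            continue
        keep = (calls[p] != 0) & (np.abs(theta_mv[p]) > 2.0 * sd_p) & eligible
        out.append(np.flatnonzero(keep))
    return out


def fisher_2x2(table: np.ndarray) -> dict[str, float]:
    """Sample odds ratio and two-sided Fisher exact p for a 2x2 table.

    The p-value uses the minimum-likelihood convention of the exact
    hypergeometric test; a zero margin makes the odds ratio undefined
    (NaN) with p = 1.
    """
    table = np.asarray(table)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return {"odds_ratio": float("nan"), "p_value": 1.0}
    a, b, c, d = table.ravel().astype(float)
    odds = a * d / (b * c) if b * c > 0 else float("inf")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return {"odds_ratio": float(odds), "p_value": float(p)}


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return stats.false_discovery_control(np.asarray(pvals, dtype=float),
                                         method="bh")


def directionality_prior(calls: np.ndarray, estimates: np.ndarray) -> float:
    """Empirical prior probability of a positive direction given a hit.

    Aggregates one phenotype's called hits across lines: the fraction of
    nonzero calls whose effect estimate is positive.
    """
    calls = np.asarray(calls)
    estimates = np.asarray(estimates, dtype=float)
    hit = calls != 0
    if not hit.any():
        raise ValueError("no called hits at this phenotype")
    return float(np.mean(estimates[hit] > 0))


def bayes_factor(priors: np.ndarray, signs_a: np.ndarray,
                 signs_b: np.ndarray) -> float:
    """Bayes factor for disputed signed calls between two methods.

    Each dispute carries the phenotype's prior probability of a positive
    direction; the factor is the ratio of products of per-call prior
    probabilities under method A's signs versus method B's.
    """
    priors = np.asarray(priors, dtype=float)
    signs_a = np.asarray(signs_a)
    signs_b = np.asarray(signs_b)
    p_a = np.where(signs_a > 0, priors, 1.0 - priors)
    p_b = np.where(signs_b > 0, priors, 1.0 - priors)
    return float(np.prod(p_a) / np.prod(p_b))
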