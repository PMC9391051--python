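"""Synthetic data with the model's assumed structure.

Generators at two levels: UV-output level (effect estimates plus
correlated heteroscedastic noise, drawn from the scale-ladder mixture)
and animal level (rolling wild-type baseline with day/litter random
intercepts and smooth drift).  Block-wise masking by (centre, procedure)
emulates the missing-at-random structure of multi-centre screens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import UVResultTable, WT_LINE


def exchangeable_corr(P: int, rho: float) -> np.ndarray:
    """Correlation matrix with common off-diagonal rho."""
    return np.full((P, P), rho) + (1.0 - rho) * np.eye(P)


def random_factor_covariance(
    P: int,
    K: int,
    rng: np.random.Generator,
    loading_scale: float = 1.0,
    psi_scale: float = 0.3,
    sparsity: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Random (W, psi) pair defining Sigma = W W^T + diag(psi)."""
    W = rng.normal(0.0, loading_scale, size=(P, K))
    if sparsity > 0:
        W *= rng.random((P, K)) > sparsity
    psi = psi_scale * (0.5 + rng.random(P))
    return W, psi


@dataclass
class SimSpec:
    """Generative configuration for UV-level simulation.

    Defaults describe a moderate multi-phenotype screen: P = 15
    phenotypes, G = 400 knockout lines of which half are complete nulls,
    a K = 5 factor covariance shape, an M = 5 geometric scale ladder,
    and lognormal standard errors centred near 0.3 on the unit-SD
    standardised effect scale (typical per-cell power is moderate, as in
    ~14-animal cohorts).
    """

    P: int = 15
    G: int = 400
    K_true: int = 5
    S_true: int = 1
    M_true: int = 5
    omega_true: np.ndarray | None = None
    pi_true: np.ndarray | None = None
    W_true: list[np.ndarray] | None = None
    Psi_true: list[np.ndarray] | None = None
    R_true: np.ndarray | None = None
    se_law: tuple[float, float] = (np.log(0.3), 0.3)
    n_centres: int = 1
    n_procedures: int = 3
    missing_blocks: list[tuple[str, str]] = field(default_factory=list)
    null_fraction: float = 0.5
    seed: int = 0

    def materialise(self, rng: np.random.Generator) -> "SimSpec":
        """Fill in unspecified structural parameters reproducibly."""
        if self.omega_true is None:
            # geometric ladder centred at 1
            half = (self.M_true - 1) // 2
            self.omega_true = 2.0 ** np.arange(-half, self.M_true - half)
        self.omega_true = np.asarray(self.omega_true, dtype=float)
        if self.pi_true is None:
            self.pi_true = np.full(
                (self.M_true, self.S_true), 1.0 / (self.M_true * self.S_true))
        self.pi_true = np.asarray(self.pi_true, dtype=float)
        if self.W_true is None or self.Psi_true is None:
            self.W_true, self.Psi_true = [], []
            for _ in range(self.S_true):
                W, psi = random_factor_covariance(self.P, self.K_true, rng)
                self.W_true.append(W)
                self.Psi_true.append(psi)
        if self.R_true is None:
            self.R_true = np.eye(self.P)
        return self

    def sigma_true(self) -> list[np.ndarray]:
        return [W @ W.T + np.diag(psi)
                for W, psi in zip(self.W_true, self.Psi_true)]


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated table."""

    theta_true: np.ndarray  # (P, G)
    is_null_line: np.ndarray  # (G,) complete-null indicator
    component_labels: np.ndarray  # (G, 2) chosen (m, s); (-1, -1) for nulls


def _procedure_of(phenotypes: list[str], n_procedures: int) -> dict[str, str]:
    P = len(phenotypes)
    bounds = np.array_split(np.arange(P), n_procedures)
    return {
        phenotypes[i]: f"PR{k + 1}"
        for k, idx in enumerate(bounds) for i in idx
    }


def simulate_uv(
    spec: SimSpec, rng: np.random.Generator | None = None
) -> tuple[UVResultTable, SimTruth]:
    """Draw a UV result table from the mixture model's generative law.

    Per line: a (m, s) component from pi (complete-null lines get an
    all-zero effect vector), theta ~ N(0, omega_m Sigma_s), lognormal
    standard errors, and observation noise with covariance S R S; then
    block-wise masking per (centre, procedure).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    spec = spec.materialise(rng)
    P, G = spec.P, spec.G
    phenotypes = [f"P{i + 1:03d}" for i in range(P)]
    lines = [f"KO{j + 1:04d}" for j in range(G)]
    centres = [f"C{1 + j % spec.n_centres}" for j in range(G)]
    sigma = spec.sigma_true()
    chol = [np.linalg.cholesky(s) for s in sigma]
    R_chol = np.linalg.cholesky(spec.R_true)

    n_null = int(round(spec.null_fraction * G))
    is_null = np.zeros(G, dtype=bool)
    is_null[rng.choice(G, size=n_null, replace=False)] = True

    flat_pi = spec.pi_true.reshape(-1)
    comp = rng.choice(flat_pi.size, size=G, p=flat_pi / flat_pi.sum())
    m_idx, s_idx = np.unravel_index(comp, spec.pi_true.shape)

    theta = np.zeros((P, G))
    labels = np.full((G, 2), -1)
    for j in range(G):
        if is_null[j]:
            continue
        m, s = int(m_idx[j]), int(s_idx[j])
        labels[j] = (m, s)
        theta[:, j] = np.sqrt(spec.omega_true[m]) * (
            chol[s] @ rng.standard_normal(P))
    se = rng.lognormal(spec.se_law[0], spec.se_law[1], size=(P, G))
    noise = se * (R_chol @ rng.standard_normal((P, G)))
    estimate = theta + noise

    proc_of = _procedure_of(phenotypes, spec.n_procedures)
    mask = np.zeros((P, G), dtype=bool)  # True = masked
    for centre, proc in spec.missing_blocks:
        rows = [i for i, p in enumerate(phenotypes) if proc_of[p] == proc]
        cols = [j for j in range(G) if centres[j] == centre]
        mask[np.ix_(rows, cols)] = True
    estimate = np.where(mask, np.nan, estimate)
    se_out = np.where(mask, np.nan, se)

    uv = UVResultTable(
        phenotypes=phenotypes,
        lines=lines,
        centre_of_line=dict(zip(lines, centres)),
        estimate=estimate,
        se=se_out,
        is_null_line=np.zeros(G, dtype=bool),
    )
    truth = SimTruth(theta_true=theta, is_null_line=is_null,
                     component_labels=labels)
    return uv, truth


def simulate_null_uv(
    spec: SimSpec, n_null: int, rng: np.random.Generator
) -> UVResultTable:
    """Matched synthetic-null UV table: zero effects, same noise law."""
    null_spec = SimSpec(**{**spec.__dict__, "G": n_null, "null_fraction": 1.0})
    uv, _ = simulate_uv(null_spec, rng)
    uv.lines = [f"NULL{j + 1:04d}" for j in range(n_null)]
    uv.centre_of_line = dict(zip(uv.lines, [f"C{1 + j % spec.n_centres}"
                                            for j in range(n_null)]))
    uv.is_null_line = np.ones(n_null, dtype=bool)
    return uv


# ---------------------------------------------------------------------------
# animal level


@dataclass
class AnimalDesign:
    """Experimental-design knobs for animal-level simulation.

    Mirrors a rolling-baseline screen: many small wild-type litters
    spread across the date range, knockout cohorts of a few litters
    (~14 animals in the default 4 x 4 design, split across sexes).
    """

    n_wt_litters: int = 40
    wt_litter_size: int = 4
    n_ko_litters: int = 4
    ko_litter_size: int = 4
    day_span: int = 360
    drift_amplitude: float = 0.0
    drift_period: float = 180.0
    sigma_day: float = 0.0
    sigma_litter: float = 0.0
    sigma_resid: float = 1.0
    sex_effect: float = 0.0


def simulate_animals(
    theta: np.ndarray,
    lines: list[str],
    phenotypes: list[str],
    design: AnimalDesign,
    rng: np.random.Generator,
    centre: str = "C1",
    n_procedures: int = 1,
) -> tuple[pd.DataFrame, SimTruth]:
    """Animal-level table from the linear multilevel generative law.

    Wild-type animals form a rolling baseline with smooth sinusoidal
    drift and day/litter random intercepts; each knockout line is
    measured in ``n_ko_litters`` litters at random dates with effect
    theta[p, g] added to every animal of line g at phenotype p.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    P, G = theta.shape
    if len(lines) != G or len(phenotypes) != P:
        raise ValueError("theta shape inconsistent with labels")
    proc_of = _procedure_of(phenotypes, n_procedures)

    day_effect: dict[int, float] = {}
    litter_effect: dict[str, float] = {}

    def _day_re(day: int) -> float:
        if day not in day_effect:
            day_effect[day] = rng.normal(0.0, design.sigma_day)
        return day_effect[day]

    rows = []
    animal_counter = 0

    def _add_cohort(line_id: str, zygosity: str, n_litters: int,
                    litter_size: int, days: np.ndarray,
                    theta_col: np.ndarray) -> None:
        nonlocal animal_counter
        for li in range(n_litters):
            litter_id = f"{line_id}_L{li + 1}"
            litter_effect[litter_id] = rng.normal(0.0, design.sigma_litter)
            day = int(days[li])
            for a in range(litter_size):
                animal_counter += 1
                animal_id = f"A{animal_counter:06d}"
                sex = "F" if a % 2 == 0 else "M"
                base = (
                    design.drift_amplitude
                    * np.sin(2.0 * np.pi * day / design.drift_period)
                    + _day_re(day)
                    + litter_effect[litter_id]
                    + (design.sex_effect if sex == "M" else 0.0)
                )
                resid = rng.normal(0.0, design.sigma_resid, size=P)
                for p in range(P):
                    rows.append(
                        (animal_id, line_id, zygosity, sex, centre,
                         proc_of[phenotypes[p]], phenotypes[p], day,
                         litter_id, base + theta_col[p] + resid[p])
                    )

    wt_days = np.linspace(0, design.day_span, design.n_wt_litters).round()
    _add_cohort(WT_LINE, "wt", design.n_wt_litters, design.wt_litter_size,
                wt_days, np.zeros(P))
    for j, line in enumerate(lines):
        ko_days = rng.integers(0, design.day_span + 1,
                               size=design.n_ko_litters)
        _add_cohort(line, "hom", design.n_ko_litters, design.ko_litter_size,
                    np.sort(ko_days), theta[:, j])

    animals = pd.DataFrame(
        rows,
        columns=["animal_id", "line_id", "zygosity", "sex", "centre",
                 "procedure", "phenotype", "date", "litter_id", "value"],
    )
    truth = SimTruth(theta_true=theta,
                     is_null_line=(np.abs(theta).max(axis=0) == 0),
                     component_labels=np.full((G, 2), -1))
    return animals, truth


def mask_procedure(
    uv: UVResultTable, line: str, phenotypes: list[str]
) -> UVResultTable:
    """Mask one line's block of phenotypes (a measured procedure).

    Used by the mask-predict-compare harness: the returned table has the
    block removed while the input is left untouched for comparison.
    """
    j = uv.lines.index(line)
    rows = [uv.phenotypes.index(p) for p in phenotypes]
    if np.isnan(uv.estimate[rows, j]).all():
        raise ValueError(f"block ({line}, {phenotypes}) is already missing")
    estimate = uv.estimate.copy()
    se = uv.se.copy()
    estimate[rows, j] = np.nan
    se[rows, j] = np.nan
    return UVResultTable(
        phenotypes=list(uv.phenotypes),
        lines=list(uv.lines),
        centre_of_line=dict(uv.centre_of_line),
        estimate=estimate,
        se=se,
        is_null_line=uv.is_null_line.copy(),
    )


def symmetrized_kl(sigma_a: np.ndarray, sigma_b: np.ndarray) -> float:
    """Symmetrized KL divergence between N(0, Sigma_a) and N(0, Sigma_b).

    Closed form 0.5 * [tr(Sigma_b^-1 Sigma_a) + tr(Sigma_a^-1 Sigma_b) - 2P].
    """
    sigma_a = np.atleast_2d(np.asarray(sigma_a, dtype=float))
    sigma_b = np.atleast_2d(np.asarray(sigma_b, dtype=float))
    if sigma_a.shape != sigma_b.shape:
        raise ValueError("covariance dimensions differ")
    P = sigma_a.shape[0]
    t1 = np.trace(np.linalg.solve(sigma_b, sigma_a))
    t2 = np.trace(np.linalg.solve(sigma_a, sigma_b))
    return 0.5 * float(t1 + t2 - 2 * P)
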