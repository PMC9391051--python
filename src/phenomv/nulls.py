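"""Synthetic null lines and the experimental noise correlation.

A synthetic null line is a design-matched resample of wild-type
animals: for each litter of a template knockout line, a wild-type
litter at the same centre with at least as many animals is drawn, with
litters measured closer in time preferred, and the required number of
animals sampled from it.  Null lines are true complete nulls by
construction and drive both permutation error-rate control and the
estimate of the noise correlation R.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import UVResultTable, WT_LINE

logger = logging.getLogger("phenomv")


@dataclass
class NullLineDesign:
    """Litter-structure template for one synthetic null line."""

    template_line: str
    centre: str
    litters: list[tuple[int, int]]  # (size l, first day d)

    def __post_init__(self) -> None:
        if any(l < 1 for l, _ in self.litters):
            raise ValueError("litter sizes must be >= 1")


def design_from_line(animals: pd.DataFrame, line_id: str) -> NullLineDesign:
    """Extract the litter design (sizes and first days) of a KO line."""
    sub = animals[animals["line_id"] == line_id]
    if sub.empty:
        raise ValueError(f"line {line_id} not present")
    centre = sub["centre"].iloc[0]
    litters = []
    for _, lit in sub.groupby("litter_id"):
        litters.append((lit["animal_id"].nunique(), int(lit["date"].min())))
    return NullLineDesign(template_line=line_id, centre=centre,
                          litters=sorted(litters, key=lambda t: t[1]))


def make_synthetic_null(
    design: NullLineDesign,
    wt: pd.DataFrame,
    rng: np.random.Generator,
    null_id: str = "NULL1",
    decay: float = 1.0,
) -> pd.DataFrame:
    """Assemble one synthetic null line from wild-type animals.

    For each template litter (l, d), an eligible WT litter (same centre,
    >= l animals) is drawn with probability proportional to
    1 / (1 + decay * |litter day - d|), then l animals are sampled from
    it without replacement.  A WT litter is used at most once per null
    line.  Returned rows are relabelled with ``null_id``.
    """
    pool = wt[(wt["line_id"] == WT_LINE) & (wt["centre"] == design.centre)]
    litter_info = (
        pool.groupby("litter_id")
        .agg(n_animals=("animal_id", "nunique"), day=("date", "min"))
        .reset_index()
    )
    used: set[str] = set()
    chunks = []
    for l, d in design.litters:
        elig = litter_info[
            (litter_info["n_animals"] >= l)
            & ~litter_info["litter_id"].isin(used)
        ]
        if elig.empty:
            raise ValueError(
                f"no eligible WT litter at centre {design.centre} "
                f"for litter size {l}")
        w = 1.0 / (1.0 + decay * np.abs(elig["day"].to_numpy() - d))
        chosen = elig["litter_id"].to_numpy()[
            rng.choice(len(elig), p=w / w.sum())]
        used.add(chosen)
        ids = pool.loc[pool["litter_id"] == chosen, "animal_id"].unique()
        take = rng.choice(ids, size=l, replace=False)
        chunks.append(pool[pool["animal_id"].isin(take)])
    out = pd.concat(chunks, ignore_index=True).copy()
    out["line_id"] = null_id
    return out


@dataclass
class NoiseCorrelation:
    """Estimated experimental noise correlation with PD shrinkage."""

    R: np.ndarray
    n_pairs: np.ndarray
    shrinkage: float

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if not np.allclose(R, R.T):
            raise ValueError("R must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("R must have unit diagonal")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("R must be positive definite after shrinkage")


def estimate_R(
    null_uv: UVResultTable,
    min_pairs: int = 5,
    eig_floor: float = 1e-4,
) -> NoiseCorrelation:
    """Noise correlation from synthetic-null z-scores.

    Pairwise-complete correlation of z = estimate/se across null lines
    (z-scores rather than raw estimates so heteroscedastic standard
    errors cancel), with per-pair complete-case counts recorded; pairs
    with fewer than ``min_pairs`` complete cases are zeroed with a
    warning.  Linear shrinkage towards the identity with the smallest
    gamma in {0, 0.01, ...} making the smallest eigenvalue >= 1e-4.
    """
    if null_uv.n_lines < 30:
        raise ValueError("need at least 30 null lines to estimate R")
    z = pd.DataFrame(null_uv.z.T)  # lines x phenotypes
    P = null_uv.n_phenotypes
    obs = (~np.isnan(null_uv.z)).astype(int)
    n_pairs = obs @ obs.T
    if P == 1:
        return NoiseCorrelation(R=np.eye(1), n_pairs=n_pairs, shrinkage=0.0)
    corr = z.corr(min_periods=2).to_numpy()
    corr = np.where(np.isnan(corr), 0.0, corr)
    thin = (n_pairs < min_pairs) & ~np.eye(P, dtype=bool)
    if thin.any():
        warnings.warn(
            f"{int(thin.sum() // 2)} phenotype pair(s) with fewer than "
            f"{min_pairs} complete null cases set to 0", RuntimeWarning)
        corr[thin] = 0.0
    corr = 0.5 * (corr + corr.T)
    np.fill_diagonal(corr, 1.0)
    gamma = 0.0
    R = corr
    while np.linalg.eigvalsh(R).min() < eig_floor:
        gamma = round(gamma + 0.01, 10)
        if gamma >= 1.0:
            R = np.eye(P)
            gamma = 1.0
            break
        R = (1.0 - gamma) * corr + gamma * np.eye(P)
    np.fill_diagonal(R, 1.0)
    logger.info("estimated R from %d null lines (shrinkage %.2f)",
                null_uv.n_lines, gamma)
    return NoiseCorrelation(R=R, n_pairs=n_pairs, shrinkage=gamma)
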