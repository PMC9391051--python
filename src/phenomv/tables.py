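"""Shared data model and file formats.

All matrices are phenotype-major (P x G): rows index phenotypes, columns
index lines.  Missing cells are encoded as absent rows in long-format TSV
and as NaN in memory; orderings are lexicographic and therefore
deterministic given the input content.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("phenomv")

#: line id reserved for wild-type control animals
WT_LINE = "WT"

ANIMAL_COLUMNS = [
    "animal_id",
    "line_id",
    "zygosity",
    "sex",
    "centre",
    "procedure",
    "phenotype",
    "date",
    "litter_id",
    "value",
]

ZYGOSITIES = {"het", "hom", "wt"}
SEXES = {"F", "M"}


def validate_animal_table(animals: pd.DataFrame) -> pd.DataFrame:
    """Validate an animal-level phenotype table.

    Checks column presence, uniqueness of (animal_id, phenotype),
    nonnegative dates, zygosity/sex domains, the WT zygosity convention
    and that every knockout line maps to a single centre.  Returns the
    (unmodified) frame so calls can be chained.
    """
    missing = [c for c in ANIMAL_COLUMNS if c not in animals.columns]
    if missing:
        raise ValueError(f"animal table missing columns: {missing}")
    dup = animals.duplicated(subset=["animal_id", "phenotype"])
    if dup.any():
        row = animals[dup].iloc[0]
        raise ValueError(
            f"duplicate (animal_id, phenotype) row: "
            f"({row['animal_id']}, {row['phenotype']})"
        )
    if (animals["date"] < 0).any():
        raise ValueError("dates must be >= 0")
    bad_zyg = set(animals["zygosity"]) - ZYGOSITIES
    if bad_zyg:
        raise ValueError(f"unknown zygosity values: {sorted(bad_zyg)}")
    bad_sex = set(animals["sex"]) - SEXES
    if bad_sex:
        raise ValueError(f"unknown sex values: {sorted(bad_sex)}")
    wt = animals["line_id"] == WT_LINE
    if (animals.loc[wt, "zygosity"] != "wt").any():
        raise ValueError("WT rows must have zygosity 'wt'")
    ko = animals.loc[~wt]
    n_centres = ko.groupby("line_id")["centre"].nunique()
    multi = n_centres[n_centres > 1]
    if len(multi):
        raise ValueError(
            f"lines measured in more than one centre: {list(multi.index)}"
        )
    return animals


def read_animal_table(path: str | Path) -> pd.DataFrame:
    animals = pd.read_csv(path, sep="\t", dtype={"animal_id": str, "line_id": str,
                                                 "litter_id": str})
    return validate_animal_table(animals)


def write_animal_table(animals: pd.DataFrame, path: str | Path) -> None:
    validate_animal_table(animals)
    animals.to_csv(path, sep="\t", index=False)


@dataclass
class UVResultTable:
    """Per-(phenotype, line) estimates and standard errors.

    ``estimate`` and ``se`` are P x G arrays with NaN at unobserved
    cells; ``is_null_line`` flags synthetic null lines assembled from
    wild-type animals.
    """

    phenotypes: list[str]
    lines: list[str]
    centre_of_line: dict[str, str]
    estimate: np.ndarray
    se: np.ndarray
    is_null_line: np.ndarray
    scale_factors: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.estimate = np.asarray(self.estimate, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.is_null_line = np.asarray(self.is_null_line, dtype=bool)
        P, G = self.estimate.shape
        if len(self.phenotypes) != P or len(self.lines) != G:
            raise ValueError("matrix shape inconsistent with axis labels")
        if self.se.shape != (P, G):
            raise ValueError("se shape mismatch")
        if self.is_null_line.shape != (G,):
            raise ValueError("is_null_line shape mismatch")
        if not np.array_equal(np.isnan(self.estimate), np.isnan(self.se)):
            raise ValueError("se must be present iff estimate is present")
        with np.errstate(invalid="ignore"):
            if np.any(self.se <= 0):
                raise ValueError("standard errors must be positive")
        if P and G and not self.observed_mask.any(axis=0).all():
            empty = [self.lines[j] for j in
                     np.flatnonzero(~self.observed_mask.any(axis=0))]
            raise ValueError(f"lines with no observed cells: {empty}")

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotypes)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.estimate)

    @property
    def z(self) -> np.ndarray:
        """z-statistics theta-hat / se (NaN at missing cells)."""
        with np.errstate(invalid="ignore"):
            return self.estimate / self.se

    def centres(self) -> np.ndarray:
        return np.asarray([self.centre_of_line[g] for g in self.lines])

    def subset_lines(self, idx: Sequence[int] | np.ndarray) -> "UVResultTable":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        lines = [self.lines[j] for j in idx]
        return UVResultTable(
            phenotypes=list(self.phenotypes),
            lines=lines,
            centre_of_line={g: self.centre_of_line[g] for g in lines},
            estimate=self.estimate[:, idx],
            se=self.se[:, idx],
            is_null_line=self.is_null_line[idx],
        )

    def to_long(self) -> pd.DataFrame:
        P, G = self.estimate.shape
        obs = self.observed_mask
        pi, gi = np.nonzero(obs)
        return pd.DataFrame(
            {
                "phenotype": np.asarray(self.phenotypes)[pi],
                "line": np.asarray(self.lines)[gi],
                "centre": [self.centre_of_line[self.lines[j]] for j in gi],
                "estimate": self.estimate[pi, gi],
                "se": self.se[pi, gi],
                "is_null": self.is_null_line[gi].astype(int),
            }
        )


def concat_lines(a: UVResultTable, b: UVResultTable) -> UVResultTable:
    """Concatenate two tables over lines (phenotype axes must match)."""
    if a.phenotypes != b.phenotypes:
        raise ValueError("phenotype axes differ")
    if set(a.lines) & set(b.lines):
        raise ValueError("line ids overlap")
    return UVResultTable(
        phenotypes=list(a.phenotypes),
        lines=a.lines + b.lines,
        centre_of_line={**a.centre_of_line, **b.centre_of_line},
        estimate=np.concatenate([a.estimate, b.estimate], axis=1),
        se=np.concatenate([a.se, b.se], axis=1),
        is_null_line=np.concatenate([a.is_null_line, b.is_null_line]),
    )


def read_uv_table(path: str | Path) -> UVResultTable:
    """Read a long-format UV result TSV into matrix layout.

    Phenotype and line orderings are lexicographic; cells with no row
    are missing.  Duplicate (phenotype, line) rows and nonpositive
    standard errors are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"phenotype": str, "line": str,
                                            "centre": str},
                     float_precision="round_trip")
    required = {"phenotype", "line", "centre", "estimate", "se", "is_null"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"UV table missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["phenotype", "line"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate (phenotype, line) row: ({row['phenotype']}, {row['line']})"
        )
    bad_se = df["se"] <= 0
    if bad_se.any():
        row = df[bad_se].iloc[0]
        raise ValueError(
            f"nonpositive se at (phenotype={row['phenotype']}, line={row['line']})"
        )
    phenotypes = sorted(df["phenotype"].unique())
    lines = sorted(df["line"].unique())
    p_idx = {p: i for i, p in enumerate(phenotypes)}
    g_idx = {g: j for j, g in enumerate(lines)}
    P, G = len(phenotypes), len(lines)
    estimate = np.full((P, G), np.nan)
    se = np.full((P, G), np.nan)
    rows = df["phenotype"].map(p_idx).to_numpy()
    cols = df["line"].map(g_idx).to_numpy()
    estimate[rows, cols] = df["estimate"].to_numpy()
    se[rows, cols] = df["se"].to_numpy()
    centre_of_line = dict(df.groupby("line")["centre"].first())
    null_of_line = df.groupby("line")["is_null"].first()
    is_null = np.asarray([bool(null_of_line[g]) for g in lines])
    table = UVResultTable(phenotypes, lines, centre_of_line, estimate, se, is_null)
    logger.info(
        "read UV table: %d phenotypes, %d lines, %d missing cells",
        P, G, int((~table.observed_mask).sum()),
    )
    return table


def write_uv_table(uv: UVResultTable, path: str | Path) -> None:
    # default float repr is shortest-round-trip; keep full precision
    uv.to_long().to_csv(path, sep="\t", index=False)


def write_annotations(
    calls: np.ndarray,
    uv: UVResultTable,
    path: str | Path,
    z: np.ndarray | None = None,
    tau: float | None = None,
) -> None:
    """Write signed annotation calls as long-format TSV.

    One row per (phenotype, line) cell in stable (lexicographic-axis)
    order, with the z statistic and its tau-scaled version alongside.
    """
    calls = np.asarray(calls)
    if calls.shape != (uv.n_phenotypes, uv.n_lines):
        raise ValueError("calls shape does not match UV table")
    if z is None:
        z = np.full(calls.shape, np.nan)
    z_scaled = z / tau if tau not in (None, 0) else np.full(calls.shape, np.nan)
    P, G = calls.shape
    pi, gi = np.unravel_index(np.arange(P * G), (P, G))
    pd.DataFrame(
        {
            "phenotype": np.asarray(uv.phenotypes)[pi],
            "line": np.asarray(uv.lines)[gi],
            "call": calls[pi, gi].astype(int),
            "z": z[pi, gi],
            "z_scaled": z_scaled[pi, gi],
        }
    ).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


@dataclass
class RunConfig:
    """Run-level configuration shared by all stages.

    K is the factor rank, S the number of mixture covariance shapes and
    ``omega_ladder`` the fixed scale grid of the mixture prior.  The
    default ladder is geometric, 2^-4 ... 2^4, so one learned covariance
    shape can serve effects spanning two orders of magnitude.
    """

    K: int = 20
    S: int = 1
    omega_ladder: tuple[float, ...] = tuple(2.0 ** k for k in range(-4, 5))
    C: int = 10
    N_tra: int = 2000
    alpha: float = 0.05
    eps_jitter: float = 0.05
    eps_tol: float = 1e-4
    seed: int = 0
    prior_H0: float = 1.0
    # multiply (paper's printed rule) or divide N_tra into the EM tolerance
    tol_scale_mode: str = "multiply"

    def __post_init__(self) -> None:
        if self.K < 1 or self.S < 1 or self.C < 1 or self.N_tra < 1:
            raise ValueError("K, S, C, N_tra must be positive")
        om = np.asarray(self.omega_ladder, dtype=float)
        if om.ndim != 1 or len(om) == 0 or np.any(om <= 0):
            raise ValueError("omega_ladder must be positive reals")
        if np.any(np.diff(om) <= 0):
            raise ValueError("omega_ladder must be strictly increasing")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.prior_H0 <= 1:
            raise ValueError("prior_H0 must lie in (0, 1]")
        if self.eps_jitter <= 0 or self.eps_tol <= 0:
            raise ValueError("eps_jitter and eps_tol must be positive")
        if self.tol_scale_mode not in ("multiply", "divide"):
            raise ValueError("tol_scale_mode must be 'multiply' or 'divide'")

    @property
    def M(self) -> int:
        return len(self.omega_ladder)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "omega_ladder" in raw:
            raw["omega_ladder"] = tuple(raw["omega_ladder"])
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["omega_ladder"] = list(self.omega_ladder)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)
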