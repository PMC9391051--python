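"""Univariate stage: per-(phenotype, line) effect estimation and QC.

Each knockout line is compared against the rolling wild-type baseline
of its centre with a linear mixed model: genotype main effect (the
quantity of interest), sex and sex-genotype interaction as fixed terms,
random day and litter intercepts, and a penalised B-spline of date
absorbing slow baseline drift.  Estimation is by REML; the estimate and
its standard error stand in for the posterior mean/SD of a Bayesian
multilevel fit under noninformative priors.

Downstream filters drop centre-procedure blocks with anomalous
longitudinal trends, drop sparsely measured phenotypes, and standardise
estimates to unit SD within each (phenotype, centre).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .tables import UVResultTable, WT_LINE

logger = logging.getLogger("phenomv")


# ---------------------------------------------------------------------------
# Box-Cox


def boxcox_transform(
    values: np.ndarray, lmbda: float | None = None
) -> tuple[np.ndarray, float, float]:
    """Box-Cox transform with automatic shift and profile-ML lambda.

    Nonpositive inputs are first shifted by (1 - min) so the transform
    is defined; when ``lmbda`` is None it is chosen by profile maximum
    likelihood (grid-free, via scipy's MLE optimiser).  Returns the
    transformed values, the lambda used and the shift applied.
    """
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        raise ValueError("all-constant input: lambda is unidentifiable")
    shift = 0.0
    if values.min() <= 0:
        shift = 1.0 - values.min()
    y = values + shift
    if lmbda is None:
        lmbda = float(stats.boxcox_normmax(y, method="mle"))
    return special.boxcox(y, lmbda), float(lmbda), shift


# ---------------------------------------------------------------------------
# mixed-model fit


@dataclass
class UVModelSpec:
    """Model specification for the univariate mixed model."""

    fixed_terms: tuple[str, ...] = ("sex", "sex_genotype")
    random_terms: tuple[str, ...] = ("date", "litter_id")
    spline_knots: int = 5
    spline_degree: int = 3
    boxcox_lambda: float | None = 1.0  # None: profile ML on WT animals
    apply_boxcox: bool = False

    def __post_init__(self) -> None:
        if self.spline_knots < 0:
            raise ValueError("spline_knots must be >= 0")


@dataclass
class UVFit:
    theta_hat: float
    se: float
    n_ko: int
    n_wt: int
    converged: bool
    boxcox_lambda: float = np.nan
    boxcox_shift: float = 0.0
    diagnostic: str = ""


def _bspline_basis(x: np.ndarray, n_knots: int, degree: int) -> np.ndarray:
    """B-spline basis over the observed range with interior knots at
    quantiles; used as random deviations around the linear trend."""
    from scipy.interpolate import BSpline

    lo, hi = x.min(), x.max()
    if hi == lo or n_knots == 0:
        return np.empty((len(x), 0))
    interior = np.quantile(x, np.linspace(0, 1, n_knots + 2)[1:-1])
    knots = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    n_basis = len(knots) - degree - 1
    design = BSpline.design_matrix(x, knots, degree, extrapolate=True)
    return np.asarray(design.todense())[:, :n_basis]


def fit_uv(animals: pd.DataFrame, spec: UVModelSpec) -> UVFit:
    """Genotype main-effect estimate for one (phenotype, centre, line).

    ``animals`` holds rows for a single phenotype: the knockout cohort
    plus the contemporaneous wild-type baseline.  Sex is coded +-1/2 so
    the genotype coefficient is the average of the sex-specific effects.
    With no random terms and no spline the fit reduces to ordinary least
    squares (and, in a balanced design without covariates, to the
    two-sample mean difference).
    """
    ko = animals[animals["line_id"] != WT_LINE]
    wt = animals[animals["line_id"] == WT_LINE]
    n_ko = ko["animal_id"].nunique()
    n_wt = wt["animal_id"].nunique()
    if n_ko < 2:
        raise ValueError("need at least 2 knockout animals")
    if n_wt < 10:
        raise ValueError("need at least 10 wild-type animals")
    lines = ko["line_id"].unique()
    if len(lines) != 1:
        raise ValueError(f"expected a single knockout line, got {lines}")

    df = animals.copy()
    values = df["value"].to_numpy(dtype=float)
    lam, shift = np.nan, 0.0
    if spec.apply_boxcox:
        lmbda = spec.boxcox_lambda
        if lmbda is None:
            wt_vals = wt["value"].to_numpy(dtype=float)
            off = 1.0 - min(values.min(), 0.0)
            _, lmbda, _ = boxcox_transform(wt_vals + off - 1.0
                                           if wt_vals.min() <= 0 else wt_vals)
        values, lam, shift = boxcox_transform(values, lmbda)
    y = values

    geno = (df["line_id"] != WT_LINE).to_numpy(dtype=float)
    cols = {"const": np.ones(len(df)), "geno": geno}
    if "sex" in spec.fixed_terms:
        sex = np.where(df["sex"] == "M", 0.5, -0.5)
        if np.ptp(sex) > 0:
            cols["sex"] = sex
            if "sex_genotype" in spec.fixed_terms:
                cols["sex_geno"] = sex * geno
    dates = df["date"].to_numpy(dtype=float)
    if spec.spline_knots > 0 and np.ptp(dates) > 0:
        # linear trend is the unpenalised part of the baseline spline
        cols["date_c"] = (dates - dates.mean()) / max(dates.std(), 1.0)
    X = pd.DataFrame(cols)
    # drop aliased columns (keep geno; rank-check via QR)
    keep = ["const", "geno"]
    for name in X.columns:
        if name in keep:
            continue
        trial = X[keep + [name]].to_numpy()
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            keep.append(name)
    X = X[keep]
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        return UVFit(np.nan, np.nan, n_ko, n_wt, converged=False,
                     diagnostic="singular design after aliasing")

    use_day = "date" in spec.random_terms and df["date"].nunique() > 1
    use_litter = ("litter_id" in spec.random_terms
                  and df["litter_id"].nunique() > 1)
    spline = (_bspline_basis(dates, spec.spline_knots, spec.spline_degree)
              if spec.spline_knots > 0 and np.ptp(dates) > 0
              else np.empty((len(df), 0)))

    if not use_day and not use_litter and spline.shape[1] == 0:
        import statsmodels.api as sm

        res = sm.OLS(y, X.to_numpy()).fit()
        j = keep.index("geno")
        return UVFit(float(res.params[j]), float(res.bse[j]), n_ko, n_wt,
                     converged=True, boxcox_lambda=lam, boxcox_shift=shift)

    from statsmodels.regression.mixed_linear_model import MixedLM

    data = X.copy()
    data["y"] = y
    data["date_f"] = df["date"].astype(str).to_numpy()
    data["litter_f"] = df["litter_id"].astype(str).to_numpy()
    for k in range(spline.shape[1]):
        data[f"spl{k}"] = spline[:, k]
    vc = {}
    if use_day:
        vc["day"] = "0 + C(date_f)"
    if use_litter:
        vc["litter"] = "0 + C(litter_f)"
    if spline.shape[1] > 0:
        vc["spline"] = "0 + " + " + ".join(
            f"spl{k}" for k in range(spline.shape[1]))
    fixed = " + ".join(c for c in keep if c != "const")
    data["groups"] = 1
    res = None
    last_exc: Exception | None = None
    for method in ("lbfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = MixedLM.from_formula(
                    f"y ~ {fixed}", groups="groups", vc_formula=vc,
                    data=data)
                trial = model.fit(reml=True, method=method, maxiter=200)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
            continue
        if res is None:
            res = trial
        # prefer an optimiser that reports clean convergence, but a
        # finite REML fit at a variance boundary is still usable
        if bool(getattr(trial, "converged", True)):
            res = trial
            break
    if res is None:
        return UVFit(np.nan, np.nan, n_ko, n_wt, converged=False,
                     diagnostic=f"mixed model failed: {last_exc}")
    if np.any(np.isclose(list(res.vcomp), 0.0, atol=1e-10)):
        warnings.warn("variance component at zero boundary", RuntimeWarning)
    theta = float(res.params["geno"])
    se = float(res.bse["geno"])
    ok = np.isfinite(theta) and np.isfinite(se) and se > 0
    diag = "" if bool(getattr(res, "converged", True)) \
        else "optimizer reported non-convergence; boundary REML fit used"
    return UVFit(theta, se, n_ko, n_wt, converged=ok,
                 boxcox_lambda=lam, boxcox_shift=shift, diagnostic=diag)


def run_uv_stage(
    animals: pd.DataFrame,
    spec: UVModelSpec,
    null_lines: set[str] | None = None,
) -> UVResultTable:
    """Fit the univariate model for every (phenotype, line) pair.

    Lines failing preconditions or convergence are left missing at the
    affected phenotype.  ``null_lines`` flags synthetic null lines in
    the output table.
    """
    null_lines = null_lines or set()
    phenotypes = sorted(animals["phenotype"].unique())
    ko = animals[animals["line_id"] != WT_LINE]
    lines = sorted(ko["line_id"].unique())
    centre_of_line = dict(ko.groupby("line_id")["centre"].first())
    P, G = len(phenotypes), len(lines)
    estimate = np.full((P, G), np.nan)
    se = np.full((P, G), np.nan)
    for j, g in enumerate(lines):
        centre = centre_of_line[g]
        for i, p in enumerate(phenotypes):
            sl = animals[
                (animals["phenotype"] == p)
                & (animals["centre"] == centre)
                & (animals["line_id"].isin([g, WT_LINE]))
            ]
            if sl.empty or (sl["line_id"] == g).sum() == 0:
                continue
            try:
                fit = fit_uv(sl, spec)
            except ValueError:
                continue
            if fit.converged:
                estimate[i, j] = fit.theta_hat
                se[i, j] = fit.se
    observed = ~np.isnan(estimate)
    keep = observed.any(axis=0)
    lines_kept = [g for j, g in enumerate(lines) if keep[j]]
    logger.info("UV stage: %d phenotypes, %d/%d lines with estimates",
                P, len(lines_kept), G)
    return UVResultTable(
        phenotypes=phenotypes,
        lines=lines_kept,
        centre_of_line={g: centre_of_line[g] for g in lines_kept},
        estimate=estimate[:, keep],
        se=se[:, keep],
        is_null_line=np.asarray([g in null_lines for g in lines_kept]),
    )


# ---------------------------------------------------------------------------
# QC and scaling


def qc_longitudinal_filter(
    uv: UVResultTable,
    procedure_of: dict[str, str],
    time_order: dict[str, int],
    threshold: float = 4.0,
    n_boot: int = 200,
    min_lines: int = 20,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Flag centre-procedure blocks with anomalous longitudinal trends.

    For each block, line-level mean estimates are regressed on the
    within-centre time order with the Theil-Sen estimator; the slope is
    standardised by its bootstrap SE and the block dropped when the
    standardised slope exceeds ``threshold`` in magnitude.  Blocks with
    fewer than ``min_lines`` lines are exempted as "insufficient".
    """
    if rng is None:
        rng = np.random.default_rng(0)
    centres = uv.centres()
    records = []
    for centre in np.unique(centres):
        cols = np.flatnonzero(centres == centre)
        order = np.asarray([time_order[uv.lines[j]] for j in cols])
        for proc in sorted(set(procedure_of.values())):
            rows = [i for i, p in enumerate(uv.phenotypes)
                    if procedure_of[p] == proc]
            if not rows:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                y = np.nanmean(uv.estimate[np.ix_(rows, cols)], axis=0)
            ok = ~np.isnan(y)
            x, yy = order[ok].astype(float), y[ok]
            n = ok.sum()
            if n < min_lines:
                records.append((centre, proc, n, np.nan, np.nan, np.nan,
                                "insufficient"))
                continue
            if np.ptp(yy) == 0:
                records.append((centre, proc, n, 0.0, np.nan, 0.0, "kept"))
                continue
            slope = stats.theilslopes(yy, x).slope
            boots = np.empty(n_boot)
            for b in range(n_boot):
                idx = rng.integers(0, n, size=n)
                if np.ptp(x[idx]) == 0:
                    boots[b] = np.nan
                    continue
                boots[b] = stats.theilslopes(yy[idx], x[idx]).slope
            se = np.nanstd(boots, ddof=1)
            stat = slope / se if se > 0 else 0.0
            status = "dropped" if abs(stat) > threshold else "kept"
            records.append((centre, proc, n, slope, se, stat, status))
    report = pd.DataFrame(
        records,
        columns=["centre", "procedure", "n_lines", "slope", "slope_se",
                 "statistic", "status"],
    )
    n_drop = int((report["status"] == "dropped").sum())
    if n_drop:
        logger.info("QC filter: dropping %d centre-procedure block(s)", n_drop)
    return report


def apply_qc_filter(
    uv: UVResultTable,
    report: pd.DataFrame,
    procedure_of: dict[str, str],
) -> UVResultTable:
    """Mask the cells of blocks the QC report marks as dropped."""
    estimate = uv.estimate.copy()
    se = uv.se.copy()
    centres = uv.centres()
    for _, row in report[report["status"] == "dropped"].iterrows():
        rows = [i for i, p in enumerate(uv.phenotypes)
                if procedure_of[p] == row["procedure"]]
        cols = np.flatnonzero(centres == row["centre"])
        estimate[np.ix_(rows, cols)] = np.nan
        se[np.ix_(rows, cols)] = np.nan
    keep = ~np.isnan(estimate).all(axis=0)
    lines = [g for j, g in enumerate(uv.lines) if keep[j]]
    return UVResultTable(
        phenotypes=list(uv.phenotypes),
        lines=lines,
        centre_of_line={g: uv.centre_of_line[g] for g in lines},
        estimate=estimate[:, keep],
        se=se[:, keep],
        is_null_line=uv.is_null_line[keep],
    )


def filter_and_scale(uv: UVResultTable, min_lines: int = 500) -> UVResultTable:
    """Drop sparse phenotypes and standardise per (phenotype, centre).

    Phenotypes observed in fewer than ``min_lines`` lines are removed;
    within each (phenotype, centre) group both estimates and SEs are
    divided by the group's sample SD of estimates, so z statistics are
    unchanged.  Scale factors are recorded on the returned table.
    """
    obs = uv.observed_mask
    keep_p = obs.sum(axis=1) >= min_lines
    phenotypes = [p for i, p in enumerate(uv.phenotypes) if keep_p[i]]
    estimate = uv.estimate[keep_p].copy()
    se = uv.se[keep_p].copy()
    centres = uv.centres()
    factors = []
    for i, p in enumerate(phenotypes):
        for centre in np.unique(centres):
            cols = np.flatnonzero(centres == centre)
            vals = estimate[i, cols]
            ok = ~np.isnan(vals)
            if ok.sum() == 0:
                continue
            if ok.sum() < 2:
                warnings.warn(
                    f"(phenotype={p}, centre={centre}): fewer than 2 "
                    "observed values, group dropped", RuntimeWarning)
                estimate[i, cols] = np.nan
                se[i, cols] = np.nan
                continue
            sd = float(np.std(vals[ok], ddof=1))
            if sd == 0:
                warnings.warn(
                    f"(phenotype={p}, centre={centre}): zero SD, group "
                    "dropped", RuntimeWarning)
                estimate[i, cols] = np.nan
                se[i, cols] = np.nan
                continue
            estimate[i, cols] = vals / sd
            se[i, cols] = se[i, cols] / sd
            factors.append((p, centre, sd))
    keep_g = ~np.isnan(estimate).all(axis=0)
    lines = [g for j, g in enumerate(uv.lines) if keep_g[j]]
    out = UVResultTable(
        phenotypes=phenotypes,
        lines=lines,
        centre_of_line={g: uv.centre_of_line[g] for g in lines},
        estimate=estimate[:, keep_g],
        se=se[:, keep_g],
        is_null_line=uv.is_null_line[keep_g],
        scale_factors=pd.DataFrame(
            factors, columns=["phenotype", "centre", "scale"]),
    )
    logger.info(
        "filter_and_scale: kept %d/%d phenotypes, %d/%d lines",
        len(phenotypes), uv.n_phenotypes, len(lines), uv.n_lines)
    return out
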