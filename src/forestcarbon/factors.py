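"""Categorised additive regression of subplot carbon on stand/site factors.

The analysis regresses per-subplot carbon stock (tC/ha) on categorised
predictors — stem volume, mean dbh, tree count, altitude, development
region and ownership — with an additive linear model

    y = β₀ + β₁x₁ + … + βₙxₙ + ε,

coded with sum-to-zero (deviation) contrasts so that the intercept is the
grand mean of level means and each factor's level effects sum to zero.
The workflow is: categorise → fit → inspect a residual QQ plot → drop
records whose raw residual exceeds a threshold (one pass) → refit →
compute each level's adjusted mean with a 95% CI and classify the CI as
entirely above, around, or entirely below the overall mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

#: Default residual threshold (tC/ha) for the one-pass outlier removal.
DEFAULT_OUTLIER_THRESHOLD = 40.0


@dataclass(frozen=True)
class CategorySpec:
    """Breakpoints turning a numeric variable into ordered levels.

    With breakpoints (b₁, …, b_m) a value v maps to the first level when
    v < b₁, to interior level i when v ≤ b_i (so printed bounds like
    "91–199" are inclusive on both ends), and to the last level otherwise.
    A single breakpoint gives the two-level split v < b vs v ≥ b.
    """

    name: str
    breakpoints: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.breakpoints) + 1:
            raise ValueError(f"{self.name}: need one more label than breakpoints")
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError(f"{self.name}: breakpoints must be strictly increasing")

    def level(self, value: float) -> str | None:
        """Level label for one value; None for missing values."""
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        if value < self.breakpoints[0]:
            return self.labels[0]
        for i in range(1, len(self.breakpoints)):
            if value <= self.breakpoints[i]:
                return self.labels[i]
        return self.labels[-1]


def categorize(value: float, spec: CategorySpec) -> str | None:
    """Level label of ``value`` under ``spec`` (None when missing)."""
    return spec.level(value)


def categorize_series(values: pd.Series, spec: CategorySpec) -> pd.Series:
    return values.map(spec.level)


#: Cutpoints of the survey regime this package emulates: stem-volume and
#: dbh levels at the sample quartiles, tree count at the median, altitude
#: at 500/1000 m.  Column names follow the SubplotSummary table.
DEFAULT_CATEGORY_SPECS: dict[str, CategorySpec] = {
    "stem_volume": CategorySpec(
        "stem_volume", (91.0, 199.0), ("sv_low", "sv_mid", "sv_high")
    ),
    "dbh": CategorySpec("dbh", (27.1, 43.4), ("dbh_low", "dbh_mid", "dbh_high")),
    "tree_count": CategorySpec("tree_count", (20.0,), ("tn_lt20", "tn_ge20")),
    "altitude": CategorySpec(
        "altitude", (500.0, 1000.0), ("alt_low", "alt_mid", "alt_high")
    ),
}

#: SubplotSummary column feeding each categorised factor.
FACTOR_SOURCE_COLUMNS: dict[str, str] = {
    "stem_volume": "stem_volume_m3_ha",
    "dbh": "mean_dbh_cm",
    "tree_count": "tree_count",
    "altitude": "altitude_m",
}

#: Categorical columns used as-is.
CATEGORICAL_FACTORS: tuple[str, ...] = ("region", "ownership")

REGION_LEVELS: tuple[str, ...] = ("FW", "MW", "W", "C", "E")
OWNERSHIP_LEVELS: tuple[str, ...] = ("community", "other")


def build_levels(
    subplots: pd.DataFrame,
    specs: dict[str, CategorySpec] | None = None,
    source_columns: dict[str, str] | None = None,
    categorical: tuple[str, ...] = CATEGORICAL_FACTORS,
) -> pd.DataFrame:
    """Factor-level table (one column per factor) from a SubplotSummary table.

    Rows with any missing factor value are excluded with a warning.
    """
    specs = specs if specs is not None else DEFAULT_CATEGORY_SPECS
    source_columns = source_columns or FACTOR_SOURCE_COLUMNS
    out = pd.DataFrame(index=subplots.index)
    for factor, spec in specs.items():
        out[factor] = categorize_series(subplots[source_columns[factor]], spec)
    for factor in categorical:
        if factor in subplots.columns:
            out[factor] = subplots[factor].astype(str).where(subplots[factor].notna())
    bad = out.isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} records with missing factor values",
            stacklevel=2,
        )
        out = out.loc[~bad]
    return out


def sum_contrast_design(
    levels: pd.DataFrame,
    level_orders: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Sum-to-zero design matrix (with intercept) from a factor-level table.

    Each factor with L observed levels contributes L−1 columns coded
    +1 for the column's own level, −1 for the last level, 0 otherwise, so
    the implied level effects sum to zero and the last level's effect is
    minus the sum of the others.  Factors with a single observed level are
    dropped with a warning.

    Returns the design matrix and the ordered level list per retained factor.
    """
    level_orders = level_orders or {}
    X = pd.DataFrame(index=levels.index)
    X["Intercept"] = 1.0
    meta: dict[str, list[str]] = {}
    for factor in levels.columns:
        observed = list(pd.unique(levels[factor]))
        order = [l for l in level_orders.get(factor, observed) if l in observed]
        order += [l for l in observed if l not in order]
        if len(order) < 2:
            warnings.warn(f"factor {factor!r} has one level; dropped", stacklevel=2)
            continue
        meta[factor] = order
        last = order[-1]
        for lev in order[:-1]:
            col = np.where(
                levels[factor] == lev, 1.0, np.where(levels[factor] == last, -1.0, 0.0)
            )
            X[f"{factor}[{lev}]"] = col
    return X, meta


@dataclass
class ModelFit:
    """A fitted additive linear model with everything CIs need."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    resid: pd.Series
    nobs: int
    df_resid: float
    rsquared: float
    rsquared_adj: float
    scale: float  # unbiased residual variance s²
    cov_params: pd.DataFrame
    factor_levels: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_removed_baseline(self) -> int:  # convenience for accounting
        return 0

    def linear_combo(self, c: np.ndarray) -> tuple[float, float]:
        """Estimate and standard error of cᵀβ."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.params.to_numpy())
        se = float(np.sqrt(c @ self.cov_params.to_numpy() @ c))
        return est, se


def _rank_check(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank == mat.shape[1]:
        return
    offending = []
    for j, name in enumerate(X.columns):
        reduced = np.delete(mat, j, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            offending.append(name)
    raise ValueError(
        f"design matrix is rank deficient (rank {rank} < {mat.shape[1]}); "
        f"linearly dependent columns include {offending}"
    )


def fit_ols(
    y: pd.Series | np.ndarray,
    X: pd.DataFrame,
    factor_levels: dict[str, list[str]] | None = None,
) -> ModelFit:
    """Ordinary least squares with t-based inference.

    Standard errors use the unbiased residual variance; p-values are
    two-sided t; adjusted R² = 1 − (1−R²)(n−1)/(n−p−1).
    """
    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="y")
    if len(y) <= X.shape[1]:
        raise ValueError(
            f"need more observations ({len(y)}) than design columns ({X.shape[1]})"
        )
    _rank_check(X)
    res = sm.OLS(y, X).fit()
    return ModelFit(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        resid=res.resid,
        nobs=int(res.nobs),
        df_resid=float(res.df_resid),
        rsquared=float(res.rsquared),
        rsquared_adj=float(res.rsquared_adj),
        scale=float(res.scale),
        cov_params=res.cov_params(),
        factor_levels=dict(factor_levels or {}),
    )


def qq_residuals(resid) -> tuple[np.ndarray, np.ndarray]:
    """Normal QQ pairs: theoretical quantiles vs sorted standardised residuals.

    The i-th theoretical quantile is Φ⁻¹((i − 0.5)/n); residuals are
    standardised to sample mean 0 and sd 1 (left as centred zeros when the
    residuals are constant).
    """
    r = np.sort(np.asarray(resid, dtype=float))
    n = len(r)
    if n < 3:
        raise ValueError("need at least 3 residuals for a QQ plot")
    theo = st.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    sd = np.std(r, ddof=1)
    standardized = (r - np.mean(r)) / sd if sd > 0 else r - np.mean(r)
    return theo, standardized


@dataclass
class OutlierRefit:
    """Result of the single removal–refit pass."""

    first_fit: ModelFit
    final_fit: ModelFit
    removed_index: pd.Index
    n_removed: int


def outlier_refit(
    y: pd.Series,
    X: pd.DataFrame,
    threshold: float = DEFAULT_OUTLIER_THRESHOLD,
    two_sided: bool = False,
    levels: pd.DataFrame | None = None,
    factor_levels: dict[str, list[str]] | None = None,
) -> OutlierRefit:
    """Fit, drop records with raw residual above ``threshold``, refit once.

    The default rule is one-sided (residual > +threshold), the convention
    for removing the upper-tail departures a QQ plot reveals; set
    ``two_sided`` to drop |residual| > threshold instead.  When ``levels``
    is given, removal that empties a factor level aborts with an error.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="y")
    first = fit_ols(y, X, factor_levels)
    resid = first.resid
    mask = (resid.abs() > threshold) if two_sided else (resid > threshold)
    removed = y.index[mask]
    keep = y.index[~mask]
    if levels is not None and len(removed):
        kept_levels = levels.loc[levels.index.intersection(keep)]
        for factor in levels.columns:
            lost = set(levels[factor].unique()) - set(kept_levels[factor].unique())
            if lost:
                raise ValueError(
                    f"outlier removal empties level(s) {sorted(lost)} of factor {factor!r}"
                )
    if len(removed) == 0:
        return OutlierRefit(first, first, removed, 0)
    final = fit_ols(y.loc[keep], X.loc[keep], factor_levels)
    return OutlierRefit(first, final, removed, int(len(removed)))


def level_effects(fit: ModelFit, factor: str) -> pd.Series:
    """Sum-to-zero level effects of one factor, last level recovered as −Σ."""
    if factor not in fit.factor_levels:
        raise KeyError(f"factor {factor!r} not in fitted model")
    order = fit.factor_levels[factor]
    effects = {lev: fit.params[f"{factor}[{lev}]"] for lev in order[:-1]}
    effects[order[-1]] = -sum(effects.values())
    return pd.Series(effects, name=factor)


def _contrast_vector(fit: ModelFit, factor: str, level: str) -> np.ndarray:
    order = fit.factor_levels[factor]
    c = np.zeros(len(fit.params))
    cols = list(fit.params.index)
    c[cols.index("Intercept")] = 1.0
    if level == order[-1]:
        for lev in order[:-1]:
            c[cols.index(f"{factor}[{lev}]")] = -1.0
    else:
        c[cols.index(f"{factor}[{level}]")] = 1.0
    return c


def level_difference_ci(
    fit: ModelFit,
    factor: str,
    level: str,
    ref_level: str | None = None,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Estimate and CI of one level's effect minus a reference level's.

    With sum-to-zero coding this recovers the usual treatment-style
    contrast (difference of adjusted means); the intercept cancels.
    """
    order = fit.factor_levels[factor]
    ref_level = ref_level if ref_level is not None else order[0]
    c = _contrast_vector(fit, factor, level) - _contrast_vector(fit, factor, ref_level)
    est, se = fit.linear_combo(c)
    tq = st.t.ppf(1 - alpha / 2, fit.df_resid)
    return est, est - tq * se, est + tq * se


def classify_ci(ci_low: float, ci_high: float, overall_mean: float) -> str:
    """Trichotomy of a level CI against the overall mean.

    ``above`` when the whole interval exceeds the mean, ``below`` when it
    lies entirely under it, ``around`` otherwise — including the boundary
    case where an endpoint equals the mean.
    """
    if ci_low > overall_mean:
        return "above"
    if ci_high < overall_mean:
        return "below"
    return "around"


def contrast_cis(
    fit: ModelFit,
    factor: str,
    levels: pd.DataFrame,
    y: pd.Series,
    overall_mean: float | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Adjusted mean, 95% CI, crude mean and classification per factor level.

    The adjusted mean of a level is intercept + level effect (other factors
    held at their contrast-balanced zero); its CI uses the t quantile with
    the fit's residual degrees of freedom and the exact linear-combination
    variance cᵀ·Cov(β)·c.  Crude means come from the analysed raw data.
    ``levels`` and ``y`` must be restricted to the analysed records (the
    fit's rows).
    """
    order = fit.factor_levels[factor]
    y = pd.Series(np.asarray(y, dtype=float), index=levels.index)
    # restrict to the rows the fit actually used
    used = fit.resid.index
    lev_used = levels.loc[used]
    y_used = y.loc[used]
    if overall_mean is None:
        overall_mean = float(y_used.mean())
    tq = st.t.ppf(1 - alpha / 2, fit.df_resid)
    rows = []
    for lev in order:
        c = _contrast_vector(fit, factor, lev)
        est, se = fit.linear_combo(c)
        lo, hi = est - tq * se, est + tq * se
        crude = float(y_used[lev_used[factor] == lev].mean())
        rows.append(
            {
                "factor": factor,
                "level": lev,
                "adjusted_mean": est,
                "ci_low": lo,
                "ci_high": hi,
                "crude_mean": crude,
                "classification": classify_ci(lo, hi, overall_mean),
            }
        )
    return pd.DataFrame(rows)


def coefficients_table(fit: ModelFit) -> pd.DataFrame:
    """Long-format coefficient table (variable, level, estimate, se, p).

    Reference rows (the last level of each factor, whose effect is the
    negative sum of the others) are included with the recovered estimate
    and no standard error, mirroring how such tables are usually printed.
    """
    rows = [
        {
            "variable": "Intercept",
            "level": "",
            "estimate": fit.params["Intercept"],
            "std_error": fit.bse["Intercept"],
            "p_value": fit.pvalues["Intercept"],
        }
    ]
    for factor, order in fit.factor_levels.items():
        eff = level_effects(fit, factor)
        for lev in order:
            name = f"{factor}[{lev}]"
            known = name in fit.params.index
            rows.append(
                {
                    "variable": factor,
                    "level": lev,
                    "estimate": fit.params[name] if known else eff[lev],
                    "std_error": fit.bse[name] if known else np.nan,
                    "p_value": fit.pvalues[name] if known else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class FactorAnalysis:
    """End-to-end result of the categorise→fit→refit→contrast workflow."""

    levels: pd.DataFrame
    first_fit: ModelFit
    final_fit: ModelFit
    removed_index: pd.Index
    n_removed: int
    overall_mean: float
    contrasts: dict[str, pd.DataFrame]

    @property
    def coefficients(self) -> pd.DataFrame:
        return coefficients_table(self.final_fit)

    @property
    def contrast_table(self) -> pd.DataFrame:
        return pd.concat(self.contrasts.values(), ignore_index=True)


def fit_factor_model(
    subplots: pd.DataFrame,
    carbon_column: str = "carbon_tC_ha",
    specs: dict[str, CategorySpec] | None = None,
    outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD,
    two_sided_outliers: bool = False,
    level_orders: dict[str, list[str]] | None = None,
) -> FactorAnalysis:
    """Run the full factor-association analysis on a SubplotSummary table.

    The overall mean used for the CI trichotomy is the mean carbon of the
    analysed (post-removal) records.
    """
    orders = dict(level_orders or {})
    orders.setdefault("region", list(REGION_LEVELS))
    orders.setdefault("ownership", list(OWNERSHIP_LEVELS))
    for factor, spec in (specs if specs is not None else DEFAULT_CATEGORY_SPECS).items():
        orders.setdefault(factor, list(spec.labels))
    levels = build_levels(subplots, specs)
    y = subplots.loc[levels.index, carbon_column]
    X, meta = sum_contrast_design(levels, orders)
    refit = outlier_refit(
        y,
        X,
        threshold=outlier_threshold,
        two_sided=two_sided_outliers,
        levels=levels,
        factor_levels=meta,
    )
    used = refit.final_fit.resid.index
    overall = float(pd.Series(np.asarray(y, dtype=float), index=levels.index).loc[used].mean())
    contrasts = {
        factor: contrast_cis(refit.final_fit, factor, levels, y, overall_mean=overall)
        for factor in meta
    }
    return FactorAnalysis(
        levels=levels,
        first_fit=refit.first_fit,
        final_fit=refit.final_fit,
        removed_index=refit.removed_index,
        n_removed=refit.n_removed,
        overall_mean=overall,
        contrasts=contrasts,
    )
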