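"""Tree-level allometry: stem volume, biomass and carbon per hectare.

The estimation chain converts field measurements into per-subplot,
per-hectare carbon stocks:

1. diameter at breast height d = c/π from tape-measured circumference,
2. total height h from a species-group height–diameter (H–D) curve fitted
   to the systematically height-sampled trees,
3. stem volume from the log-linear allometric form
   ln v = a + b·ln d + c·ln h with species-specific coefficients,
4. air-dry stem biomass = v × wood density (kg/m³), converted to oven-dry
   mass with factor 0.91, then to carbon with a configurable fraction
   (presets 0.47 for the biomass route and 0.5 for the volume route),
5. per-hectare expansion by the nested-circle factor 10⁴/(πr²) of the
   concentric circle in which the stem was enumerated, summed per subplot.

Only the stem compartment is modelled: no branch, leaf, root, litter or
soil carbon, and no bark corrections.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .design import MIN_DBH_CM, expansion_factor, inclusion_radii

OVEN_DRY_FACTOR = 0.91
#: Carbon fraction presets; both are in common use for stem stocks.
CARBON_FRACTION_VOLUME_ROUTE = 0.5
CARBON_FRACTION_BIOMASS_ROUTE = 0.47

#: Key of the pooled fallback H–D model.
POOLED_GROUP = "__pooled__"

BREAST_HEIGHT_M = 1.3


@dataclass(frozen=True)
class SpeciesAllometry:
    """Per-species volume coefficients, wood density and H–D group label."""

    species_code: str
    vol_a: float
    vol_b: float
    vol_c: float
    wood_density_kg_m3: float
    hd_group: str

    def __post_init__(self) -> None:
        if self.wood_density_kg_m3 <= 0:
            raise ValueError(f"{self.species_code}: wood density must be positive")


@dataclass
class AllometryConfig:
    """Configuration of the volume→biomass→carbon conversion chain.

    ``biomass_mode`` selects between ``"volume-scaled"`` (biomass =
    v × density, the physically meaningful product and the shipped default)
    and ``"literal"`` (biomass = ln(v) × density), kept selectable because
    the latter form circulates in print even though it goes negative for
    stems under 1 m³.
    """

    biomass_mode: str = "volume-scaled"
    oven_dry_factor: float = OVEN_DRY_FACTOR
    carbon_fraction: float = CARBON_FRACTION_VOLUME_ROUTE
    height_sample_interval: int = 5
    min_hd_group_obs: int = 3

    def __post_init__(self) -> None:
        if self.biomass_mode not in ("volume-scaled", "literal"):
            raise ValueError(f"unknown biomass mode {self.biomass_mode!r}")
        if not 0 < self.carbon_fraction < 1:
            raise ValueError(
                f"carbon fraction must be in (0, 1), got {self.carbon_fraction}"
            )


def dbh_from_circumference(circumference_cm):
    """Diameter at breast height d = c/π (cm). Accepts scalars or arrays."""
    c = np.asarray(circumference_cm, dtype=float)
    if np.any(c < 0):
        raise ValueError("circumference must be non-negative")
    out = c / math.pi
    return float(out) if np.isscalar(circumference_cm) else out


def stem_volume(dbh_cm, height_m, vol_a, vol_b, vol_c):
    """Stem volume v = exp(a + b·ln d + c·ln h) (m³). Vectorised."""
    d = np.asarray(dbh_cm, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if np.any(d <= 0) or np.any(h <= 0):
        raise ValueError("diameter and height must be positive")
    out = np.exp(vol_a + vol_b * np.log(d) + vol_c * np.log(h))
    return float(out) if out.ndim == 0 else out


def stem_biomass(volume_m3, density_kg_m3, mode: str = "volume-scaled"):
    """Air-dry stem biomass (kg) from volume and wood density.

    ``"volume-scaled"`` returns v × density; ``"literal"`` returns
    ln(v) × density and warns when v ≤ 1 m³ makes the result non-positive.
    """
    v = np.asarray(volume_m3, dtype=float)
    rho = np.asarray(density_kg_m3, dtype=float)
    if np.any(v <= 0) or np.any(rho <= 0):
        raise ValueError("volume and density must be positive")
    if mode == "volume-scaled":
        out = v * rho
    elif mode == "literal":
        if np.any(v <= 1):
            warnings.warn(
                "literal biomass mode yields non-positive mass for volumes <= 1 m3",
                stacklevel=2,
            )
        out = np.log(v) * rho
    else:
        raise ValueError(f"unknown biomass mode {mode!r}")
    return float(out) if out.ndim == 0 else out


def to_oven_dry(air_dry_mass, factor: float = OVEN_DRY_FACTOR):
    """Oven-dry mass from air-dry mass (default factor 0.91)."""
    m = np.asarray(air_dry_mass, dtype=float)
    if np.any(m < 0):
        raise ValueError("mass must be non-negative")
    out = m * factor
    return float(out) if out.ndim == 0 else out


def carbon_from_biomass(oven_dry_mass, fraction: float = CARBON_FRACTION_VOLUME_ROUTE):
    """Carbon mass as a fixed fraction of oven-dry biomass."""
    if not 0 < fraction < 1:
        raise ValueError(f"carbon fraction must be in (0, 1), got {fraction}")
    m = np.asarray(oven_dry_mass, dtype=float)
    out = m * fraction
    return float(out) if out.ndim == 0 else out


def sample_height_trees(
    species_codes, interval: int = 5
) -> np.ndarray:
    """Flag trees for height measurement from an ordered enumeration list.

    Every ``interval``-th tree (positions 5, 10, … for the default) is
    flagged; additionally the first occurrence of any species that would
    otherwise go unmeasured is flagged, so every species present in the
    list has at least one height observation.

    Parameters
    ----------
    species_codes : sequence
        Species of each tree, in enumeration order.

    Returns
    -------
    numpy.ndarray of bool, same length as the input.
    """
    codes = list(species_codes)
    n = len(codes)
    flags = np.zeros(n, dtype=bool)
    if n == 0:
        return flags
    flags[interval - 1 :: interval] = True
    covered = {codes[i] for i in np.flatnonzero(flags)}
    seen: set = set()
    for i, code in enumerate(codes):
        if code not in covered and code not in seen:
            flags[i] = True
            covered.add(code)
        seen.add(code)
    return flags


def saturating_height(dbh_cm, asymptote_m, rate_per_cm):
    """Monotone H–D curve h = 1.3 + A·(1 − exp(−r·d)).

    Predicts above breast height for every enumerable stem and approaches
    the asymptote 1.3 + A for large diameters.
    """
    return BREAST_HEIGHT_M + asymptote_m * (1.0 - np.exp(-rate_per_cm * np.asarray(dbh_cm, dtype=float)))


@dataclass(frozen=True)
class HeightDiameterModel:
    """A fitted saturating H–D curve for one species group."""

    hd_group: str
    asymptote_m: float
    rate_per_cm: float
    resid_sd: float
    n_obs: int

    def predict(self, dbh_cm):
        out = saturating_height(dbh_cm, self.asymptote_m, self.rate_per_cm)
        return float(out) if np.ndim(out) == 0 else out


def _fit_hd_curve(dbh: np.ndarray, height: np.ndarray, group: str) -> HeightDiameterModel:
    a0 = max(float(np.max(height)) - BREAST_HEIGHT_M, 1.0)
    p0 = (a0, 0.05)
    params, _ = curve_fit(
        saturating_height,
        dbh,
        height,
        p0=p0,
        bounds=([0.1, 1e-4], [150.0, 2.0]),
        maxfev=20000,
    )
    resid = height - saturating_height(dbh, *params)
    sd = float(np.std(resid, ddof=2)) if len(dbh) > 2 else 0.0
    return HeightDiameterModel(group, float(params[0]), float(params[1]), sd, len(dbh))


def fit_height_diameter(
    dbh_cm,
    height_m,
    hd_groups=None,
    min_obs: int = 3,
) -> dict[str, HeightDiameterModel]:
    """Fit the saturating H–D curve per species group by least squares.

    Groups with fewer than ``min_obs`` height observations, or whose fit
    fails to converge, fall back to the pooled model fitted on all sampled
    trees; the pooled model is always returned under :data:`POOLED_GROUP`.
    """
    d = np.asarray(dbh_cm, dtype=float)
    h = np.asarray(height_m, dtype=float)
    mask = np.isfinite(d) & np.isfinite(h)
    d, h = d[mask], h[mask]
    if len(d) < min_obs:
        raise ValueError(f"need at least {min_obs} height observations, got {len(d)}")
    models = {POOLED_GROUP: _fit_hd_curve(d, h, POOLED_GROUP)}
    if hd_groups is None:
        return models
    groups = np.asarray(hd_groups)[mask]
    for group in pd.unique(groups):
        sel = groups == group
        if sel.sum() < min_obs:
            warnings.warn(
                f"H-D group {group!r} has {int(sel.sum())} height trees; using pooled model",
                stacklevel=2,
            )
            continue
        try:
            models[str(group)] = _fit_hd_curve(d[sel], h[sel], str(group))
        except RuntimeError:
            warnings.warn(
                f"H-D fit failed to converge for group {group!r}; using pooled model",
                stacklevel=2,
            )
    return models


def predict_heights(
    dbh_cm, hd_groups, models: dict[str, HeightDiameterModel]
) -> np.ndarray:
    """Model-predicted heights per tree, pooled fallback for unknown groups."""
    d = np.asarray(dbh_cm, dtype=float)
    groups = np.asarray(hd_groups, dtype=object)
    out = np.empty(len(d), dtype=float)
    for group in pd.unique(groups):
        model = models.get(str(group), models[POOLED_GROUP])
        sel = groups == group
        out[sel] = model.predict(d[sel])
    return out


REQUIRED_TREE_COLUMNS = ("tree_id", "subplot_id", "species_code")
REQUIRED_SPECIES_COLUMNS = (
    "species_code",
    "vol_a",
    "vol_b",
    "vol_c",
    "wood_density_kg_m3",
    "hd_group",
)

SUMMARY_COLUMNS = (
    "subplot_id",
    "carbon_tC_ha",
    "stem_volume_m3_ha",
    "air_dry_biomass_t_ha",
    "mean_dbh_cm",
    "tree_count",
    "stems_per_ha",
)


def _prepare_trees(trees: pd.DataFrame, species: pd.DataFrame) -> pd.DataFrame:
    """Resolve dbh, drop non-enumerable stems, attach species coefficients."""
    missing = [c for c in REQUIRED_TREE_COLUMNS if c not in trees.columns]
    if missing:
        raise ValueError(f"tree table is missing columns {missing}")
    missing = [c for c in REQUIRED_SPECIES_COLUMNS if c not in species.columns]
    if missing:
        raise ValueError(f"species table is missing columns {missing}")
    t = trees.copy()
    if "dbh_cm" not in t.columns:
        t["dbh_cm"] = np.nan
    if "circumference_cm" in t.columns:
        need = t["dbh_cm"].isna() & t["circumference_cm"].notna()
        t.loc[need, "dbh_cm"] = dbh_from_circumference(
            t.loc[need, "circumference_cm"].to_numpy()
        )
    if t["dbh_cm"].isna().any():
        raise ValueError("trees without dbh or circumference present")
    small = t["dbh_cm"] < MIN_DBH_CM
    if small.any():
        warnings.warn(
            f"excluding {int(small.sum())} stems below the {MIN_DBH_CM} cm limit",
            stacklevel=3,
        )
        t = t.loc[~small]
    unknown = set(t["species_code"]) - set(species["species_code"])
    if unknown:
        raise ValueError(f"species codes without allometric coefficients: {sorted(unknown)[:5]}")
    return t.merge(species, on="species_code", how="left", validate="many_to_one")


def estimate_carbon(
    trees: pd.DataFrame,
    species: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    config: AllometryConfig | None = None,
) -> pd.DataFrame:
    """Per-subplot per-hectare stem volume, biomass and carbon.

    Heights come from H–D curves fitted to the height-sampled trees
    (``height_sampled`` flag with ``height_m`` measured); all other trees
    get model-predicted heights.  Each stem's volume, biomass and carbon
    are expanded by the per-hectare factor of the concentric circle in
    which it was enumerated and summed per subplot; carbon is reported in
    tonnes per hectare.

    Returns one row per subplot with the columns of
    :data:`SUMMARY_COLUMNS`, joined with ``covariates`` (on ``subplot_id``)
    when provided.
    """
    config = config or AllometryConfig()
    t = _prepare_trees(trees, species)
    if len(t) == 0:
        warnings.warn("no enumerable trees; returning empty summary", stacklevel=2)
        return pd.DataFrame(columns=list(SUMMARY_COLUMNS))

    if (
        "height_sampled" in t.columns
        and "height_m" in t.columns
        and t["height_sampled"].fillna(False).any()
    ):
        sampled = t["height_sampled"].fillna(False).astype(bool)
        models = fit_height_diameter(
            t.loc[sampled, "dbh_cm"],
            t.loc[sampled, "height_m"],
            t.loc[sampled, "hd_group"],
            min_obs=config.min_hd_group_obs,
        )
        heights = predict_heights(t["dbh_cm"], t["hd_group"], models)
        if "height_m" in t.columns:
            measured = sampled & t["height_m"].notna()
            heights[measured.to_numpy()] = t.loc[measured, "height_m"].to_numpy()
    elif "height_m" in t.columns and t["height_m"].notna().all():
        heights = t["height_m"].to_numpy(dtype=float)
    else:
        raise ValueError(
            "need either height-sampled trees to fit H-D curves or measured heights for all trees"
        )
    t["height_used_m"] = heights

    t["volume_m3"] = stem_volume(
        t["dbh_cm"], t["height_used_m"], t["vol_a"], t["vol_b"], t["vol_c"]
    )
    t["biomass_kg"] = stem_biomass(
        t["volume_m3"], t["wood_density_kg_m3"], mode=config.biomass_mode
    )
    oven = to_oven_dry(np.maximum(t["biomass_kg"], 0.0), config.oven_dry_factor)
    t["carbon_kg"] = carbon_from_biomass(oven, config.carbon_fraction)

    radii = inclusion_radii(t["dbh_cm"].to_numpy())
    t["expansion"] = 1e4 / (math.pi * radii**2)

    t["_carbon_t_ha"] = t["carbon_kg"] * t["expansion"] / 1000.0
    t["_volume_m3_ha"] = t["volume_m3"] * t["expansion"]
    t["_biomass_t_ha"] = t["biomass_kg"] * t["expansion"] / 1000.0
    g = t.groupby("subplot_id", sort=True)
    summary = pd.DataFrame(
        {
            "carbon_tC_ha": g["_carbon_t_ha"].sum(),
            "stem_volume_m3_ha": g["_volume_m3_ha"].sum(),
            "air_dry_biomass_t_ha": g["_biomass_t_ha"].sum(),
            "mean_dbh_cm": g["dbh_cm"].mean(),
            "tree_count": g.size(),
            "stems_per_ha": g["expansion"].sum(),
        }
    ).reset_index()
    if covariates is not None:
        summary = summary.merge(covariates, on="subplot_id", how="left")
    return summary


def aggregate_subplot(
    trees: pd.DataFrame,
    species: pd.DataFrame,
    config: AllometryConfig | None = None,
) -> dict:
    """Aggregate a single subplot's tree list to per-hectare totals.

    Trees must carry measured or pre-predicted heights in ``height_m``.
    Returns a plain dict mirroring one row of :func:`estimate_carbon`.
    """
    if len(trees) == 0:
        warnings.warn("empty tree list; returning all-zero summary", stacklevel=2)
        return {
            "carbon_tC_ha": 0.0,
            "stem_volume_m3_ha": 0.0,
            "air_dry_biomass_t_ha": 0.0,
            "mean_dbh_cm": float("nan"),
            "tree_count": 0,
            "stems_per_ha": 0.0,
        }
    if trees["subplot_id"].nunique() != 1:
        raise ValueError("aggregate_subplot expects trees from a single subplot")
    row = estimate_carbon(trees, species, covariates=None, config=config).iloc[0]
    return {k: row[k] for k in SUMMARY_COLUMNS if k != "subplot_id"}
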