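"""Two-phase systematic sampling design and nested concentric-plot geometry.

National forest inventories commonly lay a square grid over the territory,
attach a cluster of subplots to every grid knot, and enumerate trees inside
nested concentric circles so that large stems are tallied over a wider area
than small ones.  This module implements the arithmetic of such a design:

* systematic 1-in-k selection of forest clusters and the accessible-cluster
  accounting that follows,
* the six-subplot "N"-shaped cluster layout (two columns 300 m apart, rows
  150 m apart, numbered south→north then west→east),
* circle areas, diameter-class inclusion radii and the per-hectare
  expansion factors 10⁴/(πr²) that turn circle tallies into stand rates.

All coordinates are planar metres relative to the grid knot; no geodesy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Minimum diameter at breast height (cm) for a stem to be enumerated at all.
MIN_DBH_CM = 5.0

#: Spacing of subplots within a cluster (metres).
SUBPLOT_NORTHING_SPACING_M = 150.0
SUBPLOT_EASTING_SPACING_M = 300.0


class NotEnumerableError(ValueError):
    """Raised for stems below the enumeration threshold (dbh < 5 cm)."""


@dataclass(frozen=True)
class ConcentricRule:
    """One nested circle: a half-open dbh class [low, high) and its radius."""

    dbh_low_cm: float
    dbh_high_cm: float  # exclusive upper bound; math.inf for the open class
    radius_m: float

    def contains(self, dbh_cm: float) -> bool:
        return self.dbh_low_cm <= dbh_cm < self.dbh_high_cm


#: The nested-plot design: larger stems are enumerated over larger radii.
NESTED_PLOT_RULES: tuple[ConcentricRule, ...] = (
    ConcentricRule(5.0, 10.0, 4.0),
    ConcentricRule(10.0, 20.0, 8.0),
    ConcentricRule(20.0, 30.0, 15.0),
    ConcentricRule(30.0, math.inf, 20.0),
)


@dataclass(frozen=True)
class GridCluster:
    """A 4 km grid knot with its survey status flags."""

    cluster_id: int
    easting_index: int
    northing_index: int
    is_forest: bool = False
    is_accessible: bool = True
    is_selected: bool = False

    def __post_init__(self) -> None:
        if self.is_selected and not self.is_forest:
            raise ValueError(
                f"cluster {self.cluster_id}: only forest clusters can be selected"
            )


@dataclass(frozen=True)
class SubplotLayout:
    """Position of one subplot relative to its cluster's grid knot."""

    subplot_number: int  # 1..6
    offset_east_m: float
    offset_north_m: float


def circle_area(radius_m: float) -> float:
    """Area (m²) of a circle of radius ``radius_m``; equals πd²/4 with d = 2r."""
    if radius_m < 0:
        raise ValueError(f"radius must be non-negative, got {radius_m}")
    return math.pi * radius_m * radius_m


def expansion_factor(radius_m: float) -> float:
    """Per-hectare multiplier 10⁴/(πr²) for a tally in a circle of radius r."""
    if radius_m <= 0:
        raise ValueError(f"radius must be positive, got {radius_m}")
    return 1e4 / circle_area(radius_m)


def inclusion_radius(
    dbh_cm: float, rules: tuple[ConcentricRule, ...] = NESTED_PLOT_RULES
) -> float:
    """Radius (m) of the concentric circle in which a stem of this dbh is counted.

    Raises :class:`NotEnumerableError` below the 5 cm enumeration floor.
    """
    if not np.isfinite(dbh_cm) or dbh_cm < rules[0].dbh_low_cm:
        raise NotEnumerableError(
            f"dbh {dbh_cm} cm is below the {rules[0].dbh_low_cm} cm enumeration limit"
        )
    for rule in rules:
        if rule.contains(dbh_cm):
            return rule.radius_m
    raise AssertionError("concentric rules do not cover the dbh range")


def inclusion_radii(
    dbh_cm: np.ndarray, rules: tuple[ConcentricRule, ...] = NESTED_PLOT_RULES
) -> np.ndarray:
    """Vectorised :func:`inclusion_radius`; NaN marks non-enumerable stems."""
    d = np.asarray(dbh_cm, dtype=float)
    conds = [(d >= r.dbh_low_cm) & (d < r.dbh_high_cm) for r in rules]
    return np.select(conds, [r.radius_m for r in rules], default=np.nan)


def select_every_kth(n_forest_clusters: int, k: int) -> np.ndarray:
    """1-based indices of a systematic 1-in-k selection starting at the first.

    Selecting every k-th of n clusters beginning with cluster 1 yields
    indices 1, 1+k, 1+2k, … ≤ n, i.e. ceil(n/k) clusters.
    """
    if k <= 0:
        raise ValueError(f"selection interval k must be >= 1, got {k}")
    if n_forest_clusters < 1:
        raise ValueError(f"need at least one cluster, got {n_forest_clusters}")
    return np.arange(1, n_forest_clusters + 1, k)


@dataclass(frozen=True)
class ClusterAccounting:
    """Bookkeeping of a systematic cluster selection after access losses."""

    selected: int
    inaccessible: int
    accessible: int
    subplots: int
    accessible_pct_of_forest: float | None = None


def cluster_accounting(
    selected: int,
    inaccessible: int,
    subplots_per_cluster: int = 6,
    n_forest_clusters: int | None = None,
) -> ClusterAccounting:
    """Accessible-cluster and subplot totals after dropping inaccessible clusters.

    If ``n_forest_clusters`` is given, also reports accessible clusters as a
    percentage of all forest clusters, rounded to 1 decimal place.
    """
    if min(selected, inaccessible, subplots_per_cluster) < 0:
        raise ValueError("counts must be non-negative")
    if inaccessible > selected:
        raise ValueError("inaccessible clusters cannot exceed selected clusters")
    accessible = selected - inaccessible
    pct = None
    if n_forest_clusters is not None:
        if n_forest_clusters <= 0:
            raise ValueError("forest cluster total must be positive")
        pct = round(100.0 * accessible / n_forest_clusters, 1)
    return ClusterAccounting(
        selected=selected,
        inaccessible=inaccessible,
        accessible=accessible,
        subplots=accessible * subplots_per_cluster,
        accessible_pct_of_forest=pct,
    )


def layout_subplots(
    knot_easting_m: float = 0.0, knot_northing_m: float = 0.0
) -> tuple[SubplotLayout, ...]:
    """The six subplot positions of one cluster, in an "N" pattern.

    Subplots 1–3 ascend the west column south→north, 4–6 the east column,
    rows 150 m apart and columns 300 m apart.  Offsets are relative to the
    cluster's grid knot, which coincides with subplot 1.
    """
    layouts = []
    for number in range(1, 7):
        col = (number - 1) // 3  # 0 = west column, 1 = east column
        row = (number - 1) % 3
        layouts.append(
            SubplotLayout(
                subplot_number=number,
                offset_east_m=knot_easting_m + col * SUBPLOT_EASTING_SPACING_M,
                offset_north_m=knot_northing_m + row * SUBPLOT_NORTHING_SPACING_M,
            )
        )
    return tuple(layouts)


def design_summary(
    n_forest_clusters: int = 999,
    k: int = 8,
    n_inaccessible: int = 4,
    subplots_per_cluster: int = 6,
) -> dict:
    """Full accounting of the two-phase design as a plain dict (CLI output).

    Defaults reproduce the survey regime this package emulates: 999 forest
    clusters, every 8th selected, 4 lost to access, 6 subplots per cluster.
    """
    selected = select_every_kth(n_forest_clusters, k)
    acct = cluster_accounting(
        selected=len(selected),
        inaccessible=n_inaccessible,
        subplots_per_cluster=subplots_per_cluster,
        n_forest_clusters=n_forest_clusters,
    )
    return {
        "forest_clusters": n_forest_clusters,
        "selection_interval": k,
        "selected_clusters": acct.selected,
        "inaccessible_clusters": acct.inaccessible,
        "accessible_clusters": acct.accessible,
        "total_subplots": acct.subplots,
        "accessible_pct_of_forest": acct.accessible_pct_of_forest,
        "subplot_area_m2": round(circle_area(NESTED_PLOT_RULES[-1].radius_m), 1),
    }
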