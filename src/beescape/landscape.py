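"""Landscape floral-resource quantification.

Quadrat flower counts on each transect are converted to a floral-volume
density (mm³ per m² of transect), land-type medians of those densities are
taken per time period, and the medians are multiplied by the area of each
land type inside a circular buffer (250/500/750 m) around every sampling
location to give the total landscape floral-resource volume.

Land falls into four categories: ``non_resource`` (contributes zero),
``resource_providing`` (contributes area × land-type median density),
``unknown`` (imputed), and ``soybean`` (of uncertain reward value: treated
as unknown land only during its flowering periods, zero otherwise).  The
unknown-land imputation has two variants: ``median`` assigns the median of
the densities of the land types present within the same buffer and period;
``minimum`` assigns zero (the minimum observed land-type density is always
zero in practice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry
from shapely.validation import explain_validity

__all__ = [
    "LandPatch",
    "QUADRAT_AREA_M2",
    "PERIODS",
    "RADII_M",
    "VARIANTS",
    "SOYBEAN_FLOWERING_PERIODS",
    "transect_density",
    "landtype_median",
    "area_within_radius",
    "landscape_total",
    "landscape_resource_table",
    "filter_observations",
]

#: Side of a floral quadrat is 1.5 m, so each quadrat covers 2.25 m².
QUADRAT_AREA_M2 = 1.5 * 1.5
#: The four within-season sampling periods, in order.
PERIODS = ("T1", "T2", "T3", "T4")
#: Buffer radii (metres) at which landscape composition is quantified.
RADII_M = (250, 500, 750)
#: Unknown-land imputation variants.
VARIANTS = ("median", "minimum")
#: Periods in which soybean flowers (early and mid-summer).
SOYBEAN_FLOWERING_PERIODS = frozenset({"T2", "T3"})

CATEGORIES = ("non_resource", "resource_providing", "unknown", "soybean")


class GeometryError(ValueError):
    """A land patch polygon is invalid (self-intersecting or empty)."""


class MissingSpeciesError(KeyError):
    """Quadrat counts reference species without a per-flower volume."""


class IncompleteRecordError(ValueError):
    """A weather record is missing a required field."""


class ImputationNeededWarning(UserWarning):
    """A resource-providing land type in a buffer has no median density for
    the period; its area is treated as unknown land."""


@dataclass(frozen=True)
class LandPatch:
    """One digitised land patch: polygon (planar metric CRS), land-type
    label, and resource category."""

    patch_id: str
    polygon: BaseGeometry
    land_type: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.polygon.is_empty or not self.polygon.is_valid:
            raise GeometryError(
                f"patch {self.patch_id}: {explain_validity(self.polygon)}"
            )
        if self.polygon.area <= 0:
            raise GeometryError(f"patch {self.patch_id}: zero area")


def check_no_overlap(patches: Sequence[LandPatch], tol: float = 1e-6) -> None:
    """Raise if any two patches overlap by more than ``tol`` m² (patches
    must tile the landscape without double counting)."""
    from shapely.strtree import STRtree

    geoms = [p.polygon for p in patches]
    tree = STRtree(geoms)
    for i, g in enumerate(geoms):
        for j in tree.query(g):
            if j <= i:
                continue
            inter = g.intersection(geoms[j]).area
            if inter > tol:
                raise GeometryError(
                    f"patches {patches[i].patch_id} and {patches[j].patch_id} "
                    f"overlap by {inter:.3g} m²"
                )


def transect_density(
    quadrat_counts: pd.DataFrame,
    species_volumes: Mapping[str, float],
    taxon_filter: Iterable[str] | None = None,
) -> float:
    """Mean floral-volume density (mm³/m²) over the quadrats of one
    location × period.

    ``quadrat_counts`` has columns quadrat_id, species_id, open_flower_count
    for a single (location, period); counts are flowers (inflorescences
    already expanded; capitula count as single flowers).  Density is the
    quadrat mean of Σ_species count × per-flower volume divided by the
    2.25 m² quadrat area.  ``taxon_filter`` restricts the plant species that
    count as rewarding (the cucurbit-only filter used for squash-bee
    models); default is all species.
    """
    if quadrat_counts.empty:
        return 0.0
    missing = set(quadrat_counts["species_id"]) - set(species_volumes)
    if missing:
        raise MissingSpeciesError(
            f"no per-flower volume for species: {sorted(missing)}"
        )
    df = quadrat_counts
    if taxon_filter is not None:
        allowed = set(taxon_filter)
        df = df[df["species_id"].isin(allowed)]
    quadrats = quadrat_counts["quadrat_id"].unique()
    if df.empty:
        return 0.0
    vol = df["species_id"].map(species_volumes).astype(float)
    per_quadrat = (
        (df["open_flower_count"].astype(float) * vol)
        .groupby(df["quadrat_id"])
        .sum()
        .reindex(quadrats, fill_value=0.0)
    )
    return float(per_quadrat.mean() / QUADRAT_AREA_M2)


def landtype_median(transect_densities: pd.DataFrame) -> pd.DataFrame:
    """Median transect density per (land_type, period).

    ``transect_densities`` has columns land_type, period, density_mm3_m2
    (one row per transect).  The sample median is used (mean of the two
    central order statistics for even counts).  Groups with no transects
    simply yield no entry.
    """
    out = (
        transect_densities.groupby(["land_type", "period"])["density_mm3_m2"]
        .median()
        .rename("median_density_mm3_m2")
        .reset_index()
    )
    return out


def _disc(x: float, y: float, radius_m: float, quad_segs: int = 256) -> BaseGeometry:
    return Point(x, y).buffer(radius_m, quad_segs=quad_segs)


def area_within_radius(
    patches: Sequence[LandPatch],
    location_xy: tuple[float, float],
    radius_m: float,
    quad_segs: int = 256,
) -> dict[str, float]:
    """Exact polygon ∩ disc intersection area (m²) per land type.

    Coordinates must be in a planar metric CRS.  The disc is a 4×quad_segs-
    gon circle approximation (relative area error < 1e-5 at the default).
    The summed areas are ≤ πr², with equality only when the patches tile
    the disc.
    """
    from shapely.strtree import STRtree

    disc = _disc(*location_xy, radius_m, quad_segs)
    tree = STRtree([p.polygon for p in patches])
    areas: dict[str, float] = {}
    for i in tree.query(disc):
        p = patches[int(i)]
        if not p.polygon.is_valid:
            raise GeometryError(f"invalid polygon for patch {p.patch_id}")
        a = p.polygon.intersection(disc).area
        if a > 0:
            areas[p.land_type] = areas.get(p.land_type, 0.0) + a
    return areas


def landscape_total(
    median_table: pd.DataFrame,
    areas: Mapping[str, float],
    period: str,
    variant: str,
    category_of: Mapping[str, str],
    soybean_flowering_periods: frozenset[str] = SOYBEAN_FLOWERING_PERIODS,
) -> float:
    """Total landscape floral-resource volume (mm³) in one buffer.

    ``areas`` maps land_type -> m² inside the buffer (from
    :func:`area_within_radius`); ``category_of`` maps land_type to its
    resource category.  Resource-providing land contributes
    area × median density for the period.  Unknown land (plus soybean
    during its flowering periods) is imputed: the ``median`` variant
    assigns the median of the densities of the land types present within
    this buffer and period, the ``minimum`` variant assigns zero.  Soybean
    outside its flowering periods and non-resource land contribute zero.
    A resource-providing land type with no median entry for the period is
    demoted to unknown with a warning.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    med = median_table[median_table["period"] == period].set_index("land_type")[
        "median_density_mm3_m2"
    ]
    resource_total = 0.0
    unknown_area = 0.0
    local_densities: list[float] = []
    for land_type, area in areas.items():
        cat = category_of.get(land_type)
        if cat is None:
            raise KeyError(f"land type {land_type!r} has no category")
        if cat == "non_resource":
            continue
        if cat == "soybean":
            if period in soybean_flowering_periods:
                unknown_area += area
            continue
        if cat == "unknown":
            unknown_area += area
            continue
        # resource-providing
        if land_type in med.index:
            d = float(med.loc[land_type])
            local_densities.append(d)
            resource_total += area * d
        else:
            warnings.warn(
                f"no median density for resource-providing land type "
                f"{land_type!r} in period {period}; treating as unknown",
                ImputationNeededWarning,
                stacklevel=2,
            )
            unknown_area += area
    if unknown_area > 0 and variant == "median" and local_densities:
        resource_total += unknown_area * float(np.median(local_densities))
    return resource_total


def landscape_resource_table(
    patches: Sequence[LandPatch],
    locations: pd.DataFrame,
    median_table: pd.DataFrame,
    radii_m: Sequence[float] = RADII_M,
    variants: Sequence[str] = VARIANTS,
    periods: Sequence[str] = PERIODS,
    soybean_flowering_periods: frozenset[str] = SOYBEAN_FLOWERING_PERIODS,
) -> pd.DataFrame:
    """Total floral volume per (location, period, radius, variant).

    ``locations`` has columns location_id, x_m, y_m.  Returns a long
    DataFrame with columns location_id, period, radius_m, variant,
    total_mm3.  The minimum-variant total never exceeds the median-variant
    total for the same key.
    """
    category_of = {p.land_type: p.category for p in patches}
    rows = []
    for loc in locations.itertuples(index=False):
        for radius in radii_m:
            areas = area_within_radius(patches, (loc.x_m, loc.y_m), radius)
            for period in periods:
                for variant in variants:
                    total = landscape_total(
                        median_table,
                        areas,
                        period,
                        variant,
                        category_of,
                        soybean_flowering_periods,
                    )
                    rows.append(
                        {
                            "location_id": loc.location_id,
                            "period": period,
                            "radius_m": radius,
                            "variant": variant,
                            "total_mm3": total,
                        }
                    )
    return pd.DataFrame(rows)


def filter_observations(
    shade_temp_c: float, mean_wind_ms: float, max_wind_ms: float
) -> bool:
    """Whether an observation bout met the survey weather conditions.

    Valid iff shaded temperature above 11.9 °C, mean wind below 1.9 m/s and
    maximum wind below 4.0 m/s — all strict inequalities.
    """
    vals = (shade_temp_c, mean_wind_ms, max_wind_ms)
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
        raise IncompleteRecordError(f"missing weather field in {vals}")
    return shade_temp_c > 11.9 and mean_wind_ms < 1.9 and max_wind_ms < 4.0
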