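"""Synthetic study-shaped datasets with known ground truth.

The generator emulates the structure of a season-long farm survey: ~27
sites, each an independent landscape tile with an irregular (Voronoi)
mosaic of land patches classed as non-resource / resource-providing /
unknown / soybean; 1–6 sampling locations per site (~102 total); four
within-season time periods; 1.5 m × 1.5 m floral quadrats on each
transect; genus-specific foraging windows; and ZINB-distributed visit
counts with crossed site and period random intercepts driven by one of
the competing resource hypotheses.

Two entry points matter for testing:

* the **geometry path** (:func:`generate_landscape`,
  :func:`generate_floral_data`, :func:`true_resource_table`) exercises the
  full pipeline from patches and quadrats up, storing the generating truth
  for recovery checks;
* the **panel path** (:func:`generate_predictor_panel`,
  :func:`generate_visits`) skips the geometry and draws the predictor
  panel directly, for fast estimation/selection simulations at large n.

Every routine takes an explicit ``numpy`` Generator or seed; identical
seeds give identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram

from .landscape import (
    PERIODS,
    QUADRAT_AREA_M2,
    RADII_M,
    LandPatch,
    landtype_median,
    landscape_resource_table,
    transect_density,
)
from .predictors import build_predictor_table, observation_minutes
from .zinb import ModelSpec, ZinbData, fit_zinb, simulate_response

__all__ = [
    "SimulationConfig",
    "LAND_TYPES",
    "CUCURBIT_SPECIES",
    "generate_landscape",
    "generate_species_pool",
    "generate_floral_data",
    "true_resource_table",
    "generate_predictor_panel",
    "generate_visits",
    "run_end_to_end",
    "write_dataset",
]

#: Land types by category.  Resource-providing types have nonzero seasonal
#: density curves; unknown and soybean types have true densities that the
#: estimation pipeline must impute.
LAND_TYPES: dict[str, str] = {
    "developed": "non_resource",
    "cereal_crop": "non_resource",
    "meadow": "resource_providing",
    "forest_edge": "resource_providing",
    "orchard": "resource_providing",
    "berry_field": "resource_providing",
    "squash_field": "resource_providing",
    "cucumber_field": "resource_providing",
    "unknown_crop": "unknown",
    "hedgerow": "unknown",
    "soybean": "soybean",
}

#: Plant species rewarding for squash bees (cucurbit specialists).
CUCURBIT_SPECIES = ("Cucurbita_pepo", "Cucumis_sativus")

#: Seasonal multiplier of floral density per resource land type: meadows
#: peak mid-season, orchards and forest edges early, cucurbit fields late.
_SEASON_CURVES: dict[str, tuple[float, float, float, float]] = {
    "meadow": (0.6, 1.0, 1.0, 0.4),
    "forest_edge": (1.0, 0.7, 0.3, 0.1),
    "orchard": (1.0, 0.4, 0.1, 0.05),
    "berry_field": (0.5, 1.0, 0.6, 0.2),
    "squash_field": (0.0, 0.1, 1.0, 0.8),
    "cucumber_field": (0.0, 0.2, 1.0, 0.7),
    "unknown_crop": (0.4, 0.8, 0.8, 0.3),
    "hedgerow": (0.8, 0.6, 0.4, 0.2),
    "soybean": (0.0, 0.7, 1.0, 0.0),
}

#: Periods each genus forages in (first period = foraging onset).
FORAGING_WINDOWS: dict[str, tuple[str, ...]] = {
    "Andrena": ("T1", "T2", "T3", "T4"),
    "Bombus": ("T1", "T2", "T3", "T4"),
    "Halictus": ("T1", "T2", "T3", "T4"),
    "Lasioglossum": ("T1", "T2", "T3", "T4"),
    "Megachile": ("T2", "T3", "T4"),
    "Peponapis": ("T3", "T4"),
}

#: Focal regressor(s) and signs for each generating hypothesis.
HYPOTHESIS_EFFECTS: dict[str, dict[str, float]] = {
    "H0": {},
    "H1": {"transect_fr": 1.0},
    "H2a": {"present_fr": 1.0},
    "H2b": {"present_fr": -1.0},
    "H3a": {"first_period_fr": 1.0, "change_in_fr": 1.0},
    "H3b": {"cumulative_fr": 1.0},
}


@dataclass
class SimulationConfig:
    """All knobs of the generator, with study-shaped defaults."""

    seed: int = 20160520
    n_sites: int = 27
    locations_per_site: tuple[int, int] = (1, 6)
    n_locations: int = 102
    tile_size_m: float = 2500.0
    tile_spacing_m: float = 20000.0
    patches_per_tile: int = 40
    # area proportions by category; resource split evenly over its types
    category_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "non_resource": 0.452,
            "resource_providing": 0.40,
            "unknown": 0.048,
            "soybean": 0.10,
        }
    )
    n_species: int = 30
    # per-land-type peak floral density, mm^3 per m^2
    peak_density: float = 2.0e4
    quadrat_dispersion: float = 1.5
    # response model truth
    hypothesis: str = "H3a"
    effect_size: float = 1.0
    beta0: float = 1.0
    beta_all_other_visits: float = 0.0
    theta: float = 1.5
    pi: float = 0.15
    sigma2_site: float = 0.25
    sigma2_period: float = 0.09
    taxon: str = "Lasioglossum"
    radius_m: int = 500

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Landscape geometry


def _assign_land_types(
    n: int, proportions: Mapping[str, float], rng: np.random.Generator
) -> list[str]:
    cats = list(proportions)
    probs = np.array([proportions[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    by_cat: dict[str, list[str]] = {}
    for lt, cat in LAND_TYPES.items():
        by_cat.setdefault(cat, []).append(lt)
    out = []
    for c in rng.choice(len(cats), size=n, p=probs):
        types = by_cat[cats[c]]
        out.append(types[rng.integers(len(types))])
    return out


def generate_landscape(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[LandPatch], pd.DataFrame]:
    """Voronoi landscape tiles and sampling locations.

    Each site is an independent square tile tessellated into irregular
    patches; tiles sit far apart on a grid so sites are spatially
    independent.  Locations are placed inside resource-providing patches,
    at least 10 m from the patch edge whenever the patch is wide enough to
    allow it.  Returns (patches, locations) with locations columns
    site_id, location_id, x_m, y_m, land_type, transect_length_m,
    transect_width_m.
    """
    rng = config.rng() if rng is None else rng
    props = dict(config.category_proportions)
    if sum(props.values()) > 1.0 + 1e-9:
        raise ValueError("category proportions must sum to <= 1")
    patches: list[LandPatch] = []
    loc_rows = []
    n_cols = int(np.ceil(np.sqrt(config.n_sites)))
    # per-site location counts: uniform in the configured range, then
    # adjusted to hit the configured total
    lo, hi = config.locations_per_site
    # widen the per-site range if the requested total cannot fit it
    lo = min(lo, config.n_locations // config.n_sites)
    hi = max(hi, -(-config.n_locations // config.n_sites))
    counts = rng.integers(lo, hi + 1, size=config.n_sites)
    for _ in range(100 * config.n_sites):
        diff = int(counts.sum()) - config.n_locations
        if diff == 0:
            break
        i = rng.integers(config.n_sites)
        if diff > 0 and counts[i] > lo:
            counts[i] -= 1
        elif diff < 0 and counts[i] < hi:
            counts[i] += 1
    else:  # pragma: no cover - range always admits the total after widening
        raise ValueError("cannot distribute locations across sites")

    # occasional non-standard transects (short rows / single crop row)
    transect_dims = np.array([[30, 4], [30, 2], [25, 4], [24, 4]], dtype=float)
    dim_probs = np.array([89, 8, 1, 4], dtype=float)
    dim_probs /= dim_probs.sum()

    loc_counter = 0
    for s in range(config.n_sites):
        ox = (s % n_cols) * config.tile_spacing_m
        oy = (s // n_cols) * config.tile_spacing_m
        tile = box(ox, oy, ox + config.tile_size_m, oy + config.tile_size_m)
        pts = rng.uniform(0, config.tile_size_m, size=(config.patches_per_tile, 2))
        pts += (ox, oy)
        cells = voronoi_diagram(MultiPoint([Point(*p) for p in pts]), envelope=tile)
        site_patches = []
        for g in cells.geoms:
            poly = g.intersection(tile)
            if poly.is_empty or poly.area <= 0:
                continue
            site_patches.append(poly)
        types = _assign_land_types(len(site_patches), props, rng)
        resource_polys = []
        for j, (poly, lt) in enumerate(zip(site_patches, types)):
            pid = f"S{s:02d}P{j:03d}"
            patches.append(
                LandPatch(patch_id=pid, polygon=poly, land_type=lt, category=LAND_TYPES[lt])
            )
            if LAND_TYPES[lt] == "resource_providing":
                resource_polys.append((poly, lt))
        if not resource_polys:
            # guarantee at least one resource patch per site
            j = rng.integers(len(site_patches))
            lt = "meadow"
            patches[-len(site_patches) + j] = LandPatch(
                patch_id=patches[-len(site_patches) + j].patch_id,
                polygon=site_patches[j],
                land_type=lt,
                category="resource_providing",
            )
            resource_polys.append((site_patches[j], lt))
        for _ in range(int(counts[s])):
            poly, lt = resource_polys[rng.integers(len(resource_polys))]
            minx, miny, maxx, maxy = poly.bounds
            wide = min(maxx - minx, maxy - miny) > 25.0
            target = poly.buffer(-10.0) if wide else poly
            if target.is_empty:
                target = poly
            for _try in range(200):
                x = rng.uniform(minx, maxx)
                y = rng.uniform(miny, maxy)
                if target.contains(Point(x, y)):
                    break
            else:  # fall back to a representative interior point
                rp = target.representative_point()
                x, y = rp.x, rp.y
            dims = transect_dims[rng.choice(4, p=dim_probs)]
            loc_rows.append(
                {
                    "site_id": f"S{s:02d}",
                    "location_id": f"L{loc_counter:03d}",
                    "x_m": x,
                    "y_m": y,
                    "land_type": lt,
                    "transect_length_m": dims[0],
                    "transect_width_m": dims[1],
                }
            )
            loc_counter += 1
    return patches, pd.DataFrame(loc_rows)


# ---------------------------------------------------------------------------
# Floral data


def generate_species_pool(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    reward_exponent: float = 1.0,
    reward_noise_sd: float = 0.8,
) -> pd.DataFrame:
    """Species table with log-normal floral dimensions and rewards.

    Rewards follow ``reward = c * volume**reward_exponent * lognormal
    noise`` so the proxy's log–log correlation has a known generating
    structure; nectar is present for ~half the pool and pollen for ~a
    third, with a mix of measurement sources.  Two cucurbit crop species
    and a couple of capitulum-counted (Asteraceae-like) species are always
    included.
    """
    rng = config.rng() if rng is None else rng
    n = config.n_species
    ids = [f"sp{i:02d}" for i in range(n - 2)] + list(CUCURBIT_SPECIES)
    length = np.exp(rng.normal(np.log(8.0), 0.7, size=n))
    width = length * np.exp(rng.normal(-0.1, 0.3, size=n))
    height = np.exp(rng.normal(np.log(6.0), 0.6, size=n))
    # cucurbit flowers are large
    length[-2:] = [95.0, 40.0]
    width[-2:] = [90.0, 38.0]
    height[-2:] = [45.0, 30.0]
    volume = np.pi * np.maximum(length, width) / 2 * np.minimum(length, width) / 2 * height
    fpi = np.where(rng.random(n) < 0.4, np.round(np.exp(rng.normal(1.5, 0.8, size=n))) + 1, 1.0)
    unit = np.where(rng.random(n) < 0.15, "capitulum", "flower")
    unit[-2:] = "flower"
    source = rng.choice(["field", "literature", "combined"], size=n, p=[0.6, 0.3, 0.1])
    nectar = np.where(
        rng.random(n) < 0.55,
        0.05 * volume**reward_exponent * np.exp(rng.normal(0, reward_noise_sd, n)),
        np.nan,
    )
    pollen = np.where(
        rng.random(n) < 0.38,
        0.002 * volume**reward_exponent * np.exp(rng.normal(0, reward_noise_sd, n)),
        np.nan,
    )
    return pd.DataFrame(
        {
            "species_id": ids,
            "length_mm": length,
            "width_mm": width,
            "height_mm": height,
            "flowers_per_inflorescence": fpi,
            "floral_unit": unit,
            "source": source,
            "nectar_ug_day": nectar,
            "pollen_ul": pollen,
        }
    )


def true_density_table(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """True floral density (mm³/m²) per (land_type, period).

    Peak density is scaled by each land type's seasonal curve with a small
    lognormal wobble; non-resource land is always zero.
    """
    rng = config.rng() if rng is None else rng
    rows = []
    for lt, cat in LAND_TYPES.items():
        if cat == "non_resource":
            continue
        curve = _SEASON_CURVES[lt]
        scale = config.peak_density * np.exp(rng.normal(0, 0.3))
        for p, mult in zip(PERIODS, curve):
            rows.append(
                {
                    "land_type": lt,
                    "period": p,
                    "true_density_mm3_m2": scale * mult,
                }
            )
    return pd.DataFrame(rows)


def _species_for_land_type(
    land_type: str, species: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    if land_type == "squash_field":
        return species[species["species_id"] == "Cucurbita_pepo"]
    if land_type == "cucumber_field":
        return species[species["species_id"] == "Cucumis_sativus"]
    pool = species[~species["species_id"].isin(CUCURBIT_SPECIES)]
    k = min(3, len(pool))
    idx = rng.choice(len(pool), size=k, replace=False)
    return pool.iloc[idx]


def generate_floral_data(
    config: SimulationConfig,
    patches: Sequence[LandPatch],
    locations: pd.DataFrame,
    rng: np.random.Generator | None = None,
    species: pd.DataFrame | None = None,
    density: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Quadrat flower counts whose expected transect density equals the
    local land-type truth.

    For each sampled location × period, 3 quadrats (a 4th only when the
    first three were empty) draw per-species counts from a negative
    binomial whose mean makes E[count × per-flower volume / 2.25 m²] equal
    the land type's true density.  Capitulum species are counted as single
    flower heads.  Returns dict with species, quadrats, density (truth),
    and the species->volume map used.
    """
    from .floral_geometry import species_frame

    rng = config.rng() if rng is None else rng
    if species is None:
        species = generate_species_pool(config, rng)
    if density is None:
        density = true_density_table(config, rng)
    sp = species_frame(species)
    volumes = dict(zip(sp["species_id"], sp["volume"]))
    dens = density.set_index(["land_type", "period"])["true_density_mm3_m2"]
    # sorted so rng consumption is independent of hash randomisation
    lt_species = {
        lt: _species_for_land_type(lt, sp, rng)
        for lt in sorted({p.land_type for p in patches} | set(locations["land_type"]))
        if LAND_TYPES[lt] != "non_resource"
    }
    rows = []
    disp = config.quadrat_dispersion
    for loc in locations.itertuples(index=False):
        lt = loc.land_type
        chosen = lt_species[lt]
        shares = np.full(len(chosen), 1.0 / len(chosen))
        for period in PERIODS:
            d = float(dens.get((lt, period), 0.0))
            if d <= 0:
                continue  # location not sampled: no open flowers
            def draw_quadrat(q: int) -> bool:
                # returns True when the quadrat held any open flowers; an
                # empty quadrat is registered with an explicit zero row so
                # it still enters the transect mean
                any_flowers = False
                for share, srow in zip(shares, chosen.itertuples(index=False)):
                    mean = d * share * QUADRAT_AREA_M2 / volumes[srow.species_id]
                    p_nb = disp / (disp + mean)
                    c = int(rng.negative_binomial(disp, p_nb))
                    if c > 0:
                        any_flowers = True
                        rows.append(
                            {
                                "location_id": loc.location_id,
                                "period": period,
                                "quadrat_id": q,
                                "species_id": srow.species_id,
                                "open_flower_count": c,
                            }
                        )
                if not any_flowers:
                    rows.append(
                        {
                            "location_id": loc.location_id,
                            "period": period,
                            "quadrat_id": q,
                            "species_id": chosen.iloc[0]["species_id"],
                            "open_flower_count": 0,
                        }
                    )
                return any_flowers

            drew_any = False
            for q in (1, 2, 3):
                drew_any |= draw_quadrat(q)
            if not drew_any:
                # a 4th quadrat is attempted only when the first 3 were empty
                draw_quadrat(4)
    quadrats = pd.DataFrame(
        rows,
        columns=["location_id", "period", "quadrat_id", "species_id", "open_flower_count"],
    )
    return {
        "species": species,
        "quadrats": quadrats,
        "density": density,
        "volumes": volumes,
    }


def true_resource_table(
    config: SimulationConfig,
    patches: Sequence[LandPatch],
    locations: pd.DataFrame,
    density: pd.DataFrame,
    radii_m: Sequence[float] = RADII_M,
) -> pd.DataFrame:
    """Ground-truth landscape totals: true density × exact land-type areas.

    Unknown and soybean land contribute their *true* densities (soybean
    only in its flowering periods via its zero curve entries), so the
    estimation pipeline's imputation can be judged against this table.
    Returns columns location_id, period, radius_m, total_mm3 with
    variant = 'truth'.
    """
    from .landscape import area_within_radius

    dens = density.set_index(["land_type", "period"])["true_density_mm3_m2"]
    rows = []
    for loc in locations.itertuples(index=False):
        for radius in radii_m:
            areas = area_within_radius(patches, (loc.x_m, loc.y_m), radius)
            for period in PERIODS:
                total = sum(
                    a * float(dens.get((lt, period), 0.0))
                    for lt, a in areas.items()
                )
                rows.append(
                    {
                        "location_id": loc.location_id,
                        "period": period,
                        "radius_m": radius,
                        "variant": "truth",
                        "total_mm3": total,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fast panel path (no geometry)


def generate_predictor_panel(
    n_sites: int,
    locations_per_site: int,
    rng: np.random.Generator,
    periods: Sequence[str] = PERIODS,
    first_period: str = "T1",
    decline_prob: float = 0.5,
) -> pd.DataFrame:
    """Draw a predictor panel directly (no landscape geometry).

    Per location the cube-root landscape resource series follows a
    site-level log-normal baseline with a seasonal trajectory that
    declines in later periods for ``decline_prob`` of locations and rises
    for the rest, so FirstTimePeriodFR, ChangeInFR, CumulativeFR and
    PresentFR all vary and are only moderately correlated.  All resource
    regressors are z-scored across the panel; ``visits`` is left for
    :func:`generate_visits` to fill.
    """
    from .predictors import change_in_fr, cumulative_fr

    periods = list(periods)
    first_idx = periods.index(first_period)
    rows = []
    site_base = rng.normal(0.0, 0.4, size=n_sites)
    for s in range(n_sites):
        for l in range(locations_per_site):
            loc = f"S{s:02d}L{l:02d}"
            declining = rng.random() < decline_prob
            level = 25.0 * np.exp(site_base[s] + rng.normal(0, 0.4))
            # cube-root-scale series with period-to-period noise
            drift = -0.2 if declining else 0.15
            series = {}
            val = level * np.exp(rng.normal(0, 0.25))
            for k, p in enumerate(periods):
                if k:
                    val = max(val * np.exp(drift + rng.normal(0, 0.3)), 1.0)
                series[p] = val
            minutes = float(rng.choice([30.0, 15.0, 25.0, 24.0], p=[0.87, 0.08, 0.01, 0.04]))
            for k, p in enumerate(periods[first_idx:], start=first_idx):
                rows.append(
                    {
                        "site_id": f"S{s:02d}",
                        "location_id": loc,
                        "period": p,
                        "transect_fr": float(np.exp(rng.normal(2.5, 0.8))),
                        "present_fr": series[p],
                        "first_period_fr": series[first_period],
                        "change_in_fr": change_in_fr(series, first_period, p, periods),
                        "cumulative_fr": cumulative_fr(series, first_period, p, periods),
                        "all_other_visits": int(rng.poisson(40)),
                        "observation_time": minutes,
                    }
                )
    panel = pd.DataFrame(rows)
    return panel


RESOURCE_TERMS = (
    "transect_fr",
    "present_fr",
    "first_period_fr",
    "change_in_fr",
    "cumulative_fr",
)


def standardize(panel: pd.DataFrame, columns: Sequence[str] = RESOURCE_TERMS) -> pd.DataFrame:
    """Z-score the given columns (in place on a copy); zero-variance
    columns are left centred."""
    out = panel.copy()
    for c in columns:
        x = out[c].to_numpy(dtype=float)
        sd = x.std()
        out[c] = (x - x.mean()) / sd if sd > 0 else x - x.mean()
    return out


def generate_visits(
    config: SimulationConfig,
    panel: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw ZINB visit counts onto a predictor panel under the configured
    generating hypothesis.

    The linear predictor is ``beta0 + sum(beta_t * x_t) + log(minutes) +
    u_site + v_period`` on z-scored resource regressors; the hypothesis
    fixes which betas are nonzero (H2b's present-resource effect is
    negative — dilution).  Returns (panel with ``visits``, truth dict with
    betas and latent effects).
    """
    rng = config.rng() if rng is None else rng
    if config.hypothesis not in HYPOTHESIS_EFFECTS:
        raise ValueError(f"unknown hypothesis {config.hypothesis!r}")
    effects = {
        t: sgn * config.effect_size
        for t, sgn in HYPOTHESIS_EFFECTS[config.hypothesis].items()
    }
    panel = standardize(panel)
    sites = pd.Categorical(panel["site_id"])
    pers = pd.Categorical(panel["period"])
    u = rng.normal(0.0, np.sqrt(config.sigma2_site), size=len(sites.categories))
    v = rng.normal(0.0, np.sqrt(config.sigma2_period), size=len(pers.categories))
    eta = np.full(len(panel), config.beta0)
    for t, b in effects.items():
        eta += b * panel[t].to_numpy(dtype=float)
    eta += config.beta_all_other_visits * panel["all_other_visits"].to_numpy(dtype=float)
    eta += np.log(panel["observation_time"].to_numpy(dtype=float))
    eta += u[sites.codes] + v[pers.codes]
    mu = np.exp(eta)
    p_nb = config.theta / (config.theta + mu)
    y = rng.negative_binomial(config.theta, p_nb)
    if config.pi > 0:
        y = np.where(rng.random(len(y)) < config.pi, 0, y)
    out = panel.copy()
    out["visits"] = y.astype(int)
    truth = {
        "hypothesis": config.hypothesis,
        "beta0": config.beta0,
        "effects": effects,
        "beta_all_other_visits": config.beta_all_other_visits,
        "theta": config.theta,
        "pi": config.pi,
        "sigma2_site": config.sigma2_site,
        "sigma2_period": config.sigma2_period,
        "u_site": u.tolist(),
        "v_period": v.tolist(),
    }
    return out, truth


# ---------------------------------------------------------------------------
# End to end


def run_end_to_end(
    config: SimulationConfig,
    radii_m: Sequence[int] | None = None,
) -> dict:
    """Full pipeline on one generated dataset.

    Generates a landscape + floral data, estimates the landscape resource
    table from quadrats (both imputation variants), builds predictors from
    the *true* resource series for the response draw, fits every candidate
    model on the *estimated* predictors, and runs summed-ΔAICc selection.
    Returns a report with the winning hypothesis, the truth, and averaged
    coefficients for the winner.
    """
    from .selection import CandidateModel, enumerate_models, model_average, select

    rng = config.rng()
    radii = list(radii_m) if radii_m is not None else [config.radius_m]
    patches, locations = generate_landscape(config, rng)
    floral = generate_floral_data(config, patches, locations, rng)

    # estimated resource table from quadrats
    dens_rows = []
    for (loc_id, period), grp in floral["quadrats"].groupby(["location_id", "period"]):
        lt = locations.set_index("location_id").loc[loc_id, "land_type"]
        dens_rows.append(
            {
                "location_id": loc_id,
                "land_type": lt,
                "period": period,
                "density_mm3_m2": transect_density(grp, floral["volumes"]),
            }
        )
    transect_table = pd.DataFrame(dens_rows)
    medians = landtype_median(transect_table)
    resources = landscape_resource_table(
        patches, locations, medians, radii_m=radii
    )

    # truth-driven response
    truth_resources = true_resource_table(
        config, patches, locations, floral["density"], radii_m=radii
    )
    panel = _panel_from_tables(
        config, locations, transect_table, truth_resources, radii[0], rng
    )
    panel, truth = generate_visits(config, panel, rng)

    # estimated predictors join: replace resource terms with estimates
    est_panels = {}
    for variant in ("median", "minimum"):
        est = _panel_from_tables(
            config,
            locations,
            transect_table,
            resources[resources["variant"] == variant],
            radii[0],
            rng,
            visits=panel["visits"].to_numpy(),
        )
        est_panels[variant] = standardize(est)

    fits = {}
    for cand in enumerate_models(
        config.taxon, radii_m=radii
    ):
        frame = est_panels[cand.variant]
        data = ZinbData.from_frame(frame, cand.spec)
        try:
            fit = fit_zinb(data, spec=cand.spec)
        except Exception:
            continue
        if fit.converged:
            fits[cand] = fit
    result = select(fits)
    avg = {
        variant: model_average(fits, result.winner[0], variant)
        for variant in ("median", "minimum")
    }
    result.averaged = avg
    return {
        "truth": truth,
        "selection": result,
        "winner": result.winner,
        "n_rows": len(panel),
        "fits": fits,
        "panel": panel,
    }


def _panel_from_tables(
    config: SimulationConfig,
    locations: pd.DataFrame,
    transect_table: pd.DataFrame,
    resources: pd.DataFrame,
    radius_m: int,
    rng: np.random.Generator,
    visits: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble a model panel from resource/transect tables (one radius).

    The foraging window of the configured taxon fixes the first period.
    ``visits`` can inject an already-drawn response (so estimated-predictor
    panels model the same counts as the truth panel).
    """
    from .predictors import change_in_fr, cube_root, cumulative_fr

    window = FORAGING_WINDOWS.get(config.taxon, PERIODS)
    first = window[0]
    sub = resources[resources["radius_m"] == radius_m]
    tt = transect_table.set_index(["location_id", "period"])
    loc_meta = locations.set_index("location_id")
    rows = []
    for loc_id, grp in sub.groupby("location_id"):
        raw = grp.set_index("period")["total_mm3"].to_dict()
        series = {p: cube_root(v) for p, v in raw.items()}
        meta = loc_meta.loc[loc_id]
        for p in window:
            if (loc_id, p) not in tt.index:
                continue
            td = float(tt.loc[(loc_id, p), "density_mm3_m2"])
            rows.append(
                {
                    "site_id": meta["site_id"],
                    "location_id": loc_id,
                    "period": p,
                    "transect_fr": cube_root(td),
                    "present_fr": series[p],
                    "first_period_fr": series[first],
                    "change_in_fr": change_in_fr(series, first, p),
                    "cumulative_fr": cumulative_fr(series, first, p),
                    "all_other_visits": int(rng.poisson(40)),
                    "observation_time": observation_minutes(
                        float(meta["transect_length_m"]),
                        float(meta["transect_width_m"]),
                    ),
                }
            )
    panel = pd.DataFrame(rows).sort_values(["location_id", "period"]).reset_index(drop=True)
    if visits is not None:
        panel["visits"] = visits[: len(panel)]
    return panel


def write_dataset(config: SimulationConfig, out_dir) -> dict[str, str]:
    """Write the file set the pipeline consumes (patches.geojson,
    species.csv, quadrats.csv, locations.csv, weather.csv, visits.csv,
    truth.json) for one simulated study."""
    import json
    from pathlib import Path

    from shapely.geometry import mapping

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = config.rng()
    patches, locations = generate_landscape(config, rng)
    floral = generate_floral_data(config, patches, locations, rng)
    truth_res = true_resource_table(
        config, patches, locations, floral["density"], radii_m=[config.radius_m]
    )
    # weather: bouts that all pass the survey thresholds, with wobble
    weather = pd.DataFrame(
        {
            "location_id": np.repeat(locations["location_id"].to_numpy(), len(PERIODS)),
            "period": np.tile(PERIODS, len(locations)),
            "shade_temp_c": rng.normal(25.3, 4.0, size=len(locations) * len(PERIODS)).round(1),
            "mean_wind_ms": np.abs(rng.normal(0.6, 0.4, size=len(locations) * len(PERIODS))).round(2),
            "max_wind_ms": np.abs(rng.normal(1.5, 0.8, size=len(locations) * len(PERIODS))).round(2),
        }
    )
    # transect densities from quadrats, then a truth-driven panel + visits
    dens_rows = []
    for (loc_id, period), grp in floral["quadrats"].groupby(["location_id", "period"]):
        lt = locations.set_index("location_id").loc[loc_id, "land_type"]
        dens_rows.append(
            {
                "location_id": loc_id,
                "land_type": lt,
                "period": period,
                "density_mm3_m2": transect_density(grp, floral["volumes"]),
            }
        )
    transect_table = pd.DataFrame(dens_rows)
    panel = _panel_from_tables(
        config, locations, transect_table, truth_res, config.radius_m, rng
    )
    panel, truth = generate_visits(config, panel, rng)
    visits = panel[["location_id", "period", "visits"]].copy()
    visits["taxon"] = config.taxon

    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(p.polygon),
                "properties": {
                    "patch_id": p.patch_id,
                    "land_type": p.land_type,
                    "category": p.category,
                },
            }
            for p in patches
        ],
    }
    files = {}
    (out / "patches.geojson").write_text(json.dumps(fc))
    files["patches"] = str(out / "patches.geojson")
    for name, df in [
        ("species", floral["species"]),
        ("quadrats", floral["quadrats"]),
        ("locations", locations),
        ("weather", weather),
        ("visits", visits),
    ]:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        files[name] = str(path)
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    files["truth"] = str(out / "truth.json")
    return files
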