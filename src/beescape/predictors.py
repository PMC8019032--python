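"""Temporal floral-resource predictors for bee-visit models.

For each (taxon, location, period) observation row the candidate models use
a small set of regressors built from cube-root-transformed floral-resource
volumes:

* ``TransectFR`` — floral volume within the transect itself;
* ``PresentFR`` — landscape total within a radius, current period;
* ``FirstTimePeriodFR`` — landscape total in the taxon's first foraging
  period (the earliest period with any visit by that taxon);
* ``ChangeInFR`` — the accumulated *negative* changes in landscape total
  since the first foraging period (increases count as zero change);
* ``CumulativeFR`` — the running sum of landscape totals from the first
  foraging period through the present one;
* ``AllOtherVisits`` — visits by all bees other than the focal taxon in the
  same transect and period;
* ``ObservationTime`` — observation minutes (the models use its log as an
  offset).

By default the cube-root transform is applied to each period's volume
*before* the temporal difference/sum operators; set
``transform_first=False`` to difference raw volumes and transform after.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .landscape import PERIODS

__all__ = [
    "cube_root",
    "change_in_fr",
    "cumulative_fr",
    "first_period_fr",
    "all_other_visits",
    "observation_minutes",
    "build_predictor_table",
]


class MissingPeriodError(ValueError):
    """The per-period resource series has a gap inside the foraging window."""


class NoForagingOnsetError(ValueError):
    """The focal taxon was never observed, so no first foraging period exists."""


def cube_root(volume: float | np.ndarray) -> float | np.ndarray:
    """Cube-root transform used on all floral-volume quantities."""
    v = np.asarray(volume, dtype=float)
    if np.any(v < 0):
        raise ValueError("volumes must be non-negative")
    out = np.cbrt(v)
    return float(out) if out.ndim == 0 else out


def _window(
    fr_series: Mapping[str, float],
    first_period: str,
    current_period: str,
    periods: Sequence[str] = PERIODS,
) -> list[float]:
    i0, i1 = periods.index(first_period), periods.index(current_period)
    if i1 < i0:
        raise ValueError(
            f"current period {current_period} precedes first period {first_period}"
        )
    window = []
    for p in periods[i0 : i1 + 1]:
        if p not in fr_series:
            raise MissingPeriodError(f"resource series missing period {p}")
        window.append(float(fr_series[p]))
    return window


def change_in_fr(
    fr_series: Mapping[str, float],
    first_period: str,
    current_period: str,
    periods: Sequence[str] = PERIODS,
) -> float:
    """Accumulated negative change in the resource series (ΔFR ≤ 0).

    Sums ``min(0, FR_j − FR_{j−1})`` over successive periods from the first
    foraging period to the current one; any non-decreasing series gives 0,
    and the first period itself gives 0.
    """
    w = _window(fr_series, first_period, current_period, periods)
    return float(sum(min(0.0, b - a) for a, b in zip(w, w[1:])))


def cumulative_fr(
    fr_series: Mapping[str, float],
    first_period: str,
    current_period: str,
    periods: Sequence[str] = PERIODS,
) -> float:
    """Running sum of the resource series from the first foraging period
    through the current period (inclusive)."""
    return float(sum(_window(fr_series, first_period, current_period, periods)))


def first_period_fr(
    fr_series: Mapping[str, float],
    taxon_first_period: str | None,
) -> float:
    """Resource value at the taxon's first foraging period."""
    if taxon_first_period is None:
        raise NoForagingOnsetError("taxon was never observed visiting flowers")
    if taxon_first_period not in fr_series:
        raise MissingPeriodError(
            f"resource series missing first period {taxon_first_period}"
        )
    return float(fr_series[taxon_first_period])


def taxon_first_period(
    visits: pd.DataFrame, taxon: str, periods: Sequence[str] = PERIODS
) -> str | None:
    """Earliest period with any visit by ``taxon`` across the dataset."""
    sub = visits[(visits["taxon"] == taxon) & (visits["visits"] > 0)]
    seen = set(sub["period"])
    for p in periods:
        if p in seen:
            return p
    return None


def all_other_visits(
    visits: pd.DataFrame, focal_taxon: str, location_id: str, period: str
) -> int:
    """Visits at (location, period) by every taxon except the focal one."""
    sub = visits[
        (visits["location_id"] == location_id)
        & (visits["period"] == period)
        & (visits["taxon"] != focal_taxon)
    ]
    return int(sub["visits"].sum())


def observation_minutes(
    transect_length_m: float, transect_width_m: float
) -> float:
    """Observation time for a transect: 1 minute per 4 m² of transect area
    (the default 30 m × 4 m transect gives 30 min)."""
    area = transect_length_m * transect_width_m
    if area <= 0:
        raise ValueError("transect area must be positive")
    return area / 4.0


def build_predictor_table(
    resources: pd.DataFrame,
    transect_fr: pd.DataFrame,
    visits: pd.DataFrame,
    taxon: str,
    radii_m: Sequence[float] | None = None,
    periods: Sequence[str] = PERIODS,
    transform_first: bool = True,
) -> pd.DataFrame:
    """Assemble the regressor table for one taxon.

    Parameters
    ----------
    resources
        Long table (location_id, period, radius_m, variant, total_mm3) from
        the landscape module.
    transect_fr
        Table (location_id, period, volume_mm3, transect_length_m,
        transect_width_m) of within-transect floral volume; rows exist only
        for sampled location × period combinations.
    visits
        Table (location_id, period, taxon, visits).
    taxon
        Focal bee taxon; its first foraging period is the earliest period
        with any visit in ``visits``.
    transform_first
        If True (default) cube-root each period's landscape total before
        the temporal operators; otherwise operate on raw volumes and
        cube-root is applied only to the present-period regressors.

    Returns a DataFrame with one row per (location_id, period, radius_m,
    variant) restricted to sampled rows and to periods from the taxon's
    first foraging period onward, carrying every regressor plus the
    response ``visits``.
    """
    if radii_m is None:
        radii_m = sorted(resources["radius_m"].unique())
    first = taxon_first_period(visits, taxon, periods)
    if first is None:
        raise NoForagingOnsetError(f"taxon {taxon!r} never observed")
    first_idx = periods.index(first)

    focal = (
        visits[visits["taxon"] == taxon]
        .set_index(["location_id", "period"])["visits"]
        .to_dict()
    )
    total_by_lp = (
        visits.groupby(["location_id", "period"])["visits"].sum().to_dict()
    )
    tf = transect_fr.set_index(["location_id", "period"])

    rows = []
    for (loc, radius, variant), grp in resources.groupby(
        ["location_id", "radius_m", "variant"]
    ):
        raw = grp.set_index("period")["total_mm3"].to_dict()
        series = (
            {p: cube_root(v) for p, v in raw.items()} if transform_first else raw
        )
        for period in periods[first_idx:]:
            if (loc, period) not in tf.index:
                continue  # location not sampled this period
            trow = tf.loc[(loc, period)]
            present = series.get(period)
            if present is None:
                raise MissingPeriodError(
                    f"no landscape total for {loc} {period} r={radius}"
                )
            delta = change_in_fr(series, first, period, periods)
            cumul = cumulative_fr(series, first, period, periods)
            first_fr = first_period_fr(series, first)
            if not transform_first:
                # signed cube root after the temporal operators
                present = cube_root(present)
                first_fr = cube_root(first_fr)
                delta = float(np.cbrt(delta))
                cumul = cube_root(cumul)
            y = int(focal.get((loc, period), 0))
            other = int(total_by_lp.get((loc, period), 0)) - y
            rows.append(
                {
                    "taxon": taxon,
                    "location_id": loc,
                    "period": period,
                    "radius_m": radius,
                    "variant": variant,
                    "visits": y,
                    "transect_fr": cube_root(float(trow["volume_mm3"])),
                    "present_fr": present,
                    "first_period_fr": first_fr,
                    "change_in_fr": delta,
                    "cumulative_fr": cumul,
                    "all_other_visits": other,
                    "observation_time": observation_minutes(
                        float(trow["transect_length_m"]),
                        float(trow["transect_width_m"]),
                    ),
                }
            )
    return pd.DataFrame(rows)
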