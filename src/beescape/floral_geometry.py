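"""Floral reward proxies from flower dimensions, and their validation.

A flower (or Asteraceae capitulum) is idealised as an elliptic cylinder:
the receptacle length and width give the ellipse axes, and the height from
the receptacle to the tip of the longest sexual organ (or corolla, when the
sexual organs are hidden) gives the cylinder height.  Surface area
``A = pi*a*b`` and volume ``V = pi*a*b*h`` — with ``a`` the semi-major and
``b`` the semi-minor axis — serve as cheap field-measurable proxies for the
nectar-sugar and pollen rewards a flower offers.

Validation compares the proxy against published per-flower reward
measurements (daily nectar sugar mass in µg/day, pollen volume in µl):
log–log Pearson correlations per dimension, and an ANCOVA testing whether
the measurement source (field calipers vs. literature vs. a combination)
changes the reward–volume slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FloralSpecies",
    "ProxyValidationResult",
    "floral_area",
    "floral_volume",
    "proxy_correlations",
    "ancova_source_test",
    "species_frame",
    "DIMENSIONS",
    "REWARDS",
]

#: Dimension columns available for correlation with rewards.
DIMENSIONS = ("length", "width", "height", "area", "volume")
#: Reward measurements a species table may carry.
REWARDS = ("nectar", "pollen")

_REWARD_COLUMNS = {"nectar": "nectar_ug_day", "pollen": "pollen_ul"}
_SOURCES = ("field", "literature", "combined")


class InvalidMeasurementError(ValueError):
    """A floral dimension is non-positive (lengths must be > 0 mm)."""


class InsufficientDataError(ValueError):
    """Fewer species than the minimum needed for the statistic."""


class DegenerateInputError(ValueError):
    """Zero variance or rank-deficient design; the statistic is undefined."""


@dataclass(frozen=True)
class FloralSpecies:
    """Per-species floral dimensions and optional measured rewards.

    Dimensions are in millimetres; ``flowers_per_inflorescence`` expands
    inflorescence counts to flower counts in quadrat data.  ``floral_unit``
    records whether the counting unit is a single flower or a capitulum
    (capitula are counted as single flowers).  ``source`` states where the
    dimension measurements came from.
    """

    species_id: str
    length_mm: float
    width_mm: float
    height_mm: float
    flowers_per_inflorescence: float = 1.0
    floral_unit: str = "flower"
    source: str = "field"
    nectar_ug_day: float | None = None
    pollen_ul: float | None = None

    def __post_init__(self) -> None:
        for name in ("length_mm", "width_mm", "height_mm"):
            v = getattr(self, name)
            if not (v > 0):
                raise InvalidMeasurementError(
                    f"{self.species_id}: {name}={v!r} must be > 0"
                )
        if self.flowers_per_inflorescence < 1:
            raise InvalidMeasurementError(
                f"{self.species_id}: flowers_per_inflorescence must be >= 1"
            )
        if self.floral_unit not in ("flower", "capitulum"):
            raise ValueError(f"unknown floral_unit {self.floral_unit!r}")
        if self.source not in _SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        for name in ("nectar_ug_day", "pollen_ul"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise InvalidMeasurementError(
                    f"{self.species_id}: {name}={v!r} must be > 0 when present"
                )

    @property
    def area_mm2(self) -> float:
        return floral_area(self.length_mm, self.width_mm)

    @property
    def volume_mm3(self) -> float:
        return floral_volume(self.length_mm, self.width_mm, self.height_mm)


def floral_area(length_mm: float, width_mm: float) -> float:
    """Elliptic flower surface area ``pi * a * b`` in mm².

    ``a = max(length, width)/2`` and ``b = min(length, width)/2``, so the
    result is symmetric in its arguments.
    """
    if not (length_mm > 0) or not (width_mm > 0):
        raise InvalidMeasurementError(
            f"dimensions must be > 0, got ({length_mm!r}, {width_mm!r})"
        )
    a = max(length_mm, width_mm) / 2.0
    b = min(length_mm, width_mm) / 2.0
    return math.pi * a * b


def floral_volume(length_mm: float, width_mm: float, height_mm: float) -> float:
    """Elliptic-cylinder flower volume ``pi * a * b * h`` in mm³."""
    if not (height_mm > 0):
        raise InvalidMeasurementError(f"height must be > 0, got {height_mm!r}")
    return floral_area(length_mm, width_mm) * height_mm


def species_frame(species: Iterable[FloralSpecies] | pd.DataFrame) -> pd.DataFrame:
    """Normalise a species table to a DataFrame with derived area/volume.

    Accepts an iterable of :class:`FloralSpecies` or a DataFrame with the
    ``species.csv`` columns (species_id, length_mm, width_mm, height_mm,
    flowers_per_inflorescence, floral_unit, source, nectar_ug_day, pollen_ul;
    blanks are missing rewards).
    """
    if isinstance(species, pd.DataFrame):
        df = species.copy()
    else:
        df = pd.DataFrame(
            {
                "species_id": s.species_id,
                "length_mm": s.length_mm,
                "width_mm": s.width_mm,
                "height_mm": s.height_mm,
                "flowers_per_inflorescence": s.flowers_per_inflorescence,
                "floral_unit": s.floral_unit,
                "source": s.source,
                "nectar_ug_day": s.nectar_ug_day,
                "pollen_ul": s.pollen_ul,
            }
            for s in species
        )
    for col in ("length_mm", "width_mm", "height_mm"):
        if (df[col] <= 0).any():
            bad = df.loc[df[col] <= 0, "species_id"].tolist()
            raise InvalidMeasurementError(f"non-positive {col} for {bad}")
    df["length"] = df["length_mm"].astype(float)
    df["width"] = df["width_mm"].astype(float)
    df["height"] = df["height_mm"].astype(float)
    ab = df[["length", "width"]].to_numpy(dtype=float)
    df["area"] = np.pi * ab.max(axis=1) / 2.0 * ab.min(axis=1) / 2.0
    df["volume"] = df["area"] * df["height"]
    return df


@dataclass(frozen=True)
class ProxyValidationResult:
    """Log–log Pearson correlations and source ANCOVAs for the reward proxy.

    ``correlations`` is a DataFrame indexed by (dimension, reward) with
    columns r, p, n.  ``ancova`` maps reward -> dict with F, df1, df2, p for
    the log(volume) × source interaction.
    """

    correlations: pd.DataFrame
    ancova: Mapping[str, Mapping[str, float]]

    def correlation(self, dimension: str, reward: str) -> tuple[float, float, int]:
        row = self.correlations.loc[(dimension, reward)]
        return float(row["r"]), float(row["p"]), int(row["n"])


def _pearson_log(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 species, got {n}")
    lx, ly = np.log(x), np.log(y)
    if np.ptp(lx) == 0 or np.ptp(ly) == 0:
        raise DegenerateInputError("zero variance on the log scale")
    r, p = stats.pearsonr(lx, ly)
    return float(r), float(p), int(n)


def proxy_correlations(
    species: Iterable[FloralSpecies] | pd.DataFrame,
    dimensions: Sequence[str] = DIMENSIONS,
    rewards: Sequence[str] = REWARDS,
) -> pd.DataFrame:
    """Pearson r between each log(dimension) and each log(reward).

    Species missing a reward are dropped pairwise for that reward only.
    All quantities are natural-log-transformed before correlating; the
    two-sided p-value comes from the exact t reference with n − 2 df.
    Returns a DataFrame indexed by (dimension, reward) with columns r, p, n.
    """
    df = species_frame(species)
    rows = {}
    for reward in rewards:
        col = _REWARD_COLUMNS[reward]
        sub = df[df[col].notna()]
        if (sub[col] <= 0).any():
            bad = sub.loc[sub[col] <= 0, "species_id"].tolist()
            raise InvalidMeasurementError(f"non-positive {reward} for {bad}")
        y = sub[col].to_numpy(dtype=float)
        for dim in dimensions:
            x = sub[dim].to_numpy(dtype=float)
            r, p, n = _pearson_log(x, y)
            rows[(dim, reward)] = {"r": r, "p": p, "n": n}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index = pd.MultiIndex.from_tuples(out.index, names=["dimension", "reward"])
    return out


def ancova_source_test(
    species: Iterable[FloralSpecies] | pd.DataFrame, reward: str
) -> dict[str, float]:
    """Test whether measurement source changes the reward–volume slope.

    Fits OLS ``log(reward) ~ log(volume) + source + log(volume):source`` and
    returns the sequential (interaction-entered-last) F-test of the
    interaction: the extra sum of squares of the interaction over the
    main-effects model, on (levels − 1) and residual df.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = species_frame(species)
    col = _REWARD_COLUMNS[reward]
    sub = df[df[col].notna()].copy()
    levels = sub["source"].unique()
    if len(levels) < 2:
        raise DegenerateInputError(
            "interaction not estimable: only one source level present"
        )
    counts = sub["source"].value_counts()
    if (counts < 2).any():
        thin = counts[counts < 2].index.tolist()
        raise DegenerateInputError(f"source level(s) with < 2 species: {thin}")
    sub["log_reward"] = np.log(sub[col].astype(float))
    sub["log_volume"] = np.log(sub["volume"])
    full = smf.ols("log_reward ~ log_volume * C(source)", data=sub).fit()
    if full.df_resid <= 0 or np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise DegenerateInputError("rank-deficient design: log_volume:C(source)")
    table = anova_lm(full, typ=1)
    inter = table.loc["log_volume:C(source)"]
    return {
        "F": float(inter["F"]),
        "df1": float(inter["df"]),
        "df2": float(table.loc["Residual", "df"]),
        "p": float(inter["PR(>F)"]),
        "n": int(len(sub)),
    }


def validate_proxy(
    species: Iterable[FloralSpecies] | pd.DataFrame,
    dimensions: Sequence[str] = DIMENSIONS,
    rewards: Sequence[str] = REWARDS,
) -> ProxyValidationResult:
    """Full proxy validation: correlations for every dimension × reward plus
    the per-reward source ANCOVA."""
    corr = proxy_correlations(species, dimensions, rewards)
    ancova = {reward: ancova_source_test(species, reward) for reward in rewards}
    return ProxyValidationResult(correlations=corr, ancova=ancova)
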