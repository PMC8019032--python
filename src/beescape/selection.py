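"""Hypothesis families, AICc model selection, and model averaging.

Five hypotheses about what drives local bee visits compete per taxon:

* **H0** — visits unrelated to floral resources (other bees' visits only);
* **H1** — present *local* (within-transect) floral resources;
* **H2** — present *landscape* floral resources at a radius (sign
  distinguishes limitation H2a from dilution H2b post hoc);
* **H3a** — resources at the taxon's foraging onset plus accumulated
  declines since (single-brood taxa only);
* **H3b** — cumulative resources since foraging onset (multi-brood taxa
  only).

Each hypothesis is run full and reduced (dropping AllOtherVisits and/or
TransectFR), at each landscape radius where applicable, and under both
unknown-land imputation variants.  The winning hypothesis minimises the
ΔAICc *summed over the two variants*; coefficients are then averaged
across that hypothesis's models with ΔAICc < 7 using Akaike weights
(full averaging: a term absent from a model contributes zero).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .landscape import PERIODS, RADII_M, VARIANTS
from .zinb import ModelSpec, ZinbFit

__all__ = [
    "HYPOTHESES",
    "BROOD_CLASS",
    "eligible_taxa",
    "enumerate_models",
    "select",
    "model_average",
    "SelectionResult",
]

HYPOTHESES = ("H0", "H1", "H2", "H3a", "H3b")

#: Brood classes of the study genera: single-brood-capable genera are
#: eligible for H3a, multi-brood-capable genera for H3b (Halictus and
#: Lasioglossum contain both life histories, so appear in both).
BROOD_CLASS: dict[str, frozenset[str]] = {
    "Andrena": frozenset({"single"}),
    "Halictus": frozenset({"single", "multi"}),
    "Lasioglossum": frozenset({"single", "multi"}),
    "Megachile": frozenset({"single"}),
    "Peponapis": frozenset({"single"}),
    "Bombus": frozenset({"multi"}),
}

_H2_TERMS = ("present_fr", "transect_fr", "all_other_visits")
_H3A_TERMS = ("first_period_fr", "change_in_fr", "transect_fr", "all_other_visits")
_H3B_TERMS = ("cumulative_fr", "transect_fr", "all_other_visits")


class ConfigError(ValueError):
    """Unknown brood class or hypothesis."""


@dataclass(frozen=True)
class CandidateModel:
    """One candidate: hypothesis, landscape scale (None for H0/H1), fixed
    terms, and the imputation variant it is fitted under."""

    hypothesis: str
    scale: int | None
    terms: tuple[str, ...]
    variant: str

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(
            fixed_terms=self.terms,
            label=f"{self.hypothesis}/{self.scale or '-'}/{self.variant}: "
            + ("1" if not self.terms else "+".join(self.terms)),
        )


def eligible_taxa(
    presence: pd.DataFrame,
    n_sites: int = 27,
    min_sites: int = 4,
    min_periods: int = 2,
    spatially_excluded: Iterable[str] = (),
) -> list[str]:
    """Taxa analysable under the site-presence rule.

    ``presence`` has a ``taxon`` column and one sites-present column per
    period (``T1``..``T4``).  A taxon qualifies when it was present in at
    least ``min_sites`` of the ``n_sites`` sites during at least
    ``min_periods`` distinct periods.  Taxa in ``spatially_excluded``
    (failed the Moran's I screen) are removed afterwards.
    """
    period_cols = [c for c in presence.columns if c in PERIODS]
    out = []
    excluded = set(spatially_excluded)
    for row in presence.itertuples(index=False):
        hits = sum(getattr(row, c) >= min_sites for c in period_cols)
        if hits >= min_periods and row.taxon not in excluded:
            out.append(row.taxon)
    return out


def _reductions(
    core: tuple[str, ...], droppable: tuple[str, ...]
) -> list[tuple[str, ...]]:
    """Core terms plus every subset of the droppable terms removed."""
    out = []
    for r in range(len(droppable) + 1):
        for drop in itertools.combinations(droppable, r):
            out.append(tuple(t for t in core if t not in drop))
    return out


def enumerate_models(
    taxon: str,
    brood_class: frozenset[str] | None = None,
    radii_m: Sequence[int] = RADII_M,
    variants: Sequence[str] = VARIANTS,
    include_change_in_fr: bool | None = None,
) -> list[CandidateModel]:
    """All candidate models for one taxon.

    H0 {full, −AllOtherVisits}; H1 {full, −AllOtherVisits}; H2/H3a/H3b at
    each radius × {full, −AllOtherVisits, −TransectFR, −both}; H3a only
    for single-brood-capable taxa, H3b only for multi-brood-capable taxa.
    For taxa whose resource series never declines (squash bees), H3a drops
    the ChangeInFR term entirely (``include_change_in_fr=False``; default
    is inferred: False only for Peponapis).
    """
    if brood_class is None:
        if taxon not in BROOD_CLASS:
            raise ConfigError(f"no brood class known for taxon {taxon!r}")
        brood_class = BROOD_CLASS[taxon]
    if not brood_class <= {"single", "multi"}:
        raise ConfigError(f"unknown brood class {set(brood_class)!r}")
    if include_change_in_fr is None:
        include_change_in_fr = taxon != "Peponapis"

    models: list[CandidateModel] = []
    for variant in variants:
        models.append(CandidateModel("H0", None, ("all_other_visits",), variant))
        models.append(CandidateModel("H0", None, (), variant))
        for terms in _reductions(
            ("transect_fr", "all_other_visits"), ("all_other_visits",)
        ):
            models.append(CandidateModel("H1", None, terms, variant))
        for scale in radii_m:
            for terms in _reductions(
                _H2_TERMS, ("all_other_visits", "transect_fr")
            ):
                models.append(CandidateModel("H2", int(scale), terms, variant))
            if "single" in brood_class:
                core = (
                    _H3A_TERMS
                    if include_change_in_fr
                    else tuple(t for t in _H3A_TERMS if t != "change_in_fr")
                )
                for terms in _reductions(
                    core, ("all_other_visits", "transect_fr")
                ):
                    models.append(CandidateModel("H3a", int(scale), terms, variant))
            if "multi" in brood_class:
                for terms in _reductions(
                    _H3B_TERMS, ("all_other_visits", "transect_fr")
                ):
                    models.append(CandidateModel("H3b", int(scale), terms, variant))
    return models


@dataclass
class SelectionResult:
    """Summed-ΔAICc ranking across imputation variants.

    ``table`` has one row per (hypothesis, scale) with the best model's
    log-likelihood, AICc and ΔAICc under each variant plus the summed
    total; ``winner`` is the (hypothesis, scale) minimising the total.
    """

    table: pd.DataFrame
    winner: tuple[str, int | None]
    not_evaluable: list[tuple[str, int | None]] = field(default_factory=list)
    averaged: dict[str, pd.DataFrame] = field(default_factory=dict)


def select(
    fits: Mapping[CandidateModel, ZinbFit] | Iterable[tuple[CandidateModel, ZinbFit]],
    variants: Sequence[str] = VARIANTS,
) -> SelectionResult:
    """Rank hypotheses by ΔAICc summed across imputation variants.

    Within each variant the best (lowest-AICc) surviving model per
    (hypothesis, scale) is found and its ΔAICc taken against that
    variant's overall best model; the total across variants ranks the
    hypotheses.  Unconverged fits must already have been excluded.
    (hypothesis, scale) groups missing from any variant are recorded as
    not evaluable.  Ties break toward fewer parameters, then the smaller
    scale.
    """
    items = list(fits.items()) if isinstance(fits, Mapping) else list(fits)
    best: dict[tuple[str, int | None, str], tuple[float, float, int]] = {}
    for cand, fit in items:
        key = (cand.hypothesis, cand.scale, cand.variant)
        cur = best.get(key)
        if cur is None or fit.aicc < cur[1]:
            best[key] = (fit.loglik, fit.aicc, fit.k_params)
    groups = sorted({(h, s) for (h, s, _) in best}, key=lambda t: (t[0], t[1] or 0))
    overall = {
        var: min(
            (v[1] for k, v in best.items() if k[2] == var), default=np.nan
        )
        for var in variants
    }
    rows = []
    not_evaluable = []
    for h, s in groups:
        row: dict[str, object] = {"hypothesis": h, "scale": s}
        total = 0.0
        k_best = None
        ok = True
        for var in variants:
            entry = best.get((h, s, var))
            if entry is None:
                ok = False
                break
            ll, a, k = entry
            row[f"loglik_{var}"] = ll
            row[f"aicc_{var}"] = a
            row[f"delta_aicc_{var}"] = a - overall[var]
            total += a - overall[var]
            k_best = k if k_best is None else min(k_best, k)
        if not ok:
            not_evaluable.append((h, s))
            continue
        row["total_delta_aicc"] = total
        row["k_params"] = k_best
        rows.append(row)
    if not rows:
        raise ValueError("no (hypothesis, scale) evaluable in every variant")
    table = pd.DataFrame(rows)
    table["_scale_order"] = pd.to_numeric(table["scale"], errors="coerce").fillna(-1.0)
    table = (
        table.sort_values(["total_delta_aicc", "k_params", "_scale_order"])
        .drop(columns="_scale_order")
        .reset_index(drop=True)
    )
    top = table.iloc[0]
    winner = (str(top["hypothesis"]), None if pd.isna(top["scale"]) else int(top["scale"]))
    return SelectionResult(table=table, winner=winner, not_evaluable=not_evaluable)


def model_average(
    fits: Mapping[CandidateModel, ZinbFit] | Iterable[tuple[CandidateModel, ZinbFit]],
    hypothesis: str,
    variant: str,
    threshold: float = 7.0,
    conditional: bool = False,
) -> pd.DataFrame:
    """Akaike-weight average of coefficients across one hypothesis's models.

    Retains the given hypothesis's models under ``variant`` with ΔAICc
    (within the retained candidate set) below ``threshold``; weights are
    proportional to exp(−Δ/2).  Full averaging (default) lets a term
    absent from a model contribute an estimate of 0 to the average, and
    unconditional SEs combine within-model variance and between-model
    spread; ``conditional=True`` instead averages only over the models
    containing each term.  Returns a coefficient table with averaged
    estimates and Wald 95% CIs.
    """
    items = list(fits.items()) if isinstance(fits, Mapping) else list(fits)
    pool = [
        (c, f)
        for c, f in items
        if c.hypothesis == hypothesis and c.variant == variant
    ]
    if not pool:
        raise ValueError(f"no fits for {hypothesis} under variant {variant!r}")
    aiccs = np.array([f.aicc for _, f in pool])
    delta = aiccs - aiccs.min()
    keep = delta < threshold
    if not keep.any():
        raise ValueError("empty retained set under the ΔAICc threshold")
    pool = [p for p, k in zip(pool, keep) if k]
    delta = delta[keep]
    w = np.exp(-delta / 2.0)
    w /= w.sum()

    terms: list[str] = []
    for _, f in pool:
        for t in f.term_names:
            if t not in terms:
                terms.append(t)
    rows = []
    for t in terms:
        est = np.zeros(len(pool))
        var_w = np.zeros(len(pool))
        has = np.zeros(len(pool), dtype=bool)
        for m, (_, f) in enumerate(pool):
            if t in f.term_names:
                j = f.term_names.index(t)
                est[m] = f.beta[j]
                var_w[m] = f.se[j] ** 2
                has[m] = True
        if conditional:
            wm = w[has] / w[has].sum()
            bbar = float(wm @ est[has])
            se = float(wm @ np.sqrt(var_w[has] + (est[has] - bbar) ** 2))
        else:
            bbar = float(w @ est)  # absent terms contribute 0
            se = float(w @ np.sqrt(var_w + (est - bbar) ** 2))
        rows.append(
            {
                "term": t,
                "estimate": bbar,
                "se": se,
                "ci_2.5": bbar - 1.959963984540054 * se,
                "ci_97.5": bbar + 1.959963984540054 * se,
                "weight_sum": float(w[has].sum()),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["weights"] = w
    out.attrs["n_models"] = len(pool)
    return out
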