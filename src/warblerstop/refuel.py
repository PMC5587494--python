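"""Two-tier AICc analysis of refueling-index variation.

Tier 1 screens four methodological covariates known to disturb plasma
metabolite levels — handling time before blood sampling (ln-transformed
Bleedtime), time of day, day of season, and year — over all subsets plus a
null model. The terms of the single lowest-AICc tier-1 model are then
carried into every non-null tier-2 model, where the biological terms
(breeding destination, timing class, migratory condition, age, sex) and
their meaningful two-way interactions compete. Both tiers are ranked by
AICc; estimates are model-averaged with unconditional SEs and each term's
relative importance w+(j) is reported, together with predicted group means
by destination x timing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metabolites import (
    MetaboliteCorrelation,
    RefuelingIndex,
    metabolite_correlation,
    refueling_index,
    transform_metabolites,
)
from .modelselect import (
    AveragedEstimate,
    ModelSpec,
    SelectionTable,
    build_design,
    enumerate_candidate_models,
    fit_linear_model,
    model_average,
)

__all__ = [
    "TIER1_TERMS",
    "TIER2_MAINS",
    "TIER2_INTERACTIONS",
    "RefuelingAnalysis",
    "prepare_refueling_data",
    "two_tier_refueling_analysis",
]

TIER1_TERMS = ("ln_bleedtime", "daytime", "season", "year_f")
TIER2_MAINS = ("destination", "timing", "condition", "age", "sex")
TIER2_INTERACTIONS = (
    ("destination", "timing"),
    ("destination", "age"),
    ("destination", "sex"),
    ("timing", "age"),
    ("timing", "sex"),
)


@dataclass
class RefuelingAnalysis:
    index: RefuelingIndex
    correlation: MetaboliteCorrelation
    data: pd.DataFrame
    tier1: SelectionTable
    tier2: SelectionTable
    carried_terms: tuple[str, ...]
    n_candidates: tuple[int, int]
    averaged: dict[str, dict[str, AveragedEstimate]]
    importance: dict[str, float]
    group_means: pd.DataFrame


def prepare_refueling_data(
    plasma: pd.DataFrame, birds: pd.DataFrame
) -> tuple[pd.DataFrame, RefuelingIndex, MetaboliteCorrelation]:
    """Compute the refueling index and join it to the bird covariates.

    The index (and the metabolite correlation) is computed from *all*
    plasma rows, including birds without an assigned destination; the
    modeling table is the inner join with birds that carry destination,
    timing, condition, age and sex.
    """
    plasma_t = transform_metabolites(plasma)
    corr = metabolite_correlation(plasma_t["ln_trig"], plasma_t["ln_bohb"])
    idx = refueling_index(plasma_t["ln_trig"], plasma_t["ln_bohb"])
    plasma_t = plasma_t.assign(refuel_index=idx.scores)
    keep = ["bird_id", "destination", "timing", "condition", "age", "sex"]
    missing = [c for c in keep if c not in birds.columns]
    if missing:
        raise ValueError(f"bird table missing columns: {missing}")
    joined = plasma_t.merge(birds[keep], on="bird_id", how="inner")
    joined = joined[joined["destination"].isin(("southeast", "boreal"))]
    joined = joined.dropna(subset=["timing", "condition"])
    if joined.empty:
        raise ValueError("empty join between plasma and bird tables")
    joined["year_f"] = joined["year"].astype(int).astype(str)
    joined["season"] = joined["day_of_year"].astype(float)
    return joined.reset_index(drop=True), idx, corr


def two_tier_refueling_analysis(
    plasma: pd.DataFrame,
    birds: pd.DataFrame,
    delta_threshold: float = 4.0,
    tier1_terms: tuple[str, ...] = TIER1_TERMS,
    tier2_mains: tuple[str, ...] = TIER2_MAINS,
    interactions: tuple[tuple[str, str], ...] = TIER2_INTERACTIONS,
) -> RefuelingAnalysis:
    """Run the full two-tier refueling model selection."""
    data, idx, corr = prepare_refueling_data(plasma, birds)

    tier1_specs = enumerate_candidate_models(tier1_terms)
    tier1 = SelectionTable(
        [fit_linear_model(data, "refuel_index", s) for s in tier1_specs]
    )
    carried = tier1.best.spec.mains  # terms of the single lowest-AICc model

    tier2_specs = enumerate_candidate_models(
        tier2_mains, interactions, always_include=carried
    )
    tier2 = SelectionTable(
        [fit_linear_model(data, "refuel_index", s) for s in tier2_specs]
    )

    top = tier2.top_set(delta_threshold)
    top_terms: list[str] = []
    for i in top:
        for t in tier2.fits[i].spec.terms:
            if t not in top_terms:
                top_terms.append(t)
    averaged = {t: model_average(tier2, t, subset=top) for t in top_terms}
    importance = {
        t: next(iter(averaged[t].values())).w_plus for t in top_terms
    }
    group_means = _predicted_group_means(tier2, data, top)

    return RefuelingAnalysis(
        index=idx,
        correlation=corr,
        data=data,
        tier1=tier1,
        tier2=tier2,
        carried_terms=carried,
        n_candidates=(len(tier1_specs), len(tier2_specs)),
        averaged=averaged,
        importance=importance,
        group_means=group_means,
    )


def _predicted_group_means(
    table: SelectionTable, data: pd.DataFrame, top: list[int]
) -> pd.DataFrame:
    """Model-averaged predicted refueling index per destination x timing.

    Population-averaged: each model predicts for every bird in the cell
    (continuous covariates at their observed values) and the cell mean is
    averaged over the top set with renormalized weights; the SE combines
    within-model prediction SEs and between-model spread (unconditional
    formula).
    """
    w = np.array([table.weights[i] for i in top], dtype=float)
    w = w / w.sum()
    # full-data designs so every factor level is represented in every cell
    designs = {i: build_design(data, table.fits[i].spec) for i in top}
    rows = []
    for (dest, timing), cell in data.groupby(["destination", "timing"]):
        mus, ses = [], []
        for i in top:
            fit = table.fits[i]
            X = designs[i].loc[cell.index]
            xbar = X.to_numpy().mean(axis=0)
            mu, se = fit.predict(pd.Series(xbar, index=X.columns))
            mus.append(mu)
            ses.append(se)
        mus_arr, ses_arr = np.asarray(mus), np.asarray(ses)
        mbar = float(np.sum(w * mus_arr))
        use = float(np.sum(w * np.sqrt(ses_arr**2 + (mus_arr - mbar) ** 2)))
        rows.append(
            {
                "destination": dest,
                "timing": timing,
                "n": len(cell),
                "predicted_index": mbar,
                "se": use,
            }
        )
    out = pd.DataFrame(rows)
    timing_order = {"early": 0, "middle": 1, "late": 2}
    out["_t"] = out["timing"].map(timing_order)
    out = out.sort_values(["destination", "_t"]).drop(columns="_t")
    return out.reset_index(drop=True)
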