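"""Cross-plant comparison of species sets, cohorts and aggregate dynamics.

Plants are compared on three levels: which retained species they share
(set-membership / upset-style intersection tables), whether shared
species fall in the same or neighbouring seasonal cohorts, and how
aggregate quantities (cumulative abundance of growth groups, alpha
diversity) cycle through the year.

Cohort agreement across plants is classified as *identical* (one
distinct seasonal cohort), *concomitant* (exactly two distinct cohorts
that are cyclically adjacent: winter-spring, spring-summer,
summer-autumn, autumn-winter), *mixed* (anything else, including
opposite seasons), or *all-non-significant*.  Non-significant labels are
ignored for the adjacency test but recorded in the intersection key.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

from seasonflow.decomposition import WeeklySeries, regularize_weekly
from seasonflow.seasonal import COHORTS, HarmonicFit, SeasonalResult, fit_harmonic
from seasonflow.tables import SampleTable
from seasonflow.transforms import rarefy, richness, simpson_1_minus_d

__all__ = [
    "agreement_class",
    "shared_species",
    "cohort_intersections",
    "group_series",
    "diversity_series",
]

_ADJACENT = {
    frozenset(("winter", "spring")),
    frozenset(("spring", "summer")),
    frozenset(("summer", "autumn")),
    frozenset(("autumn", "winter")),
}


def agreement_class(labels) -> str:
    """Agreement of one species' cohort labels across plants."""
    seasonal = [l for l in labels if l in COHORTS]
    if not seasonal:
        return "all-non-significant"
    distinct = set(seasonal)
    if len(distinct) == 1:
        return "identical"
    if len(distinct) == 2 and frozenset(distinct) in _ADJACENT:
        return "concomitant"
    return "mixed"


def shared_species(retained: Mapping[str, set]) -> pd.DataFrame:
    """Per-species presence across plants.

    ``retained`` maps plant id to its set of retained species.  Returns
    a boolean species x plants membership frame plus an ``n_plants``
    column; intersection-cell counts are ``membership.value_counts()``
    over the plant columns.
    """
    if len(retained) < 2:
        raise ValueError("need at least two plants to intersect")
    plants = sorted(retained)
    all_species = sorted(set().union(*retained.values()))
    data = {p: [sp in retained[p] for sp in all_species] for p in plants}
    member = pd.DataFrame(data, index=pd.Index(all_species, name="species"))
    member["n_plants"] = member[plants].sum(axis=1)
    return member


def cohort_intersections(
    results: Mapping[str, Mapping[str, SeasonalResult]],
    species: list[str] | None = None,
) -> pd.DataFrame:
    """Cohort labels across plants for shared species, with agreement class.

    ``results`` maps plant -> species -> SeasonalResult.  ``species``
    defaults to those present in every plant's results.  The
    ``intersection`` key is the sorted multiset of distinct labels
    (including "non-significant"); ``strength`` summarises each species
    by its strongest per-plant category.
    """
    plants = sorted(results)
    if species is None:
        species = sorted(
            set.intersection(*(set(results[p]) for p in plants))
        )
    rows = []
    strength_rank = ["very strong", "strong", "moderate", "weak", "very weak",
                     "non-significant"]
    for sp in species:
        labels = {p: results[p][sp].cohort for p in plants}
        strengths = [results[p][sp].strength for p in plants]
        best = min(strengths, key=strength_rank.index)
        key = "+".join(sorted(set(labels.values())))
        rows.append(
            {"species": sp, **labels, "intersection": key,
             "agreement": agreement_class(labels.values()), "strength": best}
        )
    return pd.DataFrame(rows).set_index("species")


def intersection_summary(intersections: pd.DataFrame) -> pd.DataFrame:
    """Counts per intersection cell with a strength breakdown."""
    out = (
        intersections.groupby(["intersection", "agreement", "strength"])
        .size()
        .rename("n_species")
        .reset_index()
    )
    return out.sort_values("n_species", ascending=False).reset_index(drop=True)


def group_series(
    t: SampleTable,
    assignment: Mapping[str, str],
    alpha: float = 0.01,
) -> dict[str, dict]:
    """Cumulative relative-abundance series per label, with harmonic fits.

    ``assignment`` maps species id to a label (e.g. growth group or
    cohort).  Per label the per-sample relative abundances are summed,
    regularised to a weekly grid and fitted to the annual harmonic.  The
    fit is reported only when significant (p <= alpha); the fitted
    object is kept under ``"fit_all"`` regardless for diagnostics.
    """
    rel = t.relative()
    labels = sorted(set(assignment.values()))
    dates = t.meta["date"]
    out: dict[str, dict] = {}
    for label in labels:
        members = [s for s, l in assignment.items() if l == label and s in rel.columns]
        series = rel[members].sum(axis=1)
        # average duplicate dates (unmerged replicates) before gridding
        by_date = series.groupby(dates).mean()
        ws = regularize_weekly(by_date.to_numpy(), by_date.index)
        fit = fit_harmonic(ws)
        out[label] = {
            "series": ws,
            "fit": fit if fit.p_value <= alpha else None,
            "fit_all": fit,
            "n_species": len(members),
        }
    return out


def diversity_series(
    t: SampleTable,
    depth: int = 10_000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.01,
) -> dict[str, dict]:
    """Rarefied alpha-diversity (richness, Simpson 1-D) with harmonic fits.

    Counts are rarefied to ``depth`` reads per sample (samples below the
    depth must have been filtered), diversity is computed per sample,
    duplicate dates are averaged, and each metric is regularised to a
    weekly grid and fitted to the annual harmonic.  Deterministic given
    ``seed``.
    """
    if t.is_proportions:
        raise ValueError("diversity needs integer counts (run before merging)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = t.counts.to_numpy()
    rare = rarefy(counts, depth=depth, seed=rng)
    metrics = {
        "richness": richness(rare).astype(float),
        "simpson_1_minus_d": np.asarray(simpson_1_minus_d(rare), float),
    }
    dates = t.meta["date"]
    out: dict[str, dict] = {}
    for name, vals in metrics.items():
        by_date = pd.Series(vals, index=t.sample_ids).groupby(dates).mean()
        ws = regularize_weekly(by_date.to_numpy(), by_date.index)
        fit = fit_harmonic(ws)
        out[name] = {
            "series": ws,
            "fit": fit if fit.p_value <= alpha else None,
            "fit_all": fit,
        }
    return out
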