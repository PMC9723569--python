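"""Growth-group classification from an immigration mass balance.

Activated-sludge reactors receive a continuous inoculum of bacteria with
the influent wastewater.  At steady state, a species' biomass X in the
reactor obeys

    V dX/dt = Q * C_in + k * V * X - (V / SRT) * X = 0,

where C_in is the species' biomass concentration in the influent
(relative abundance x total cells/L), X its concentration in the
reactor, Q the influent flow, V the reactor volume, SRT the solids
retention time (the wasting rate is 1/SRT) and k the apparent
first-order net growth rate.  With HRT = V/Q this inverts to the closed
form

    k = 1/SRT - C_in / (X * HRT)      [per day].

This simplified steady-state estimator labels species as growing
(k > 0 in every plant), disappearing (k < 0 everywhere: present only
through immigration), surviving (|k| <= epsilon everywhere), or
ambiguous (inconsistent signs across plants, or maximum relative read
abundance below 0.05%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GrowthEstimate",
    "estimate_net_growth",
    "classify_growth",
    "classify_growth_table",
]

GROWTH_GROUPS = ("growing", "disappearing", "surviving", "ambiguous")


@dataclass(frozen=True)
class GrowthEstimate:
    """Per-species apparent net growth rate (simplified steady-state)."""

    species_id: str
    k: float                      # median across plants, per day
    per_plant_k: dict = field(default_factory=dict)
    group: str = "ambiguous"


def estimate_net_growth(
    influent_abundance,
    influent_total_cells,
    reactor_abundance,
    reactor_total_cells,
    srt_days,
    hrt_days,
):
    """Apparent net growth rate k = 1/SRT - C_in/(X * HRT), per day.

    ``influent_abundance`` and ``reactor_abundance`` are relative
    abundances; the total cell concentrations convert them to biomass
    concentrations.  Vectorised over species/dates.  Species absent from
    the reactor (X = 0) yield NaN — the balance is undefined for them.
    """
    srt = np.asarray(srt_days, float)
    hrt = np.asarray(hrt_days, float)
    if np.any(srt <= 0) or np.any(hrt <= 0):
        raise ValueError("SRT and HRT must be positive")
    c_in = np.asarray(influent_abundance, float) * np.asarray(influent_total_cells, float)
    x = np.asarray(reactor_abundance, float) * np.asarray(reactor_total_cells, float)
    if np.any(c_in < 0) or np.any(x < 0):
        raise ValueError("abundances and cell totals must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        k = 1.0 / srt - c_in / (x * hrt)
    k = np.where(np.asarray(x) > 0, k, np.nan)
    return float(k) if np.ndim(k) == 0 else k


def classify_growth(
    per_plant_k: dict,
    max_abundance: float,
    epsilon: float = 0.005,
    min_abundance: float = 0.0005,
) -> str:
    """Sign-consistency rule for the growth group of one species.

    Requires agreement across all plants: growing if every per-plant k
    exceeds +epsilon, disappearing if every k is below -epsilon,
    surviving if every |k| <= epsilon; anything inconsistent — or any
    species whose maximum relative read abundance is below 0.05% — is
    ambiguous.
    """
    ks = np.asarray([v for v in per_plant_k.values()], float)
    ks = ks[np.isfinite(ks)]
    if ks.size == 0:
        return "ambiguous"
    if max_abundance < min_abundance:
        return "ambiguous"
    if np.all(ks > epsilon):
        return "growing"
    if np.all(ks < -epsilon):
        return "disappearing"
    if np.all(np.abs(ks) <= epsilon):
        return "surviving"
    return "ambiguous"


def classify_growth_table(
    k_table: pd.DataFrame,
    max_abundance: pd.Series,
    epsilon: float = 0.005,
    min_abundance: float = 0.0005,
) -> list[GrowthEstimate]:
    """Classify every species from a per-date, per-plant k table.

    ``k_table`` is long-format with columns ``species``, ``plant``,
    ``k``; per-species, per-plant values are aggregated by median across
    sampling dates before the sign rules (robust to outlier pairs).
    ``max_abundance`` maps species id to its maximum relative read
    abundance in the reactor.
    """
    out: list[GrowthEstimate] = []
    med = k_table.groupby(["species", "plant"])["k"].median()
    for sp, grp in med.groupby(level="species"):
        per_plant = {plant: float(v) for (_, plant), v in grp.items()}
        ks = np.asarray(list(per_plant.values()), float)
        ks = ks[np.isfinite(ks)]
        k_med = float(np.median(ks)) if ks.size else float("nan")
        ab = float(max_abundance.get(sp, 0.0))
        group = classify_growth(per_plant, ab, epsilon=epsilon,
                                min_abundance=min_abundance)
        out.append(GrowthEstimate(species_id=str(sp), k=k_med,
                                  per_plant_k=per_plant, group=group))
    return out
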