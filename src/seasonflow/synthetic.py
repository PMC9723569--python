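"""Synthetic longitudinal communities with known ground truth.

Stands in for a multi-plant, multi-year amplicon survey of activated
sludge.  Each species has a latent log-abundance trajectory

    lambda_i(t) = baseline_i + trend_i * t/365.25
                  + A_i * cos(2*pi*(t - tau_i)/365.25) + N(0, sigma_i^2),

an annual sinusoid of amplitude A_i peaking on day-of-year tau_i, plus
drift and Gaussian noise.  Reads are drawn multinomially with
probabilities proportional to exp(lambda_i(t)) at a per-sample depth
drawn uniformly from the plant's depth range, so rclr of the latent
signal is approximately sinusoidal — matching the analysis assumptions.
A configurable fraction of sampling points is emitted twice as
replicates and a fraction receives sub-threshold depth, to exercise QC.

Paired influent/reactor tables are generated so the steady-state
immigration mass balance holds exactly for each species' prescribed net
growth rate k_i, optionally perturbed by multiplicative lognormal noise.

Same seed implies byte-identical output everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from seasonflow.seasonal import season_of_day
from seasonflow.tables import RANKS, SampleTable, TaxonomyTable

__all__ = [
    "SpeciesSpec",
    "PlantSpec",
    "make_species_specs",
    "simulate_plant",
    "simulate_influent_pairs",
    "ground_truth_frame",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class SpeciesSpec:
    """Ground truth for one synthetic species.

    ``true_cohort`` is derived from ``peak_day`` through the same season
    windows the analysis uses (:func:`seasonflow.seasonal.season_of_day`),
    and is ``"none"`` exactly when the amplitude is zero.
    """

    species_id: str
    baseline_log_abundance: float
    amplitude: float
    peak_day: int
    trend_slope: float = 0.0
    noise_sd: float = 0.3
    true_growth_rate: float = 0.0
    true_cohort: str = field(init=False)

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 1 <= self.peak_day <= 365:
            raise ValueError("peak_day must be in [1, 365]")
        cohort = "none" if self.amplitude == 0 else season_of_day(self.peak_day)
        object.__setattr__(self, "true_cohort", cohort)


@dataclass(frozen=True)
class PlantSpec:
    """Sampling design and operation of one synthetic plant."""

    plant_id: str
    n_species: int = 200
    years: int = 3
    sampling_interval_days: int = 7
    depth_range: tuple[int, int] = (10_893, 170_639)
    srt_days: float = 20.0
    hrt_days: float = 1.0
    seed: int = 0
    start_date: str = "2015-01-01"
    replicate_fraction: float = 0.05
    low_depth_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.n_species <= 0 or self.years < 1:
            raise ValueError("n_species and years must be positive")
        if not 7 <= self.sampling_interval_days <= 10:
            raise ValueError("sampling_interval_days must be in [7, 10]")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("invalid depth_range")
        if self.srt_days <= 0 or self.hrt_days <= 0:
            raise ValueError("SRT and HRT must be positive")


def make_species_specs(
    n: int,
    seed: int = 0,
    seasonal_fraction: float = 0.8,
    amplitude_range: tuple[float, float] = (0.5, 2.5),
    noise_sd_range: tuple[float, float] = (0.2, 0.6),
    baseline_sd: float = 1.5,
    prefix: str = "midas_s",
    id_offset: int = 1,
) -> list[SpeciesSpec]:
    """Draw a random community specification.

    ``seasonal_fraction`` of the species get an annual sinusoid with
    amplitude uniform in ``amplitude_range`` and a peak day uniform over
    the year; the rest have amplitude 0 (no seasonal signal).  Baseline
    log-abundances are N(0, baseline_sd^2), giving realistic spread over
    orders of magnitude.  Growth rates come from a growing /
    disappearing / surviving mixture compatible with SRT = 20 d
    (all k < 1/SRT so the mass balance never degenerates).
    """
    rng = np.random.default_rng(seed)
    specs = []
    for j in range(n):
        seasonal = rng.random() < seasonal_fraction
        amp = float(rng.uniform(*amplitude_range)) if seasonal else 0.0
        peak = int(rng.integers(1, 366))
        u = rng.random()
        if u < 0.45:
            k = float(rng.uniform(0.01, 0.045))     # growing
        elif u < 0.80:
            k = float(rng.uniform(-0.30, -0.02))    # disappearing
        else:
            k = float(rng.uniform(-0.004, 0.004))   # surviving
        specs.append(
            SpeciesSpec(
                species_id=f"{prefix}_{id_offset + j}",
                baseline_log_abundance=float(rng.normal(0.0, baseline_sd)),
                amplitude=amp,
                peak_day=peak,
                trend_slope=0.0,
                noise_sd=float(rng.uniform(*noise_sd_range)),
                true_growth_rate=k,
            )
        )
    return specs


def latent_log_abundance(
    spec: SpeciesSpec, t_days: np.ndarray, start_doy: float = 1.0
) -> np.ndarray:
    """Noise-free latent log-abundance at ``t_days`` since series start."""
    t = np.asarray(t_days, float)
    doy = start_doy + t
    return (
        spec.baseline_log_abundance
        + spec.trend_slope * t / DAYS_PER_YEAR
        + spec.amplitude * np.cos(2.0 * np.pi * (doy - spec.peak_day) / DAYS_PER_YEAR)
    )


def _make_taxonomy(
    specs: list[SpeciesSpec], rng: np.random.Generator,
    unclassified_fraction: float = 0.1, n_protected: int = 0,
) -> TaxonomyTable:
    rows = {}
    for j, sp in enumerate(specs):
        asv = f"ASV{j + 1}"
        lineage = {
            "Kingdom": "Bacteria",
            "Phylum": f"phylum_{j % 17}",
            "Class": f"class_{j % 29}",
            "Order": f"order_{j % 41}",
            "Family": f"family_{j % 61}",
            "Genus": f"midas_g_{j % 97}",
            "Species": sp.species_id,
        }
        # shared (protected) species keep their label so cross-plant
        # identity survives species aggregation
        if j >= n_protected and rng.random() < unclassified_fraction:
            lineage["Species"] = ""       # classified only to genus
        rows[asv] = lineage
    ranks = pd.DataFrame.from_dict(rows, orient="index")[RANKS]
    ranks.index.name = "taxon_id"
    return TaxonomyTable(ranks)


def simulate_plant(
    spec: PlantSpec,
    shared_species: list[SpeciesSpec] | None = None,
) -> tuple[SampleTable, pd.DataFrame, TaxonomyTable, list[SpeciesSpec]]:
    """Simulate one plant's longitudinal count table.

    ``shared_species`` (same objects across plants, identical peak days)
    form a cross-plant core; the remaining ``n_species - len(shared)``
    species are drawn fresh with a plant-specific seed.  Returns the
    sample table (counts + metadata), the metadata frame, the taxonomy,
    and the full list of species specs in column order of the taxonomy.
    """
    shared = list(shared_species or [])
    if len(shared) > spec.n_species:
        raise ValueError("more shared species than n_species")
    rng = np.random.default_rng(spec.seed)
    own = make_species_specs(
        spec.n_species - len(shared),
        seed=spec.seed + 1,
        prefix=f"{spec.plant_id}_s",
    )
    specs = shared + own

    start = pd.Timestamp(spec.start_date)
    horizon = int(round(spec.years * DAYS_PER_YEAR))
    t_days = np.arange(0, horizon, spec.sampling_interval_days, dtype=float)
    start_doy = float(start.dayofyear)

    lam0 = np.stack([latent_log_abundance(s, t_days, start_doy) for s in specs], axis=1)
    sigmas = np.array([s.noise_sd for s in specs])
    lam = lam0 + rng.normal(0.0, 1.0, size=lam0.shape) * sigmas[None, :]

    n_dates = t_days.size
    replicate = rng.random(n_dates) < spec.replicate_fraction
    low_depth = rng.random(n_dates) < spec.low_depth_fraction

    rows, sample_ids, meta_rows = [], [], []
    for i, t in enumerate(t_days):
        date = start + pd.Timedelta(days=int(t))
        if low_depth[i]:
            depth = int(rng.integers(1_000, 10_000))
        else:
            depth = int(rng.integers(spec.depth_range[0], spec.depth_range[1] + 1))
        p = np.exp(lam[i] - lam[i].max())
        p /= p.sum()
        sid = f"{spec.plant_id}_S{i + 1:04d}"
        rows.append(rng.multinomial(depth, p))
        sample_ids.append(sid)
        meta_rows.append((spec.plant_id, date, np.nan))
        if replicate[i]:
            depth2 = int(rng.integers(spec.depth_range[0], spec.depth_range[1] + 1))
            rows.append(rng.multinomial(depth2, p))
            sample_ids.append(f"{sid}r")
            meta_rows.append((spec.plant_id, date, sid))

    taxonomy = _make_taxonomy(specs, rng, n_protected=len(shared))
    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=taxonomy.ranks.index,
    )
    meta = pd.DataFrame(
        meta_rows, index=counts.index, columns=["plant", "date", "replicate_of"]
    )
    table = SampleTable(counts=counts, meta=meta)
    return table, meta, taxonomy, specs


def simulate_influent_pairs(
    specs: list[SpeciesSpec],
    plant: PlantSpec,
    n_dates: int = 26,
    seed: int = 0,
    influent_mean_abundance: float = 1e-3,
    influent_log_sd: float = 0.3,
    noise_sd: float = 0.2,
    influent_total_cells: float = 1e10,
    reactor_total_cells: float = 1e12,
) -> dict:
    """Paired influent/reactor relative-abundance tables.

    Influent abundances are lognormal around ``influent_mean_abundance``;
    reactor abundances are set so the steady-state balance
    ``k = 1/SRT - C_in/(X*HRT)`` holds exactly for each species' true k,
    then perturbed by multiplicative lognormal noise of standard
    deviation ``noise_sd`` on the log scale (``noise_sd = 0`` gives the
    exact fixed point).  Species with ``k >= 1/SRT`` are rejected: they
    need no immigration and the balance degenerates.
    """
    rng = np.random.default_rng(seed)
    k = np.array([s.true_growth_rate for s in specs])
    ratio = plant.hrt_days * (1.0 / plant.srt_days - k)  # C_in / X
    bad = ratio <= 0
    if np.any(bad):
        names = [specs[i].species_id for i in np.where(bad)[0][:5]]
        raise ValueError(
            "species with k >= 1/SRT need no immigration and the steady-state "
            f"balance degenerates: {names}"
        )
    n_sp = len(specs)
    infl = influent_mean_abundance * rng.lognormal(
        0.0, influent_log_sd, size=(n_dates, n_sp)
    )
    c_in = infl * influent_total_cells
    x = c_in / ratio[None, :]
    reac = x / reactor_total_cells
    if noise_sd > 0:
        reac = reac * rng.lognormal(0.0, noise_sd, size=reac.shape)
    ids = [s.species_id for s in specs]
    dates = pd.date_range(plant.start_date, periods=n_dates, freq="14D")
    return {
        "influent": pd.DataFrame(infl, index=dates, columns=ids),
        "reactor": pd.DataFrame(reac, index=dates, columns=ids),
        "true_k": pd.Series(k, index=ids),
        "influent_total_cells": influent_total_cells,
        "reactor_total_cells": reactor_total_cells,
        "srt_days": plant.srt_days,
        "hrt_days": plant.hrt_days,
    }


def analysis_keys(
    specs: list[SpeciesSpec], taxonomy: TaxonomyTable
) -> list[str]:
    """Column keys the species-aggregated table will use, aligned to specs.

    An ASV whose species label was blanked (classified only to genus)
    keeps its ASV id as the species-level key downstream.
    """
    keys = []
    for j, sp in enumerate(specs):
        asv = f"ASV{j + 1}"
        label = taxonomy.species_label(asv)
        keys.append(label if label is not None else asv)
    return keys


def ground_truth_frame(
    specs: list[SpeciesSpec], taxonomy: TaxonomyTable | None = None
) -> pd.DataFrame:
    """Tabulate ground truth (amplitude, peak day, cohort, k) per species.

    With a taxonomy, rows are keyed by the species-aggregated column
    names the analysis will produce (see :func:`analysis_keys`).
    """
    ids = (
        analysis_keys(specs, taxonomy)
        if taxonomy is not None
        else [s.species_id for s in specs]
    )
    return pd.DataFrame(
        {
            "species_id": ids,
            "baseline": [s.baseline_log_abundance for s in specs],
            "amplitude": [s.amplitude for s in specs],
            "peak_day": [s.peak_day for s in specs],
            "noise_sd": [s.noise_sd for s in specs],
            "true_cohort": [s.true_cohort for s in specs],
            "true_k": [s.true_growth_rate for s in specs],
        }
    ).set_index("species_id")
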