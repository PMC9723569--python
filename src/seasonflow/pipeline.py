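"""End-to-end orchestration: simulate/load -> QC -> transform -> decompose
-> seasonality -> growth -> cross-plant, with a machine-readable manifest.

The stage order keeps count-based operations valid: the read-depth filter
and rarefaction-based diversity run on raw counts, replicates are then
merged on the relative-abundance scale, and everything downstream
(species aggregation, retention filter, rclr, decomposition, harmonic
inference) operates on the merged proportion table.  All randomness is
driven by per-stage seeds derived from one master seed, so a rerun with
the same config reproduces every table.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from seasonflow import __version__ as _pkg_version
from seasonflow.cross_plant import (
    cohort_intersections,
    group_series,
    intersection_summary,
    shared_species,
)
from seasonflow.decomposition import WeeklySeries, regularize_weekly, stl_periodic
from seasonflow.growth import classify_growth_table, estimate_net_growth
from seasonflow.seasonal import (
    SeasonalResult,
    assign_cohort,
    fit_harmonic,
    peak_confidence_interval,
    seasonal_strength,
    strength_category,
)
from seasonflow.tables import (
    SampleTable,
    TaxonomyTable,
    aggregate_to_species,
    filter_min_reads,
    merge_replicates,
    retain_abundant_species,
)
from seasonflow.transforms import rclr
from seasonflow.synthetic import (
    PlantSpec,
    analysis_keys,
    ground_truth_frame,
    make_species_specs,
    simulate_influent_pairs,
    simulate_plant,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "analyze_plant", "seasonality_table"]


@dataclass
class RunConfig:
    """All analysis thresholds and simulation settings in one place.

    The thresholds mirror the standard workflow: 10 000-read sample
    filter, 0.05% maximum-abundance species retention, 1% significance
    for the harmonic fit, 52-week annual frequency, Fs strength cut
    points (0.75/0.55/0.35/0.15), |k| <= 0.005 1/d for "surviving", and
    rarefaction at 10 000 reads for alpha diversity.
    """

    min_reads: int = 10_000
    abundance_threshold: float = 0.0005
    alpha: float = 0.01
    frequency: int = 52
    fs_cutpoints: tuple[float, float, float, float] = (0.75, 0.55, 0.35, 0.15)
    epsilon_k: float = 0.005
    rarefaction_depth: int = 10_000
    n_boot: int = 1000
    seed: int = 0
    rclr_zero: str = "zero"          # {"zero", "interpolate"}
    fit_on: str = "seasonal"         # {"seasonal", "raw"}
    # simulation settings (used when no input tables are supplied)
    n_plants: int = 4
    n_species: int = 200
    n_shared: int = 100
    years: int = 3
    sampling_interval_days: int = 7
    growth_n_dates: int = 26
    growth_noise_sd: float = 0.2
    outdir: str | None = None

    def __post_init__(self) -> None:
        cuts = tuple(self.fs_cutpoints)
        if list(cuts) != sorted(cuts, reverse=True) or not all(
            0 < c < 1 for c in cuts
        ):
            raise ValueError("fs_cutpoints must be strictly decreasing in (0, 1)")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.rclr_zero not in ("zero", "interpolate"):
            raise ValueError("rclr_zero must be 'zero' or 'interpolate'")
        if self.fit_on not in ("seasonal", "raw"):
            raise ValueError("fit_on must be 'seasonal' or 'raw'")


def _species_weekly_series(
    values: np.ndarray, dates: pd.DatetimeIndex, mode: str
) -> WeeklySeries:
    """Regularise one species' rclr series, handling rclr missingness.

    ``mode="zero"`` places absent taxa at 0 on the rclr scale (the
    sample's geometric mean) before interpolation; ``"interpolate"``
    drops missing observations and interpolates across them.
    """
    vals = np.asarray(values, float)
    if mode == "zero":
        vals = np.where(np.isnan(vals), 0.0, vals)
        return regularize_weekly(vals, dates)
    ok = ~np.isnan(vals)
    if ok.sum() < 2:
        vals = np.where(np.isnan(vals), 0.0, vals)
        return regularize_weekly(vals, dates)
    ws = regularize_weekly(vals[ok], dates[ok])
    return ws


def seasonality_table(
    species_table: SampleTable,
    retained: list[str],
    config: RunConfig,
    ci_rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, SeasonalResult]]:
    """Decompose and fit every retained species of one plant.

    Returns the long-format results table (one row per species) and the
    mapping species -> :class:`SeasonalResult`.
    """
    rel = species_table.relative()
    mat = rclr(rel.to_numpy())
    rclr_df = pd.DataFrame(mat, index=rel.index, columns=rel.columns)
    dates = pd.DatetimeIndex(species_table.meta["date"])
    order = np.argsort(dates.values)
    dates = dates[order]
    rclr_df = rclr_df.iloc[order]
    if ci_rng is None:
        ci_rng = np.random.default_rng(config.seed + 7777)

    plant = str(species_table.meta["plant"].iloc[0])
    rows = []
    results: dict[str, SeasonalResult] = {}
    for sp in retained:
        ws = _species_weekly_series(rclr_df[sp].to_numpy(), dates, config.rclr_zero)
        dec = stl_periodic(ws, frequency=config.frequency)
        if config.fit_on == "seasonal":
            target = WeeklySeries(dec.seasonal, start_date=ws.start_date,
                                  frequency=ws.frequency)
        else:
            target = ws
        fit = fit_harmonic(target, period=float(config.frequency))
        try:
            fs = seasonal_strength(dec)
        except ValueError:
            fs = 0.0
        strength = strength_category(fs, fit.p_value, alpha=config.alpha)
        cohort = assign_cohort(fit, alpha=config.alpha)
        if fit.p_value <= config.alpha:
            ci_low, ci_high = peak_confidence_interval(
                fit, target, n_boot=config.n_boot, seed=ci_rng
            )
        else:
            ci_low = ci_high = float("nan")
        results[sp] = SeasonalResult(
            species_id=sp, fit=fit, fs=fs, strength=strength, cohort=cohort,
            ci_low=ci_low, ci_high=ci_high,
        )
        rows.append(
            {
                "species": sp, "plant": plant, "m": fit.m, "A": fit.amplitude,
                "phi": fit.phase, "p_value": fit.p_value,
                "peak_week": fit.peak_week, "peak_doy": fit.peak_doy,
                "ci_low": ci_low, "ci_high": ci_high, "fs": fs,
                "strength": strength, "cohort": cohort,
            }
        )
    return pd.DataFrame(rows), results


def analyze_plant(
    table: SampleTable,
    taxonomy: TaxonomyTable,
    config: RunConfig,
    seed_offset: int = 0,
) -> dict:
    """QC, transform, decompose and fit one plant's table."""
    from seasonflow.cross_plant import diversity_series

    t0 = time.perf_counter()
    filtered = filter_min_reads(table, config.min_reads)
    diversity = diversity_series(
        filtered, depth=config.rarefaction_depth,
        seed=np.random.default_rng(config.seed + 31 + seed_offset),
        alpha=config.alpha,
    )
    merged = merge_replicates(filtered)
    species_table = aggregate_to_species(merged, taxonomy)
    retained = retain_abundant_species(species_table, config.abundance_threshold)
    seasonal_df, results = seasonality_table(
        species_table, retained, config,
        ci_rng=np.random.default_rng(config.seed + 7777 + seed_offset),
    )
    log.info(
        "plant %s: %d samples in, %d post-QC, %d species retained (%.1fs)",
        table.meta["plant"].iloc[0], table.n_samples, filtered.n_samples,
        len(retained), time.perf_counter() - t0,
    )
    return {
        "filtered": filtered,
        "species_table": species_table,
        "retained": retained,
        "seasonal": seasonal_df,
        "results": results,
        "diversity": diversity,
    }


def _simulate_inputs(config: RunConfig) -> dict:
    shared = make_species_specs(
        config.n_shared, seed=config.seed + 1, prefix="midas_s"
    )
    plants = {}
    for i in range(config.n_plants):
        pid = f"WWTP{chr(ord('A') + i)}"
        spec = PlantSpec(
            plant_id=pid,
            n_species=config.n_species,
            years=config.years,
            sampling_interval_days=config.sampling_interval_days,
            seed=config.seed + 101 * (i + 1),
        )
        table, meta, taxonomy, specs = simulate_plant(spec, shared_species=shared)
        pairs = simulate_influent_pairs(
            specs, spec, n_dates=config.growth_n_dates,
            seed=config.seed + 211 * (i + 1),
            noise_sd=config.growth_noise_sd,
        )
        keys = analysis_keys(specs, taxonomy)
        rename = dict(zip([s.species_id for s in specs], keys))
        pairs["influent"] = pairs["influent"].rename(columns=rename)
        pairs["reactor"] = pairs["reactor"].rename(columns=rename)
        pairs["true_k"] = pairs["true_k"].rename(index=rename)
        plants[pid] = {
            "spec": spec,
            "table": table,
            "taxonomy": taxonomy,
            "species_specs": specs,
            "truth": ground_truth_frame(specs, taxonomy),
            "pairs": pairs,
        }
    return {"shared_specs": shared, "plants": plants}


def _growth_tables(plants: dict, analyses: dict, config: RunConfig):
    """Per-date k estimates and growth-group classification across plants."""
    records = []
    max_ab = {}
    for pid, pdata in plants.items():
        pairs = pdata.get("pairs")
        if pairs is None:
            continue
        infl, reac = pairs["influent"], pairs["reactor"]
        k = estimate_net_growth(
            infl.to_numpy(), pairs["influent_total_cells"],
            reac.to_numpy(), pairs["reactor_total_cells"],
            pairs["srt_days"], pairs["hrt_days"],
        )
        k_df = pd.DataFrame(k, index=infl.index, columns=infl.columns)
        long = k_df.stack().rename("k").reset_index()
        long.columns = ["date", "species", "k"]
        long["plant"] = pid
        records.append(long[["species", "plant", "k"]])
        rel = analyses[pid]["species_table"].relative()
        for sp in rel.columns:
            max_ab[sp] = max(max_ab.get(sp, 0.0), float(rel[sp].max()))
    if not records:
        return None, None
    k_table = pd.concat(records, ignore_index=True)
    estimates = classify_growth_table(
        k_table, pd.Series(max_ab), epsilon=config.epsilon_k
    )
    growth_df = pd.DataFrame(
        {
            "species": [e.species_id for e in estimates],
            "median_k": [e.k for e in estimates],
            "group": [e.group for e in estimates],
            **{
                f"k_{pid}": [e.per_plant_k.get(pid, np.nan) for e in estimates]
                for pid in sorted(plants)
            },
        }
    ).set_index("species")
    return growth_df, estimates


def run_all(config: RunConfig, inputs: dict | None = None) -> dict:
    """Execute the full pipeline and return the result bundle.

    ``inputs`` may carry pre-built per-plant data (keys ``plants`` ->
    ``{plant_id: {"table", "taxonomy", optional "pairs"}}``); otherwise
    a multi-plant community is simulated from the config.  When
    ``config.outdir`` is set, every result table plus a JSON manifest is
    written there.
    """
    t_start = time.perf_counter()
    if inputs is None:
        inputs = _simulate_inputs(config)
    plants = inputs["plants"]

    analyses = {}
    for i, (pid, pdata) in enumerate(sorted(plants.items())):
        analyses[pid] = analyze_plant(
            pdata["table"], pdata["taxonomy"], config, seed_offset=i
        )

    seasonal_all = pd.concat(
        [a["seasonal"] for a in analyses.values()], ignore_index=True
    )
    growth_df, growth_estimates = _growth_tables(plants, analyses, config)

    membership = shared_species(
        {pid: set(a["retained"]) for pid, a in analyses.items()}
    )
    plant_ids = sorted(analyses)
    in_all = membership.index[membership["n_plants"] == len(plant_ids)]
    intersections = cohort_intersections(
        {pid: analyses[pid]["results"] for pid in plant_ids},
        species=[
            sp for sp in in_all
            if all(sp in analyses[pid]["results"] for pid in plant_ids)
        ],
    )
    summary = intersection_summary(intersections)

    groups_by_plant = {}
    if growth_df is not None:
        assignment_full = growth_df["group"].to_dict()
        for pid in plant_ids:
            assignment = {
                sp: assignment_full.get(sp, "ambiguous")
                for sp in analyses[pid]["retained"]
            }
            groups_by_plant[pid] = group_series(
                analyses[pid]["species_table"], assignment, alpha=config.alpha
            )

    manifest = {
        "package_version": _pkg_version,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "versions": _lib_versions(),
        "n_plants": len(plant_ids),
        "per_plant": {
            pid: {
                "n_samples_in": plants[pid]["table"].n_samples,
                "n_samples_qc": analyses[pid]["filtered"].n_samples,
                "n_retained_species": len(analyses[pid]["retained"]),
                "n_seasonal_rows": int(len(analyses[pid]["seasonal"])),
            }
            for pid in plant_ids
        },
        "n_shared_all_plants": int(len(in_all)),
        "runtime_s": round(time.perf_counter() - t_start, 2),
    }

    bundle = {
        "config": config,
        "inputs": inputs,
        "analyses": analyses,
        "seasonal": seasonal_all,
        "growth": growth_df,
        "growth_estimates": growth_estimates,
        "membership": membership,
        "intersections": intersections,
        "intersection_summary": summary,
        "group_series": groups_by_plant,
        "manifest": manifest,
    }
    if config.outdir:
        _write_bundle(bundle, Path(config.outdir))
    return bundle


def _lib_versions() -> dict:
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["seasonal"].to_csv(outdir / "seasonality.tsv", sep="\t", index=False)
    if bundle["growth"] is not None:
        bundle["growth"].to_csv(outdir / "growth_groups.tsv", sep="\t")
    bundle["membership"].to_csv(outdir / "shared_species.tsv", sep="\t")
    bundle["intersections"].to_csv(outdir / "cohort_intersections.tsv", sep="\t")
    bundle["intersection_summary"].to_csv(
        outdir / "intersection_summary.tsv", sep="\t", index=False
    )
    for pid, pdata in bundle["inputs"]["plants"].items():
        if "truth" in pdata:
            pdata["truth"].to_csv(outdir / f"ground_truth_{pid}.tsv", sep="\t")
    rows = []
    for pid, groups in bundle["group_series"].items():
        for label, g in groups.items():
            fit = g["fit_all"]
            rows.append(
                {"plant": pid, "group": label, "n_species": g["n_species"],
                 "p_value": fit.p_value, "peak_week": fit.peak_week,
                 "amplitude": fit.amplitude,
                 "significant": fit.p_value <= bundle["config"].alpha}
            )
    if rows:
        pd.DataFrame(rows).to_csv(outdir / "group_series_fits.tsv",
                                  sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2)
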