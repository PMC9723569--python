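"""Cross-plant cohort agreement, shared-species sets, aggregate series."""

import numpy as np
import pandas as pd
import pytest

from seasonflow.cross_plant import (
    agreement_class,
    cohort_intersections,
    diversity_series,
    group_series,
    intersection_summary,
    shared_species,
)
from seasonflow.seasonal import COHORTS, SeasonalResult, fit_harmonic
from seasonflow.decomposition import WeeklySeries
from tests.conftest import make_sample_table


class TestAgreementClass:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            (("spring",) * 4, "identical"),
            (("spring", "summer", "spring", "summer"), "concomitant"),
            (("winter", "summer", "winter", "winter"), "mixed"),  # opposite
            (("spring", "autumn", "spring", "spring"), "mixed"),  # opposite
            (("winter", "spring", "summer", "spring"), "mixed"),  # 3 cohorts
            (("autumn", "winter", "autumn", "winter"), "concomitant"),  # wraps
            (("non-significant",) * 4, "all-non-significant"),
            (("spring", "non-significant", "spring", "spring"), "identical"),
            (("spring", "summer", "non-significant", "spring"), "concomitant"),
        ],
    )
    def test_classes(self, labels, expected):
        assert agreement_class(labels) == expected

    def test_permutation_invariant(self, rng):
        labels = ["spring", "summer", "non-significant", "spring"]
        base = agreement_class(labels)
        for _ in range(5):
            rng.shuffle(labels)
            assert agreement_class(labels) == base

    def test_opposite_seasons_never_identical_or_concomitant(self):
        # structural rule: winter/summer and spring/autumn cannot agree
        for a, b in [("winter", "summer"), ("spring", "autumn")]:
            for labels in ([a, b], [a, b, a, b], [a, a, b, "non-significant"]):
                assert agreement_class(labels) == "mixed"


class TestSharedSpecies:
    def test_membership_and_counts(self):
        retained = {
            "P1": {"a", "b", "c"},
            "P2": {"a", "c"},
            "P3": {"a", "d"},
        }
        member = shared_species(retained)
        assert member.loc["a", ["P1", "P2", "P3"]].all()
        assert member.loc["a", "n_plants"] == 3
        assert member.loc["d", "n_plants"] == 1
        assert set(member.index) == {"a", "b", "c", "d"}

    def test_disjoint_sets_have_no_overlap(self):
        member = shared_species({"P1": {"a"}, "P2": {"b"}})
        assert (member["n_plants"] == 1).all()

    def test_single_plant_rejected(self):
        with pytest.raises(ValueError):
            shared_species({"P1": {"a"}})


def _result(species, cohort, strength="strong"):
    return SeasonalResult(species_id=species, fit=None, fs=0.6,
                          strength=strength, cohort=cohort)


class TestCohortIntersections:
    def test_table_and_summary(self):
        results = {
            "P1": {"a": _result("a", "spring"), "b": _result("b", "winter")},
            "P2": {"a": _result("a", "summer"), "b": _result("b", "summer")},
        }
        tab = cohort_intersections(results)
        assert tab.loc["a", "agreement"] == "concomitant"
        assert tab.loc["b", "agreement"] == "mixed"
        assert tab.loc["a", "intersection"] == "spring+summer"
        summ = intersection_summary(tab)
        assert summ["n_species"].sum() == 2

    def test_plant_order_invariance(self):
        results = {
            "P1": {"a": _result("a", "spring")},
            "P2": {"a": _result("a", "summer")},
        }
        swapped = {"P2": results["P2"], "P1": results["P1"]}
        assert (
            cohort_intersections(results).loc["a", "agreement"]
            == cohort_intersections(swapped).loc["a", "agreement"]
        )


def _seasonal_table(rng, n_weeks=160, peak_week=10):
    """Three taxa: two seasonal labelled 'g', one flat labelled 'd'."""
    dates = pd.date_range("2015-01-01", periods=n_weeks, freq="7D")
    t = np.arange(n_weeks)
    base = np.exp(1.2 * np.cos(2 * np.pi * (t - (peak_week - 1)) / 52.18))
    p = np.column_stack([base, base, np.ones(n_weeks)])
    p /= p.sum(axis=1, keepdims=True)
    counts = np.stack(
        [rng.multinomial(20_000, row) for row in p]
    )
    return make_sample_table(counts, dates)


class TestGroupSeries:
    def test_partition_sums_to_one(self, rng):
        t = _seasonal_table(rng)
        groups = group_series(t, {"t1": "g", "t2": "g", "t3": "d"})
        total = groups["g"]["series"].values + groups["d"]["series"].values
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_seasonal_label_peak_recovered(self, rng):
        t = _seasonal_table(rng, peak_week=10)
        groups = group_series(t, {"t1": "g", "t2": "g", "t3": "d"})
        fit = groups["g"]["fit"]
        assert fit is not None
        assert abs(fit.peak_week - 10.0) <= 1.0

    def test_flat_label_not_significant(self, rng):
        # the flat taxon's share is 1 - seasonal share: it inherits the
        # mirror-image seasonality, so use an all-flat table instead
        dates = pd.date_range("2015-01-01", periods=160, freq="7D")
        counts = np.stack(
            [rng.multinomial(20_000, [0.5, 0.3, 0.2]) for _ in range(160)]
        )
        t = make_sample_table(counts, dates)
        groups = group_series(t, {"t1": "g", "t2": "g", "t3": "d"})
        assert groups["d"]["fit"] is None


class TestDiversitySeries:
    def test_deterministic_and_fits_present(self, rng):
        counts = rng.integers(50, 400, size=(120, 40))
        counts[:, 0] += 12_000
        dates = pd.date_range("2015-01-06", periods=120, freq="9D")
        t = make_sample_table(counts, dates)
        d1 = diversity_series(t, depth=10_000, seed=3)
        d2 = diversity_series(t, depth=10_000, seed=3)
        np.testing.assert_array_equal(
            d1["richness"]["series"].values, d2["richness"]["series"].values
        )
        assert set(d1) == {"richness", "simpson_1_minus_d"}
        for m in d1.values():
            assert len(m["series"]) >= 104

    def test_richness_seasonality_recovered(self, rng):
        # community where many taxa only appear around autumn: the
        # richness fit must peak in the autumn window
        n_weeks, n_extra = 160, 60
        dates = pd.date_range("2015-01-01", periods=n_weeks, freq="7D")
        t_idx = np.arange(n_weeks)
        doy = (t_idx * 7) % 365 + 1
        in_autumn = (doy >= 266) & (doy <= 354)
        counts = np.zeros((n_weeks, 20 + n_extra), dtype=int)
        counts[:, :20] = rng.integers(500, 1500, size=(n_weeks, 20))
        counts[in_autumn, 20:] = rng.integers(5, 60, size=(in_autumn.sum(), n_extra))
        counts[:, 0] += 15_000
        t = make_sample_table(counts, dates)
        d = diversity_series(t, depth=10_000, seed=1)
        fit = d["richness"]["fit"]
        assert fit is not None
        assert 266 <= fit.peak_doy <= 354
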