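"""Poaching counterfactual: density reduction, visit losses, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elevisits.counterfactual import (CounterfactualResult,
                                      aggregate_visit_losses,
                                      counterfactual_all, poached_density,
                                      visit_loss)
from tests.test_io import make_record
from tests.test_model import degenerate_fit


class TestPoachedDensity:
    def test_proportional_reduction(self):
        assert poached_density(1.0, 0.06) == pytest.approx(0.94)

    def test_zero_rate_identity(self):
        assert poached_density(1.7, 0.0) == 1.7

    def test_composes_with_density_definition(self):
        rec = make_record(elephant_pop_mean=2000.0, censused_area_km2=1000.0,
                          poach_decline_rate=0.05)
        assert poached_density(rec.observed_density, rec.poach_decline_rate) \
            == pytest.approx(1.90)

    @pytest.mark.parametrize("rate", [-0.1, 1.0, 1.5])
    def test_out_of_range_rate_rejected(self, rate):
        with pytest.raises(ValueError):
            poached_density(1.0, rate)


class TestVisitLoss:
    def test_zero_decline_zero_loss(self):
        fit = degenerate_fit({"intercept": np.log(1000.0), "elephant_density": 1.55})
        rec = make_record(poach_decline_rate=0.0)
        assert visit_loss(fit, rec).visit_loss == 0.0

    def test_closed_form_multiplicative_loss(self):
        """Savannah PA at baseline 1,883 visits losing 0.1 km^-2 of density:
        loss = 1883 * (1 - exp(-0.155))."""
        base_d = 2.0
        fit = degenerate_fit({"intercept": np.log(1883.0) - 1.55 * base_d,
                              "elephant_density": 1.55})
        rec = make_record(forest=False, elephant_pop_mean=2000.0,
                          censused_area_km2=1000.0,
                          poach_decline_rate=0.05)  # 2.0 -> 1.9
        res = visit_loss(fit, rec)
        assert res.median_visits_baseline == pytest.approx(1883.0, rel=1e-12)
        assert res.visit_loss == pytest.approx(1883 * (1 - np.exp(-0.155)), rel=1e-9)
        assert res.visit_loss == pytest.approx(270.3, abs=0.1)

    def test_forest_interaction_offsets_main_effect(self):
        """With the interaction cancelling most of the density effect, a
        forested PA loses almost nothing."""
        fit = degenerate_fit({"intercept": np.log(1883.0),
                              "elephant_density": 1.55, "density_forest": -2.02})
        sav = make_record(forest=False, elephant_pop_mean=2000.0,
                          censused_area_km2=1000.0, poach_decline_rate=0.05)
        forr = make_record(forest=True, elephant_pop_mean=2000.0,
                           censused_area_km2=1000.0, poach_decline_rate=0.05)
        loss_savannah = visit_loss(fit, sav).visit_loss
        loss_forest = visit_loss(fit, forr).visit_loss
        assert loss_forest < 0.1 * loss_savannah

    def test_negative_loss_floored_at_zero(self):
        fit = degenerate_fit({"intercept": np.log(100.0), "elephant_density": -1.0})
        rec = make_record(forest=False, poach_decline_rate=0.3)
        assert visit_loss(fit, rec).visit_loss == 0.0

    def test_record_without_elephants_rejected(self):
        fit = degenerate_fit({"intercept": 1.0})
        rec = make_record(elephant_pop_mean=None, elephant_pop_sd=None,
                          censused_area_km2=None)
        with pytest.raises(ValueError, match="PA001"):
            visit_loss(fit, rec)

    def test_monotone_in_decline_rate(self):
        fit = degenerate_fit({"intercept": np.log(1000.0), "elephant_density": 1.55})
        losses = []
        for rate in (0.0, 0.05, 0.1, 0.2):
            rec = make_record(forest=False, poach_decline_rate=rate)
            losses.append(visit_loss(fit, rec).visit_loss)
        assert all(a <= b for a, b in zip(losses, losses[1:]))


def cf(pa_id: str, region: str, loss: float) -> CounterfactualResult:
    return CounterfactualResult(pa_id=pa_id, region=region, baseline_density=1.0,
                                reduced_density=0.9, median_visits_baseline=loss,
                                median_visits_reduced=0.0, visit_loss=loss,
                                elephant_pop_mean=2000.0)


class TestAggregation:
    def test_regional_sums_and_grand_total(self):
        results = [cf("A", "east", 100), cf("B", "east", 200), cf("C", "west", 50)]
        agg = aggregate_visit_losses(results).set_index("region")
        assert agg.loc["east", "visit_loss"] == 300
        assert agg.loc["west", "visit_loss"] == 50
        assert agg.loc["central", "visit_loss"] == 0
        assert agg.loc["all", "visit_loss"] == 350

    def test_unknown_region_rejected(self):
        bad = cf("A", "east", 10)
        bad.region = "north"
        with pytest.raises(ValueError, match="north"):
            aggregate_visit_losses([bad])

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            aggregate_visit_losses([])

    @given(st.lists(st.tuples(st.sampled_from(["central", "east", "south", "west"]),
                              st.floats(0, 1e6)), min_size=1, max_size=20),
           st.randoms(use_true_random=False))
    @settings(max_examples=30, deadline=None)
    def test_permutation_invariant_and_exactly_additive(self, items, rnd):
        results = [cf(f"PA{i}", reg, loss) for i, (reg, loss) in enumerate(items)]
        shuffled = list(results)
        rnd.shuffle(shuffled)
        a1 = aggregate_visit_losses(results).set_index("region")
        a2 = aggregate_visit_losses(shuffled).set_index("region")
        assert a1["visit_loss"].to_dict() == a2["visit_loss"].to_dict()
        regions = [r for r in a1.index if r != "all"]
        assert a1.loc["all", "visit_loss"] == sum(a1.loc[r, "visit_loss"] for r in regions)

    def test_end_to_end_matches_brute_force(self, fitted, synthetic_study):
        records, _ = synthetic_study
        results = counterfactual_all(fitted, records)
        assert len(results) == 216
        agg = aggregate_visit_losses(results).set_index("region")
        brute = sum(r.visit_loss for r in results)
        assert agg.loc["all", "visit_loss"] == pytest.approx(brute, rel=1e-12)
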