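"""Implant engineering: surface area, residual-drug rates, regression, IVIVC."""

import math

import numpy as np
import pytest

from tafpk import (
    ImplantRecord,
    ReleaseSeries,
    aggregate_pocket,
    in_vivo_release_rate,
    ivivc,
    orifice_surface_area,
    weight_adjusted_rate,
    zero_order_regression,
)
from tafpk.release_kinetics import release_series_from_records, rates_table
from tafpk.synthetic_data import generate_release_series


def _rec(animal="d1", load=100.0, residual=38.0, days=30.0, **kw):
    return ImplantRecord(animal=animal, initial_load=load, residual=residual,
                         days_in_situ=days, **kw)


class TestOrificeSurfaceArea:
    def test_unit_circle(self):
        assert orifice_surface_area(1, 2.0) == pytest.approx(math.pi)

    def test_hand_arithmetic(self):
        assert orifice_surface_area(4, 0.5) == pytest.approx(4 * math.pi * 0.0625)

    def test_linear_in_orifice_count(self):
        assert orifice_surface_area(8, 0.37) == pytest.approx(
            2 * orifice_surface_area(4, 0.37), rel=1e-12)

    @pytest.mark.parametrize("n,d", [(0, 1.0), (1, 0.0), (1, -2.0)])
    def test_nonphysical_inputs(self, n, d):
        with pytest.raises(ValueError):
            orifice_surface_area(n, d)


class TestInVivoReleaseRate:
    def test_nothing_released(self):
        assert in_vivo_release_rate(_rec(residual=100.0)) == 0.0

    def test_hand_arithmetic(self):
        assert in_vivo_release_rate(_rec()) == pytest.approx(62.0 / 30.0)

    def test_mean_of_published_dog_single_implant_rates(self):
        """Two 10-mm implant dogs released 0.55 and 0.90 mg/d -> mean 0.73."""
        rates = [in_vivo_release_rate(_rec(load=50, residual=50 - r * 30))
                 for r in (0.55, 0.90)]
        assert np.mean(rates) == pytest.approx(0.73, abs=0.005)

    def test_invariant_to_splitting_duration(self):
        """Summed sub-interval releases over the same total duration give the
        same average rate."""
        whole = in_vivo_release_rate(_rec(load=80, residual=20, days=30))
        # same animal measured as two serial intervals releasing 35 + 25 mg
        first = in_vivo_release_rate(_rec(load=80, residual=45, days=15))
        second = in_vivo_release_rate(_rec(load=45, residual=20, days=15))
        assert (first + second) / 2 == pytest.approx(whole, rel=1e-12)

    def test_residual_exceeding_load_rejected(self):
        with pytest.raises(ValueError):
            _rec(residual=120.0)


class TestZeroOrderRegression:
    def test_perfect_line_recovered(self):
        t = np.array([3.0, 7.0, 14.0, 21.0, 28.0])
        series = ReleaseSeries(time=t, cumulative_released=0.25 * t + 0.1)
        fit = zero_order_regression(series)
        assert fit.slope == pytest.approx(0.25, rel=1e-10)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_on_hand_data(self):
        """4-point series checked against hand-expanded OLS arithmetic:
        slope = 1.225/5 = 0.245, intercept = 0.4625 - 0.245*1.5 = 0.095."""
        series = ReleaseSeries(time=[0.0, 1.0, 2.0, 3.0],
                               cumulative_released=[0.1, 0.35, 0.55, 0.85])
        fit = zero_order_regression(series)
        assert fit.slope == pytest.approx(0.245, rel=1e-12)
        assert fit.intercept == pytest.approx(0.095, rel=1e-12)

    def test_shift_changes_intercept_only(self):
        t = np.array([1.0, 5.0, 9.0, 14.0])
        y = np.array([0.4, 1.9, 3.1, 4.9])
        base = zero_order_regression(ReleaseSeries(time=t, cumulative_released=y))
        shifted = zero_order_regression(
            ReleaseSeries(time=t, cumulative_released=y + 7.0))
        assert shifted.slope == pytest.approx(base.slope, rel=1e-12)
        assert shifted.intercept == pytest.approx(base.intercept + 7.0,
                                                  rel=1e-10)

    def test_confidence_bands_cover_the_line(self):
        t = np.array([3.0, 7.0, 14.0, 21.0, 28.0])
        rng = np.random.default_rng(0)
        y = 0.3 * t + rng.normal(0, 0.2, t.size)
        fit = zero_order_regression(ReleaseSeries(time=t, cumulative_released=y))
        pred = fit.predict(t)
        assert np.all(fit.mean_lower <= pred) and np.all(pred <= fit.mean_upper)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            zero_order_regression(
                ReleaseSeries(time=[1.0, 2.0], cumulative_released=[0.1, 0.2]))

    def test_slope_recovery_within_two_se(self):
        """On synthetic serial-sacrifice data with Gaussian residual noise,
        the OLS slope lands within 2 SE of truth in >= 90% of replicates.
        A dense schedule keeps the residual degrees of freedom high enough
        that +/-2 SE is close to a 95% interval."""
        hits = 0
        n_rep = 200
        schedule = np.arange(2.0, 30.0, 2.0)
        for seed in range(n_rep):
            records = generate_release_series(
                true_rate=0.25, load=10.0, residual_noise_sd=0.4,
                schedule=schedule, seed=seed)
            series = release_series_from_records(records)
            fit = zero_order_regression(series)
            if abs(fit.slope - 0.25) <= 2 * fit.slope_se:
                hits += 1
        assert hits / n_rep >= 0.90


class TestIvivc:
    @pytest.mark.parametrize("vitro,vivo,expected", [
        (2.53, 1.53, 0.60),  # dog, 40 mm
        (1.46, 0.23, 0.16),  # mouse, 10 mm
        (1.46, 0.30, 0.21),  # sheep, 10 mm
    ])
    def test_published_table_values_to_two_sf(self, vitro, vivo, expected):
        assert round(ivivc(vitro, vivo), 2) == expected

    def test_identity_for_equal_rates(self):
        for x in (0.1, 1.0, 7.32):
            assert ivivc(x, x) == 1.0

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            ivivc(0.0, 1.0)
        with pytest.raises(ValueError):
            ivivc(1.0, -1.0)


class TestWeightAdjustedRate:
    def test_unit_case(self):
        assert weight_adjusted_rate(1.0, 1.0) == 1000.0

    def test_dog_scale_value(self):
        assert weight_adjusted_rate(2.07, 10.4) == pytest.approx(199.0, rel=0.01)

    def test_inverse_in_weight(self):
        assert weight_adjusted_rate(1.5, 20.0) == pytest.approx(
            weight_adjusted_rate(1.5, 10.0) / 2, rel=1e-12)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            weight_adjusted_rate(1.0, 0.0)


class TestAggregatePocket:
    def test_sum_of_two_implants(self):
        recs = [_rec(load=66, residual=30, days=30),   # 1.2 mg/d
                _rec(load=81, residual=30, days=30)]   # 1.7 mg/d
        total, complete = aggregate_pocket(recs)
        assert total == pytest.approx(2.9)
        assert complete

    def test_missing_implant_flagged_and_excluded(self):
        recs = [_rec(load=66, residual=30, days=30),
                _rec(residual=None, recovered=False)]
        with pytest.warns(UserWarning, match="missing"):
            total, complete = aggregate_pocket(recs)
        assert total == pytest.approx(1.2)
        assert not complete

    def test_median_iqr_of_dual_pocket_sums(self):
        """Eight dual-implant animals with hand-set rates: the median and
        IQR of per-animal sums match direct arithmetic."""
        per_animal = {f"d{i}": (0.9 + 0.1 * i, 1.1 + 0.1 * i)
                      for i in range(8)}
        sums = []
        for animal, (r1, r2) in per_animal.items():
            recs = [_rec(animal=animal, load=100, residual=100 - r1 * 30),
                    _rec(animal=animal, load=100, residual=100 - r2 * 30)]
            total, _ = aggregate_pocket(recs)
            sums.append(total)
        expected = sorted(r1 + r2 for r1, r2 in per_animal.values())
        assert np.median(sums) == pytest.approx(np.median(expected))
        assert np.percentile(sums, 25) == pytest.approx(
            np.percentile(expected, 25))

    def test_empty_and_mixed_animal_groups_rejected(self):
        with pytest.raises(ValueError):
            aggregate_pocket([])
        with pytest.raises(ValueError, match="multiple animals"):
            aggregate_pocket([_rec(animal="a"), _rec(animal="b")])


def test_rates_table_aggregates_and_weights():
    recs = [_rec(animal="d1", load=100, residual=40, days=30),
            _rec(animal="d2", load=100, residual=10, days=30),
            _rec(animal="d2", load=100, residual=40, days=30)]
    table = rates_table(recs, weights_kg={"d1": 10.0})
    d1 = table[table.animal == "d1"].iloc[0]
    d2 = table[table.animal == "d2"].iloc[0]
    assert d1.rate_mg_d == pytest.approx(2.0)
    assert d1.rate_ug_kg_d == pytest.approx(200.0)
    assert d2.rate_mg_d == pytest.approx(5.0)
    assert d2.n_recovered == 2
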