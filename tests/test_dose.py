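import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thermoshift.dose import (
    DoseSeries,
    compare_tm_groups,
    destabilization_profile,
    fit_4pl,
    grid_search_4pl_sse,
    predict_4pl,
    stabilization_suppression,
)
from thermoshift.errors import DegenerateFitError, ValidationError
from thermoshift.melt import TmEstimate


def _est(tm, well="w"):
    return TmEstimate(well_id=well, tm=tm, peak_height=1.0, search_range=(25.0, 90.0))


def _group(*tms):
    return [_est(tm, f"w{i}") for i, tm in enumerate(tms)]


DOSES = np.logspace(0, 2, 8)  # 1-100 uM


class TestPredict4pl:
    def test_midpoint_definition(self):
        assert predict_4pl(10.0, ic50=10.0, hill=1.0, top=100.0, bottom=0.0) == pytest.approx(50.0)

    def test_zero_dose_is_bottom(self):
        assert predict_4pl(0.0, 16.4, 1.0, 100.0, 5.0) == pytest.approx(5.0)

    @given(d=st.floats(1e-3, 1e4), step=st.floats(1e-3, 1e3))
    def test_monotone_for_positive_hill(self, d, step):
        lo = predict_4pl(d, 16.4, 1.2, 100.0, 0.0)
        hi = predict_4pl(d + step, 16.4, 1.2, 100.0, 0.0)
        assert lo <= hi + 1e-9


class TestFit4pl:
    def test_noiseless_round_trip(self):
        series = DoseSeries(DOSES, predict_4pl(DOSES, 16.4, 1.0, 100.0, 0.0),
                            response_kind="stabilization_fraction")
        fit = fit_4pl(series)
        assert fit.converged
        assert fit.ic50 == pytest.approx(16.4, rel=1e-3)
        assert fit.hill == pytest.approx(1.0, rel=1e-3)

    def test_symmetric_half_max_at_dose_10(self):
        doses = np.array([1.0, 5.0, 10.0, 20.0, 100.0])
        resp = predict_4pl(doses, 10.0, 1.0, 100.0, 0.0)
        fit = fit_4pl(DoseSeries(doses, resp, response_kind="stabilization_fraction"))
        assert fit.ic50 == pytest.approx(10.0, rel=1e-4)

    def test_noisy_recovery_within_15_percent(self):
        rng = np.random.default_rng(21)
        resp = predict_4pl(DOSES, 19.1, 1.0, 100.0, 0.0) + rng.normal(0, 2.0, DOSES.size)
        fit = fit_4pl(DoseSeries(DOSES, resp, response_kind="stabilization_fraction"))
        assert fit.converged
        assert abs(fit.ic50 - 19.1) / 19.1 <= 0.15

    def test_fewer_than_four_distinct_doses_rejected(self):
        with pytest.raises(ValidationError, match="4"):
            fit_4pl(DoseSeries([1.0, 2.0, 4.0], [1.0, 2.0, 3.0],
                               response_kind="stabilization_fraction"))

    @given(scale=st.floats(0.01, 100.0))
    def test_dose_scale_equivariance(self, scale):
        resp = predict_4pl(DOSES, 16.4, 1.0, 100.0, 0.0)
        base = fit_4pl(DoseSeries(DOSES, resp, response_kind="stabilization_fraction"))
        scaled = fit_4pl(DoseSeries(DOSES * scale, resp,
                                    response_kind="stabilization_fraction"))
        assert scaled.ic50 == pytest.approx(base.ic50 * scale, rel=1e-3)

    def test_matches_brute_force_grid(self):
        rng = np.random.default_rng(33)
        for _ in range(20):
            ic50 = rng.uniform(5.0, 40.0)
            hill = rng.uniform(0.7, 2.0)
            resp = predict_4pl(DOSES, ic50, hill, 100.0, 0.0) + rng.normal(0, 1.5, DOSES.size)
            series = DoseSeries(DOSES, resp, response_kind="stabilization_fraction")
            fit = fit_4pl(series)
            _, best_sse = grid_search_4pl_sse(
                series,
                ic50_grid=np.linspace(2.0, 60.0, 30),
                hill_grid=np.linspace(0.5, 2.5, 9),
                top_grid=np.linspace(90.0, 110.0, 5),
                bottom_grid=np.linspace(-5.0, 5.0, 5),
            )
            assert fit.sse <= best_sse + 1e-9


class TestDestabilizationProfile:
    def test_known_shifts_recovered_exactly(self):
        reference = _group(42.5, 42.5, 42.5)
        by_dose = {24.0: _group(41.8, 41.8, 41.8), 50.0: _group(40.8, 40.8, 40.8)}
        series = destabilization_profile(by_dose, reference)
        np.testing.assert_allclose(series.responses, [-0.7, -1.7], atol=1e-12)
        assert series.response_kind == "tm_shift"

    def test_identical_to_reference_gives_zero(self):
        reference = _group(42.5, 42.6, 42.4)
        series = destabilization_profile({10.0: _group(42.5, 42.6, 42.4)}, reference)
        assert series.responses[0] == pytest.approx(0.0, abs=1e-12)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValidationError):
            destabilization_profile({1.0: _group(42.0)}, [])

    def test_noisy_shifts_within_two_sem(self):
        rng = np.random.default_rng(4)
        ref = _group(*(42.5 + rng.normal(0, 0.1, 3)))
        by_dose = {24.0: _group(*(41.8 + rng.normal(0, 0.1, 3))),
                   50.0: _group(*(40.8 + rng.normal(0, 0.1, 3)))}
        series = destabilization_profile(by_dose, ref)
        sem = 0.1 * math.sqrt(2.0 / 3.0)
        for got, expected in zip(series.responses, (-0.7, -1.7)):
            assert abs(got - expected) <= 2 * sem


class TestStabilizationSuppression:
    def _setup(self, shift_at_dose):
        probe = _group(42.5, 42.5, 42.5)
        probe_dna = _group(43.8, 43.8, 43.8)  # 1.3 degC shift
        inh = {10.0: _group(42.5, 42.5, 42.5)}
        dna_inh = {10.0: _group(*(42.5 + shift_at_dose for _ in range(3)))}
        return probe, probe_dna, inh, dna_inh

    def test_abolished_shift_is_100_percent(self):
        series = stabilization_suppression(*self._setup(0.0))
        assert series.responses[0] == pytest.approx(100.0)

    def test_unchanged_shift_is_0_percent(self):
        series = stabilization_suppression(*self._setup(1.3))
        assert series.responses[0] == pytest.approx(0.0, abs=1e-9)

    def test_half_shift_is_50_percent(self):
        series = stabilization_suppression(*self._setup(0.65))
        assert series.responses[0] == pytest.approx(50.0)

    def test_no_stabilization_rejected(self):
        probe = _group(42.5, 42.5)
        probe_dna = _group(42.5, 42.5)
        with pytest.raises(DegenerateFitError, match="no stabilization"):
            stabilization_suppression(probe, probe_dna, {}, {1.0: _group(42.5)})


class TestCompareTmGroups:
    def test_identical_triplicates(self):
        comp = compare_tm_groups([42.5, 42.5, 42.5], [42.5, 42.5, 42.5])
        assert comp.t_stat == 0.0
        assert comp.p_value == 1.0
        assert comp.stars == "ns"

    def test_pooled_t_on_stated_groups(self):
        comp = compare_tm_groups([42.4, 42.5, 42.6], [43.4, 43.5, 43.6])
        assert comp.t_stat == pytest.approx(-12.247, abs=1e-3)
        assert comp.p_value < 0.001
        assert comp.stars == "***"

    def test_large_separation_always_three_stars(self):
        rng = np.random.default_rng(0)
        a = 42.5 + rng.normal(0, 0.1, 6)
        b = a + 10 * 0.1
        assert compare_tm_groups(a, b).stars == "***"

    @given(shift=st.floats(-2.0, 2.0))
    def test_antisymmetric_t_invariant_p(self, shift):
        a = [42.4, 42.5, 42.6]
        b = [v + shift for v in (42.45, 42.55, 42.65)]
        fwd = compare_tm_groups(a, b)
        rev = compare_tm_groups(b, a)
        assert fwd.t_stat == pytest.approx(-rev.t_stat, abs=1e-9)
        assert fwd.p_value == pytest.approx(rev.p_value, abs=1e-12)

    def test_welch_variant_runs(self):
        comp = compare_tm_groups([42.4, 42.5, 42.6], [43.0, 43.5, 44.0], welch=True)
        assert comp.p_value < 0.2

    def test_star_thresholds(self):
        # engineered p just above/below 0.05
        assert compare_tm_groups([1.0, 2.0], [1.0, 2.0]).stars == "ns"
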