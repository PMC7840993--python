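import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thermoshift.binding import (
    BindingSeries,
    bootstrap_ci,
    fit_binding,
    grid_search_sse,
    predict_delta_tm,
)
from thermoshift.errors import DegenerateFitError, ValidationError

P65 = (1.678, 2.228)  # fitted (dTmax degC, K_D uM) of the p65 probe
P50 = (2.462, 0.794)


class TestPredictDeltaTm:
    def test_p65_parameters_at_10uM(self):
        # direct evaluation of the ligand-depletion equation; the value
        # falls inside the observed 1-1.5 degC shift at 10 uM dsDNA
        assert predict_delta_tm(*P65, 10.0) == pytest.approx(1.33480, abs=1e-4)

    def test_p50_parameters_at_10uM(self):
        # inside the observed 2-3 degC shift
        assert predict_delta_tm(*P50, 10.0) == pytest.approx(2.23364, abs=1e-4)

    @given(a=st.floats(0.1, 10.0), k=st.floats(0.0, 50.0))
    def test_zero_ligand_gives_zero_shift(self, a, k):
        assert predict_delta_tm(a, k, 0.0) == pytest.approx(0.0, abs=1e-12)

    @given(a=st.floats(0.1, 10.0), k=st.floats(1e-3, 50.0),
           d=st.floats(0.0, 1e3), step=st.floats(1e-3, 10.0))
    def test_monotone_in_ligand_and_bounded(self, a, k, d, step):
        lo = predict_delta_tm(a, k, d)
        hi = predict_delta_tm(a, k, d + step)
        assert lo <= hi + 1e-12
        assert 0.0 <= lo <= a + 1e-12

    @given(a=st.floats(0.1, 10.0), k=st.floats(1e-3, 50.0),
           d=st.floats(1e-3, 1e3), kstep=st.floats(1e-3, 10.0))
    def test_non_increasing_in_kd(self, a, k, d, kstep):
        assert predict_delta_tm(a, k + kstep, d) <= predict_delta_tm(a, k, d) + 1e-12

    @given(a=st.floats(0.1, 10.0), k=st.floats(0.0, 50.0))
    def test_saturation_limit_is_delta_t_max(self, a, k):
        assert predict_delta_tm(a, k, 1e9) == pytest.approx(a, rel=1e-5)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            predict_delta_tm(-1.0, 1.0, 1.0)
        with pytest.raises(ValidationError):
            predict_delta_tm(1.0, -1.0, 1.0)
        with pytest.raises(ValidationError):
            predict_delta_tm(1.0, 1.0, -1.0)


class TestFitBinding:
    def test_noiseless_round_trip(self, titration_concs):
        series = BindingSeries(titration_concs, predict_delta_tm(*P65, titration_concs))
        fit = fit_binding(series)
        assert fit.converged
        assert fit.delta_t_max == pytest.approx(P65[0], rel=1e-4)
        assert fit.kd == pytest.approx(P65[1], rel=1e-4)

    def test_noisy_recovery_within_25_percent(self, titration_concs):
        rng = np.random.default_rng(7)
        noisy = predict_delta_tm(*P65, titration_concs) + rng.normal(0, 0.05, titration_concs.size)
        fit = fit_binding(BindingSeries(titration_concs, noisy))
        assert fit.converged
        assert abs(fit.kd - P65[1]) / P65[1] <= 0.25

    def test_all_zero_shift_degenerate(self, titration_concs):
        with pytest.raises(DegenerateFitError):
            fit_binding(BindingSeries(titration_concs, np.zeros_like(titration_concs)))

    def test_reorder_invariance(self, titration_concs):
        y = predict_delta_tm(*P65, titration_concs)
        order = np.array([3, 0, 6, 1, 5, 2, 4])
        fit_a = fit_binding(BindingSeries(titration_concs, y))
        fit_b = fit_binding(BindingSeries(titration_concs[order], y[order]))
        assert fit_b.kd == pytest.approx(fit_a.kd, rel=1e-6)

    def test_matching_multiplicity_recovers_truth(self, titration_concs):
        # generated on site concentration (two kB sites per duplex)
        y = predict_delta_tm(*P65, 2.0 * titration_concs)
        fit = fit_binding(BindingSeries(titration_concs, y, site_multiplicity=2))
        assert fit.delta_t_max == pytest.approx(P65[0], rel=1e-6)
        assert fit.kd == pytest.approx(P65[1], rel=1e-6)

    def test_multiplicity_mismatch_biases_kd_down(self, titration_concs):
        # ignoring the second site makes the ligand look more potent
        y = predict_delta_tm(*P65, 2.0 * titration_concs)
        fit = fit_binding(BindingSeries(titration_concs, y, site_multiplicity=1))
        assert fit.kd < P65[1]

    def test_series_invariants(self):
        with pytest.raises(ValidationError):
            BindingSeries([1.0, 2.0], [0.1, 0.2])
        with pytest.raises(ValidationError):
            BindingSeries([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])
        with pytest.raises(ValidationError):
            BindingSeries([-1.0, 1.0, 2.0], [0.1, 0.2, 0.3])


class TestGridSearchOracle:
    def test_fit_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            a_true = rng.uniform(0.5, 3.0)
            k_true = rng.uniform(0.3, 5.0)
            concs = np.sort(rng.uniform(0.2, 12.0, size=6))
            y = predict_delta_tm(a_true, k_true, concs) + rng.normal(0, 0.03, 6)
            if np.allclose(y, 0):
                continue
            series = BindingSeries(concs, y)
            fit = fit_binding(series)
            a_grid = np.linspace(0.2, 4.0, 60)
            k_grid = np.linspace(0.05, 8.0, 60)
            _, _, best_sse = grid_search_sse(series, a_grid, k_grid)
            # the optimizer must do at least as well as the grid optimum
            assert fit.sse <= best_sse + 1e-9


class TestBootstrap:
    def test_noiseless_interval_width_near_zero(self, titration_concs):
        series = BindingSeries(titration_concs, predict_delta_tm(*P65, titration_concs))
        fit = bootstrap_ci(series, fit_binding(series), n_boot=200, seed=3)
        assert fit.ci_kd[1] - fit.ci_kd[0] == pytest.approx(0.0, abs=1e-5)
        assert fit.ci_delta_t_max[1] - fit.ci_delta_t_max[0] == pytest.approx(0.0, abs=1e-5)

    def test_seeded_determinism(self, titration_concs):
        rng = np.random.default_rng(5)
        y = predict_delta_tm(*P65, titration_concs) + rng.normal(0, 0.05, titration_concs.size)
        series = BindingSeries(titration_concs, y)
        base = fit_binding(series)
        first = bootstrap_ci(series, base, n_boot=150, seed=11)
        second = bootstrap_ci(series, base, n_boot=150, seed=11)
        assert first.ci_kd == second.ci_kd
        assert first.ci_delta_t_max == second.ci_delta_t_max

    def test_interval_contains_point_estimate(self, titration_concs):
        rng = np.random.default_rng(9)
        y = predict_delta_tm(*P65, titration_concs) + rng.normal(0, 0.05, titration_concs.size)
        series = BindingSeries(titration_concs, y)
        fit = bootstrap_ci(series, fit_binding(series), n_boot=200, seed=1)
        assert fit.ci_kd[0] <= fit.kd <= fit.ci_kd[1]

    def test_too_few_points_rejected(self):
        concs = np.array([1.0, 2.0, 4.0])
        series = BindingSeries(concs, predict_delta_tm(*P65, concs))
        with pytest.raises(ValidationError, match="4"):
            bootstrap_ci(series, fit_binding(series), n_boot=150, seed=0)
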