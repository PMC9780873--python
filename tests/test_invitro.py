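"""In vitro assay estimators: depletion, integration plot, binding."""

import numpy as np
import pytest

from hepaclear import (
    CONTROL_TRUTH,
    CellPartitionMeasurement,
    DepletionDataset,
    DialysisPair,
    fit_depletion,
    fit_integration_plot,
    fu_from_dialysis,
    fu_hepa_from_partition,
    kpuu_ss,
    split_active_passive,
)
from hepaclear.invitro import AssayInputError, UptakeDataset
from hepaclear.synthetic import make_depletion, make_uptake


TIMES = np.array([0.0, 5.0, 10.0, 20.0, 30.0, 60.0])


class TestDepletion:
    def test_noise_free_exponential_recovered_exactly(self):
        # log-linearisation makes the fit exact on clean exponential decay
        data = DepletionDataset(TIMES, np.exp(-0.00132 * TIMES), cell_density=1.0)
        fit = fit_depletion(data)
        assert fit.k_dep == pytest.approx(0.00132, rel=1e-12)
        assert fit.clint_met_vitro == pytest.approx(1.32, rel=1e-12)
        assert fit.t_half == pytest.approx(np.log(2) / 0.00132, rel=1e-12)
        assert not fit.stable

    def test_flat_trace_flagged_stable(self):
        fit = fit_depletion(DepletionDataset(TIMES, np.ones_like(TIMES)))
        assert fit.stable
        assert fit.k_dep == 0.0
        assert fit.clint_met_vitro == 0.0
        assert np.isinf(fit.t_half)

    def test_cell_density_enters_volume_scaling(self):
        resp = np.exp(-0.002 * TIMES)
        clint_low = fit_depletion(DepletionDataset(TIMES, resp, cell_density=1.0))
        clint_high = fit_depletion(DepletionDataset(TIMES, resp, cell_density=2.0))
        assert clint_low.clint_met_vitro == pytest.approx(
            2 * clint_high.clint_met_vitro
        )

    def test_too_few_points_rejected(self):
        with pytest.raises(AssayInputError):
            DepletionDataset(np.array([0.0, 5.0]), np.array([1.0, 0.9]))

    def test_noisy_recovery_within_noise_tolerance(self):
        # simulate-refit at 5% CV: each replicate within 10% of truth k=0.02
        truth_k = 0.02
        truth = CONTROL_TRUTH
        errs = []
        for seed in range(100):
            data = make_depletion(
                truth.__class__(
                    group="x",
                    invitro=truth.invitro.__class__(
                        clint_met_vitro=truth_k * 1000,
                        ps_inf_hep=1,
                        ps_passive_hep=0,
                        fu_p=0.5,
                        fu_inc_hepa=0.5,
                        fu_hepa=0.5,
                    ),
                    mpbpk=truth.mpbpk,
                ),
                noise_cv=0.05,
                seed=seed,
            )
            errs.append(fit_depletion(data).k_dep / truth_k - 1)
        errs = np.asarray(errs)
        assert np.quantile(np.abs(errs), 0.9) < 0.10
        assert abs(np.median(errs)) < 0.02  # bias check


class TestIntegrationPlot:
    def test_exact_line_recovered(self):
        # construct points lying exactly on y = 11.9 x + 2 with x in minutes
        t = np.array([10.0, 45.0, 60.0, 90.0, 120.0])
        c = np.ones_like(t)
        # with constant buffer, AUC/C = t seconds -> x_min = t/60
        x_hep = 11.9 * (t / 60.0) + 2.0
        data = UptakeDataset(t, x_hep, c, temperature_c=37, c0_nominal=1.0)
        fit = fit_integration_plot(data)
        assert fit.slope == pytest.approx(11.9, rel=1e-12)
        assert fit.v0 == pytest.approx(2.0, rel=1e-9)

    def test_constant_ratio_gives_zero_slope(self):
        t = np.array([10.0, 45.0, 60.0, 90.0, 120.0])
        data = UptakeDataset(t, np.full_like(t, 3.0), np.ones_like(t), 37)
        fit = fit_integration_plot(data)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.v0 == pytest.approx(3.0)

    def test_synthetic_round_trip_noise_free(self):
        data = make_uptake(CONTROL_TRUTH, temperature_c=37, noise_cv=0.0)
        fit = fit_integration_plot(data)
        assert fit.slope == pytest.approx(11.9, rel=5e-3)
        assert fit.v0 == pytest.approx(2.0, rel=0.05)

    def test_simulate_refit_within_ten_percent(self):
        # repeated-dosing truth slope 43.2 µL/min/10^6 cells at 5% noise
        from hepaclear import REPEATED_TRUTH

        est = [
            fit_integration_plot(
                make_uptake(REPEATED_TRUTH, 37, noise_cv=0.05, seed=s)
            ).slope
            for s in range(100)
        ]
        est = np.asarray(est)
        assert np.quantile(np.abs(est / 43.2 - 1), 0.9) < 0.10
        assert abs(np.median(est) / 43.2 - 1) < 0.05

    def test_slope_invariant_to_uniform_concentration_rescaling(self):
        base = make_uptake(CONTROL_TRUTH, 37, noise_cv=0.02, seed=7)
        scaled = UptakeDataset(
            base.time_s,
            base.x_hep * 100.0,
            base.c_buff * 100.0,
            temperature_c=37,
            cell_density=base.cell_density,
            c0_nominal=base.c0_nominal * 100.0,
        )
        f1 = fit_integration_plot(base)
        f2 = fit_integration_plot(scaled)
        assert f2.slope == pytest.approx(f1.slope, rel=1e-10)

    def test_negative_v0_warns(self):
        t = np.array([10.0, 45.0, 60.0, 90.0, 120.0])
        x_hep = 11.9 * (t / 60.0) + 2.0
        # steep line through a negative intercept
        data = UptakeDataset(t, np.maximum(x_hep - 4.0, 0.01), np.ones_like(t), 37)
        with pytest.warns(UserWarning, match="negative initial distribution"):
            fit_integration_plot(data)


class TestTemperatureSplit:
    @pytest.mark.parametrize(
        "s37, s4, expect",
        [((10.0), 4.0, (6.0, 4.0)), (4.0, 4.0, (0.0, 4.0))],
    )
    def test_arithmetic(self, s37, s4, expect):
        split = split_active_passive(s37, s4)
        assert (split.ps_act_vitro, split.ps_diff_vitro) == expect
        assert not split.clamped

    def test_clamping_flagged_not_raised(self):
        with pytest.warns(UserWarning, match="clamped"):
            split = split_active_passive(3.0, 5.0)
        assert split.ps_act_vitro == 0.0
        assert split.clamped

    def test_synthetic_round_trip(self):
        f37 = fit_integration_plot(make_uptake(CONTROL_TRUTH, 37, noise_cv=0.0))
        f4 = fit_integration_plot(make_uptake(CONTROL_TRUTH, 4, noise_cv=0.0))
        split = split_active_passive(f37.slope, f4.slope)
        assert split.ps_act_vitro == pytest.approx(11.9 - 1.29, rel=0.01)
        assert split.ps_diff_vitro == pytest.approx(1.29, rel=0.01)


class TestBindingFractions:
    @pytest.mark.parametrize(
        "donor, receiver, expect",
        [(100.0, 0.78, 0.0078), (100.0, 3.2, 0.032), (5.0, 5.0, 1.0)],
    )
    def test_dialysis_fraction(self, donor, receiver, expect):
        assert fu_from_dialysis(DialysisPair(donor, receiver)) == pytest.approx(expect)

    def test_dialysis_equilibrium_violation_rejected(self):
        with pytest.raises(AssayInputError):
            DialysisPair(1.0, 2.0)

    @pytest.mark.parametrize(
        "a_cell, expect", [(920.0, 0.004), (368.0, 0.01), (3.68, 1.0)]
    )
    def test_fu_hepa_partition(self, a_cell, expect):
        m = CellPartitionMeasurement(a_cell=a_cell, c_buffer=1.0, v_cell=3.68)
        assert fu_hepa_from_partition(m) == pytest.approx(expect)

    def test_fu_hepa_clamped_above_one(self):
        m = CellPartitionMeasurement(a_cell=1.0, c_buffer=1.0, v_cell=3.68)
        with pytest.warns(UserWarning, match="clamped"):
            assert fu_hepa_from_partition(m) == 1.0


class TestKpuu:
    def test_equal_kp_gives_unity(self):
        assert kpuu_ss(2.5, 2.5) == 1.0

    @pytest.mark.parametrize("ratio", [0.11, 1.7])
    def test_printed_ratios(self, ratio):
        assert kpuu_ss(ratio * 3.0, 3.0) == pytest.approx(ratio)

    def test_scale_invariance(self, rng):
        for _ in range(20):
            a, k = rng.uniform(0.01, 10, 2)
            assert kpuu_ss(a * k, k) == pytest.approx(a)
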