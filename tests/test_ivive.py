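"""IVIVE scaling, extended clearance, dispersion model, scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepaclear import (
    DispersionContext,
    ExtendedClearanceParams,
    ScalingContext,
    aafe,
    clh_from_availability,
    clint_all_extended,
    clint_all_method,
    fold_error,
    hepatic_availability,
    ivive_report,
    predict_clh,
    scale_clint_met,
    scale_ps_inf,
    within_fold,
)


class TestScaling:
    @pytest.mark.parametrize(
        "clint_vitro, expect", [(1.32, 160.4), (1.69, 205.3)]
    )
    def test_metabolic_scaling_regenerates_whole_body_values(self, clint_vitro, expect):
        assert scale_clint_met(clint_vitro, 0.032) == pytest.approx(expect, abs=0.1)

    def test_identity_scaling(self):
        ctx = ScalingContext(hepatocellularity=1000.0 / 36.0, liver_weight=36.0)
        assert scale_clint_met(7.3, 1.0, ctx) == pytest.approx(7.3)

    @pytest.mark.parametrize("ps, expect", [(11.9, 46.2), (43.2, 168.0), (0.0, 0.0)])
    def test_uptake_scaling(self, ps, expect):
        assert scale_ps_inf(ps) == pytest.approx(expect, abs=0.1)

    def test_zero_fraction_unbound_rejected(self):
        with pytest.raises(ValueError):
            scale_clint_met(1.0, 0.0)


class TestExtendedClearance:
    def test_metabolism_limited_limit(self):
        # passive permeability dwarfing everything: CL_int,all -> CL_int,met
        p = ExtendedClearanceParams(clint_met=10.0, ps_inf_act=0.0, ps_diff=1e9)
        assert clint_all_extended(p) == pytest.approx(10.0, rel=1e-3)

    def test_uptake_limited_limit(self):
        p = ExtendedClearanceParams(clint_met=1e9, ps_inf_act=4.0, ps_diff=1.0)
        assert clint_all_extended(p) == pytest.approx(5.0, rel=1e-3)

    def test_general_value(self):
        p = ExtendedClearanceParams(
            clint_met=10.0, ps_inf_act=4.0, ps_diff=1.0, ps_eff_act=2.0
        )
        assert clint_all_extended(p) == pytest.approx(10.0 * 5.0 / 13.0, rel=1e-12)

    def test_method_shortcuts(self):
        p = ExtendedClearanceParams(
            clint_met=160.4, ps_inf_act=44.9, ps_diff=1.3, kpuu_ss=0.11
        )
        assert clint_all_method(1, p) == 160.4
        assert clint_all_method(2, p) == pytest.approx(46.2)
        assert clint_all_method(3, p) == pytest.approx(160.4 * 0.11)

    def test_method3_requires_kpuu(self):
        p = ExtendedClearanceParams(clint_met=1.0, ps_inf_act=1.0, ps_diff=1.0)
        with pytest.raises(ValueError, match="kpuu"):
            clint_all_method(3, p)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            clint_all_extended(
                ExtendedClearanceParams(clint_met=0, ps_inf_act=0, ps_diff=0)
            )

    @given(
        clint=st.floats(0.01, 1e3),
        act=st.floats(0.0, 1e3),
        diff=st.floats(0.01, 1e3),
        eff=st.floats(0.0, 1e3),
    )
    @settings(max_examples=200, deadline=None)
    def test_kpuu_identity(self, clint, act, diff, eff):
        # CL_int,all = CL_int,met x Kp_uu with Kp_uu the uptake/efflux ratio
        p = ExtendedClearanceParams(clint, act, diff, eff)
        kpuu = (act + diff) / (eff + diff + clint)
        assert clint_all_extended(p) == pytest.approx(clint * kpuu, rel=1e-12)


class TestDispersionModel:
    def test_no_clearance_means_full_availability(self, control_ctx):
        assert hepatic_availability(0.0, control_ctx) == pytest.approx(1.0)

    def test_parallel_tube_limit(self):
        # D_N -> 0 collapses to F_h = exp(-R_N)
        ctx = DispersionContext(fu_p=0.5, r_b=1.0, d_n=1e-6, q_h=1.0)
        clint = 0.5 / 0.5 / 60 * 1000  # R_N = 0.5
        fh = hepatic_availability(clint, ctx)
        assert fh == pytest.approx(math.exp(-0.5), rel=1e-3)

    def test_well_stirred_limit(self):
        # D_N -> inf collapses to F_h = 1/(1+R_N)
        ctx = DispersionContext(fu_p=0.5, r_b=1.0, d_n=1e6, q_h=1.0)
        clint = 0.5 / 0.5 / 60 * 1000
        fh = hepatic_availability(clint, ctx)
        assert fh == pytest.approx(1.0 / 1.5, rel=1e-3)

    @given(st.floats(0.0, 2e4), st.floats(0.0, 2e4))
    @settings(max_examples=100, deadline=None)
    def test_monotone_decreasing_in_intrinsic_clearance(self, a, b):
        ctx = DispersionContext(fu_p=0.0078, r_b=3.95)
        lo, hi = sorted((a, b))
        assert hepatic_availability(hi, ctx) <= hepatic_availability(lo, ctx) + 1e-12

    @given(st.floats(1e-3, 1e3), st.floats(1.0, 5e3))
    @settings(max_examples=100, deadline=None)
    def test_dispersion_between_limits(self, d_n, clint):
        # any finite D_N lies between the parallel-tube and well-stirred limits
        ctx = DispersionContext(fu_p=0.0078, r_b=3.95, d_n=d_n)
        rn = ctx.fu_blood * clint * 60 / 1000 / ctx.q_h
        fh = hepatic_availability(clint, ctx)
        assert math.exp(-rn) - 1e-9 <= fh <= 1.0 / (1.0 + rn) + 1e-9

    def test_availability_in_unit_interval(self, control_ctx):
        for clint in (0.0, 1.0, 100.0, 1e4, 1e7):
            fh = hepatic_availability(clint, control_ctx)
            assert 0.0 < fh <= 1.0


class TestHepaticClearance:
    @pytest.mark.parametrize(
        "clint_all, group, expect",
        [
            (160.4, "control", 74.8),
            (46.2, "control", 21.6),
            (205.3, "repeated", 95.7),
            (168.0, "repeated", 78.4),
        ],
    )
    def test_predicted_values(self, clint_all, group, expect, control_ctx, repeated_ctx):
        ctx = control_ctx if group == "control" else repeated_ctx
        assert predict_clh(clint_all, ctx).clh == pytest.approx(expect, abs=0.2)

    def test_full_availability_means_zero_clearance(self, control_ctx):
        assert clh_from_availability(1.0, control_ctx) == 0.0

    def test_bounded_by_effective_plasma_flow(self, control_ctx):
        clh = predict_clh(1e7, control_ctx).clh
        assert clh <= control_ctx.q_h * control_ctx.r_b * 1000.0

    def test_monotone_increasing_in_intrinsic_clearance(self, control_ctx):
        cls = [predict_clh(c, control_ctx).clh for c in (1, 10, 100, 1000, 1e4)]
        assert all(x < y for x, y in zip(cls, cls[1:]))


class TestScoring:
    def test_fold_error_identity(self):
        assert fold_error(7.0, 7.0) == 1.0

    @pytest.mark.parametrize(
        "pred, obs, expect", [(21.6, 30.02, 0.7195), (74.8, 30.02, 2.4917)]
    )
    def test_fold_error_values(self, pred, obs, expect):
        assert fold_error(pred, obs) == pytest.approx(expect, abs=1e-3)
        assert within_fold(pred, obs, k=3.0)

    def test_aafe_signed_cancellation(self):
        # the signed-log form is a bias measure: symmetric errors cancel
        assert aafe([(2.0, 1.0), (1.0, 2.0)]) == pytest.approx(1.0)

    def test_aafe_single_pair_is_ratio(self):
        assert aafe([(3.0, 4.0)]) == pytest.approx(0.75)

    def test_aafe_absolute_variant_cannot_cancel(self):
        assert aafe([(2.0, 1.0), (1.0, 2.0)], absolute=True) == pytest.approx(2.0)

    def test_aafe_empty_rejected(self):
        with pytest.raises(ValueError):
            aafe([])


class TestReport:
    def test_clearance_table_regeneration(self, control_ctx, repeated_ctx):
        # the six predicted hepatic clearances from printed in vitro inputs
        groups = {
            "control": ExtendedClearanceParams(
                clint_met=160.4, ps_inf_act=44.9, ps_diff=1.3, kpuu_ss=17.3 / 160.4
            ),
            "repeated": ExtendedClearanceParams(
                clint_met=205.3, ps_inf_act=164.3, ps_diff=3.7, kpuu_ss=344.3 / 205.3
            ),
        }
        report = ivive_report(
            groups,
            {"control": control_ctx, "repeated": repeated_ctx},
            observed_cl={"control": 30.02, "repeated": 137.9},
        )
        expected = {
            ("control", 1): 74.8,
            ("control", 2): 21.6,
            ("control", 3): 8.1,
            ("repeated", 1): 95.7,
            ("repeated", 2): 78.4,
            ("repeated", 3): 160.0,
        }
        for (group, method), clh in expected.items():
            row = report[(report.group == group) & (report.method == method)]
            assert row.clh_ml_h_kg.iloc[0] == pytest.approx(clh, abs=0.5)
        assert set(report.columns) >= {"fold_error", "within_3fold"}

    def test_missing_kpuu_emits_blank_row(self, control_ctx):
        groups = {
            "control": ExtendedClearanceParams(clint_met=160.4, ps_inf_act=44.9, ps_diff=1.3)
        }
        report = ivive_report(groups, {"control": control_ctx})
        row3 = report[report.method == 3]
        assert len(row3) == 1 and np.isnan(row3.clh_ml_h_kg.iloc[0])
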