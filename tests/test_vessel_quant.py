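"""Vessel extraction, diameter/velocity estimation, and flow metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivm_microflow.errors import AggregationError
from ivm_microflow.synthetic_data import (
    VesselFieldParams,
    generate_vessel_field,
    render_tube_frame,
)
from ivm_microflow.vessel_quant import (
    MicrocirculationMetrics,
    VesselSegment,
    aggregate_rois,
    compute_bfr,
    compute_tpr,
    estimate_diameter,
    estimate_velocity,
    functional_vessel_density,
    metrics_from_segments,
    quantify_field,
    segment_vessels,
)


def seg(length, diameter=10.0, velocity=100.0, perfused=True, sid=0):
    line = np.array([[0.0, 0.0], [length, 0.0]])
    return VesselSegment(
        segment_id=sid, centerline_um=line, length_um=length,
        diameter_um=diameter, velocity_um_s=velocity, perfused=perfused,
    )


class TestSegmentVessels:
    def test_single_straight_tube_length(self):
        img = render_tube_frame((560, 60), 0.5, (30, 30), (530, 30), 12.0)
        segments = segment_vessels(img[None], 0.5)
        assert len(segments) == 1
        # endpoint localization is good to ~D/4 per end
        assert segments[0].length_um == pytest.approx(500.0, rel=0.012)

    def test_blank_stack_yields_empty_list(self):
        stack = np.full((3, 64, 64), 100.0)
        assert segment_vessels(stack, 0.5) == []

    def test_noisy_multitube_field_recovers_90_percent_length(self):
        params = VesselFieldParams(
            field_size_um=(800.0, 800.0),
            pixel_size_um=1.0,
            n_segments=50,
            diameter_range_um=(6.0, 16.0),
            length_range_um=(100.0, 250.0),
            # single static frame: erythrocyte gaps average out only over
            # time, so structural recovery is tested without perfusion
            perfused_fraction=0.0,
            duration_s=1.0,
            frame_rate_hz=1.0,
            noise_sd=10.0,
        )
        stack, fov = generate_vessel_field(params, seed=17)
        segments = segment_vessels(stack, 1.0)
        total_true = sum(s.length_um for s in fov.segments)
        total_rec = sum(s.length_um for s in segments)
        assert total_rec >= 0.9 * total_true
        assert total_rec <= 1.1 * total_true


class TestEstimateDiameter:
    @pytest.mark.parametrize("true_d", [12.0, 25.0])
    def test_noise_free_fwhm_recovery(self, true_d):
        img = render_tube_frame((560, 120), 0.5, (30, 60), (530, 60), true_d)
        segments = segment_vessels(img[None], 0.5)
        d = estimate_diameter(img[None], segments[0], 0.5)
        assert d == pytest.approx(true_d, abs=0.5)

    def test_rotation_leaves_diameter_unchanged(self):
        img_h = render_tube_frame((480, 80), 0.5, (40, 40), (440, 40), 14.0)
        img_o = render_tube_frame((400, 340), 0.5, (40, 40), (360, 300), 14.0)
        d_h = estimate_diameter(
            img_h[None], segment_vessels(img_h[None], 0.5)[0], 0.5
        )
        d_o = estimate_diameter(
            img_o[None], segment_vessels(img_o[None], 0.5)[0], 0.5
        )
        assert d_h == pytest.approx(d_o, abs=0.5)

    def test_unmeasurable_profile_returns_nan(self):
        # uniform bright image: profile never drops to half maximum
        stack = np.full((1, 120, 120), 900.0)
        s = seg(40.0)
        s.centerline_um = np.array([[10.0, 30.0], [50.0, 30.0]])
        assert math.isnan(estimate_diameter(stack, s, 0.5))


class TestEstimateVelocity:
    def test_gap_train_speed_recovered(self, single_perfused_field):
        params, stack, fov = single_perfused_field
        tru = fov.segments[0]
        v = estimate_velocity(stack, tru, params.pixel_size_um,
                              params.frame_rate_hz)
        assert v == pytest.approx(500.0, rel=0.05)

    def test_static_vessel_is_zero_and_unperfused(self):
        params = VesselFieldParams(
            n_segments=1, perfused_fraction=0.0, noise_sd=0.0,
            diameter_range_um=(12.0, 12.0),
        )
        stack, fov = generate_vessel_field(params, seed=5)
        _, metrics = quantify_field(stack, params.pixel_size_um,
                                    params.frame_rate_hz)
        assert metrics.n_perfused == 0
        assert metrics.vd_cm_per_cm2 == 0.0

    def test_time_reversal_preserves_speed(self, single_perfused_field):
        params, stack, fov = single_perfused_field
        tru = fov.segments[0]
        v_fwd = estimate_velocity(stack, tru, params.pixel_size_um,
                                  params.frame_rate_hz)
        v_rev = estimate_velocity(stack[::-1], tru, params.pixel_size_um,
                                  params.frame_rate_hz)
        assert v_rev == pytest.approx(v_fwd, rel=0.02)


class TestFlowFormulas:
    def test_vd_arithmetic(self):
        # one perfused segment of 0.1 cm (=1000 um) in 0.01 cm^2
        assert functional_vessel_density([seg(1000.0)], 0.01) == pytest.approx(10.0)

    def test_vd_excludes_unperfused(self):
        assert functional_vessel_density(
            [seg(1000.0, perfused=False)], 0.01
        ) == 0.0

    def test_vd_halves_when_area_doubles(self):
        s = [seg(500.0)]
        assert functional_vessel_density(s, 0.02) == pytest.approx(
            functional_vessel_density(s, 0.01) / 2.0
        )

    @pytest.mark.parametrize(
        "d,v,expected",
        [
            (0.0, 500.0, 0.0),
            (10.0, 0.0, 0.0),
            (10.0, 1600.0, math.pi * 25.0 * 1000.0 / 1000.0),   # 78.5398...
            (20.0, 800.0, math.pi * 100.0 * 500.0 / 1000.0),    # 157.0796...
        ],
    )
    def test_bfr_hand_values(self, d, v, expected):
        assert compute_bfr(d, v) == pytest.approx(expected, rel=1e-9)

    @given(
        d=st.floats(min_value=0.0, max_value=60.0),
        v=st.floats(min_value=0.0, max_value=3000.0),
        c=st.floats(min_value=0.1, max_value=5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_bfr_quadratic_in_d_linear_in_v(self, d, v, c):
        base = compute_bfr(d, v)
        assert compute_bfr(c * d, v) == pytest.approx(c * c * base, rel=1e-9, abs=1e-12)
        assert compute_bfr(d, c * v) == pytest.approx(c * base, rel=1e-9, abs=1e-12)

    def test_bfr_rejects_negative(self):
        with pytest.raises(ValueError):
            compute_bfr(-1.0, 100.0)

    def test_tpr_arithmetic_and_empty(self):
        s = seg(100.0, diameter=10.0, velocity=1600.0)
        assert compute_tpr([s], 0.01) == pytest.approx(7853.98, rel=1e-5)
        assert compute_tpr([], 0.01) == 0.0

    def test_tpr_intensive_under_tiling(self):
        segs = [seg(300.0, 12.0, 400.0, sid=0), seg(200.0, 8.0, 250.0, sid=1)]
        single = compute_tpr(segs, 0.01)
        doubled = compute_tpr(segs + segs, 0.02)
        assert doubled == pytest.approx(single)

    def test_unperfused_never_contributes(self):
        live = seg(300.0, 12.0, 400.0)
        dead = seg(900.0, 30.0, 0.0, perfused=False)
        assert compute_tpr([live, dead], 0.01) == compute_tpr([live], 0.01)
        m = metrics_from_segments([live, dead], 0.01)
        assert m.vd_cm_per_cm2 == pytest.approx(300.0 * 1e-4 / 0.01)
        assert m.n_perfused == 1


class TestAggregateRois:
    def _metrics(self, vd):
        return MicrocirculationMetrics(
            vd_cm_per_cm2=vd, mean_diameter_um=10.0, vmean_um_s=300.0,
            bfr_pl_s=20.0, tpr_pl_s_cm2=1000.0,
        )

    def test_mean_across_three_rois(self):
        agg = aggregate_rois(
            {"border_1": self._metrics(10.0), "border_2": self._metrics(20.0),
             "center": self._metrics(30.0)}
        )
        assert agg.vd_cm_per_cm2 == pytest.approx(20.0)

    def test_identical_rois_idempotent(self):
        m = self._metrics(15.0)
        agg = aggregate_rois({"border_1": m, "border_2": m, "center": m})
        assert agg.vd_cm_per_cm2 == m.vd_cm_per_cm2
        assert agg.bfr_pl_s == m.bfr_pl_s

    def test_permutation_invariant(self):
        ms = {"center": self._metrics(30.0), "border_2": self._metrics(20.0),
              "border_1": self._metrics(10.0)}
        a = aggregate_rois(ms)
        b = aggregate_rois(dict(reversed(list(ms.items()))))
        assert a.vd_cm_per_cm2 == b.vd_cm_per_cm2

    def test_missing_roi_named_in_error(self):
        with pytest.raises(AggregationError, match="center"):
            aggregate_rois(
                {"border_1": self._metrics(1.0), "border_2": self._metrics(2.0)}
            )
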