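"""Generator contracts: determinism, preset statistics, rendering fidelity."""

import math

import numpy as np
import pytest

from ivm_microflow.errors import ConfigurationError, GenerationError
from ivm_microflow.synthetic_data import (
    GrowthPreset,
    VesselFieldParams,
    generate_cohort,
    generate_permeability_trace,
    generate_vessel_field,
    get_growth_preset,
    load_presets,
    render_tumor_frame,
)


def make_preset(**kw):
    base = dict(
        tissue="FW",
        cell_line="LnCap",
        n_implanted=15,
        engraft_prob=1.0,
        day7_area_mm2=1.0,
        rel_area_by_day={7: 100.0, 14: 382.0},
        censor_day=None,
        noise_sigma=0.0,
    )
    base.update(kw)
    return GrowthPreset(**base)


class TestGrowthPresets:
    def test_shipped_presets_are_valid_and_monotone(self):
        presets = load_presets()["growth_presets"]
        assert len(presets) == 6
        for key in presets:
            p = get_growth_preset(key)
            days = sorted(p.rel_area_by_day)
            assert p.rel_area_by_day[7] == 100.0
            vals = [p.rel_area_by_day[d] for d in days]
            assert vals == sorted(vals)  # growth never reverses
            assert 0.0 <= p.engraft_prob <= 1.0
            assert p.n_implanted == (15 if p.tissue == "FW" else 20)

    def test_unknown_preset_key_raises(self):
        with pytest.raises(ConfigurationError):
            get_growth_preset("FW:HeLa")

    def test_day7_anchor_enforced(self):
        with pytest.raises(ConfigurationError):
            make_preset(rel_area_by_day={7: 90.0, 14: 382.0})


class TestGenerateCohort:
    def test_noise_free_day14_is_382_percent_of_day7(self):
        obs, _ = generate_cohort(make_preset(), seed=11)
        by_animal = {}
        for o in obs:
            by_animal.setdefault(o.animal_id, {})[o.day] = o.area_mm2
        assert len(by_animal) == 15
        for areas in by_animal.values():
            assert areas[14] == pytest.approx(3.82 * areas[7], rel=1e-12)

    def test_zero_engraftment_probability_excludes_everyone(self):
        obs, truth = generate_cohort(make_preset(engraft_prob=0.0), seed=5)
        assert all(o.status == "excluded_no_engraftment" for o in obs)
        assert not any(a["engrafted"] for a in truth.animals)

    def test_mean_engrafted_count_matches_binomial(self):
        # brute-force Monte-Carlo of the Bernoulli engraftment draws:
        # E[count] = n * p = 15 * 0.93 = 13.95
        p = make_preset(engraft_prob=0.93)
        counts = [
            sum(a["engrafted"] for a in generate_cohort(p, s)[1].animals)
            for s in range(10_000)
        ]
        assert np.mean(counts) == pytest.approx(13.95, abs=0.1)

    def test_censoring_truncates_series(self):
        p = make_preset(
            rel_area_by_day={7: 100.0, 14: 274.0, 21: 730.0}, censor_day=14
        )
        obs, _ = generate_cohort(p, seed=2)
        assert max(o.day for o in obs) == 14
        last = [o for o in obs if o.day == 14]
        assert all(o.status == "censored_fracture" for o in last)

    def test_identical_seed_identical_output(self):
        from ivm_microflow.tumor_quant import observations_to_frame

        p = get_growth_preset("DSC:Du145")
        a, _ = generate_cohort(p, seed=42)
        b, _ = generate_cohort(p, seed=42)
        # frame comparison treats the NaN areas of excluded animals as equal
        assert observations_to_frame(a).equals(observations_to_frame(b))


class TestRenderTumorFrame:
    def test_half_maximum_contour_sits_at_true_radius(self):
        # disk with area exactly 1 mm^2 -> radius 564.19 um
        r = math.sqrt(1.0 / math.pi) * 1000.0
        img = render_tumor_frame(1.0, 4.0, noise_sd=0.0)
        c = (img.shape[0] - 1) / 2.0
        row = img[int(round(c))].astype(float)
        half = (row.max() + row.min()) / 2.0
        width_px = np.sum(row > half)
        assert width_px * 4.0 == pytest.approx(2 * r, abs=8.0)

    def test_zero_area_gives_pure_background(self):
        img = render_tumor_frame(0.0, 8.0, noise_sd=0.0)
        assert np.ptp(img) == 0

    def test_negative_area_rejected(self):
        with pytest.raises(GenerationError):
            render_tumor_frame(-1.0, 8.0)


class TestVesselField:
    def test_rendered_profile_fwhm_matches_true_diameter(self):
        params = VesselFieldParams(
            n_segments=1,
            perfused_fraction=0.0,
            diameter_range_um=(12.0, 12.0),
            noise_sd=0.0,
            duration_s=1.0,
            frame_rate_hz=2.0,
        )
        stack, fov = generate_vessel_field(params, seed=3)
        seg = fov.segments[0]
        img = stack[0].astype(float)
        mid = seg.centerline_um[len(seg.centerline_um) // 2]
        u = seg.centerline_um[-1] - seg.centerline_um[0]
        u = u / np.linalg.norm(u)
        normal = np.array([-u[1], u[0]])
        offs = np.arange(-30.0, 30.01, 0.05)
        pts = mid[None, :] + offs[:, None] * normal[None, :]
        from scipy.ndimage import map_coordinates

        prof = map_coordinates(
            img, [pts[:, 1] / 0.5, pts[:, 0] / 0.5], order=1
        )
        prof = prof - prof.min()
        above = offs[prof > prof.max() / 2.0]
        fwhm = above.max() - above.min()
        assert fwhm == pytest.approx(12.0, abs=params.pixel_size_um)

    def test_empty_field_is_pure_background(self):
        params = VesselFieldParams(
            n_segments=0, noise_sd=0.0, duration_s=1.0, frame_rate_hz=2.0
        )
        stack, fov = generate_vessel_field(params, seed=1)
        assert fov.segments == []
        assert np.ptp(stack) == 0

    def test_perfused_count_is_binomial(self):
        params = VesselFieldParams(
            field_size_um=(2000.0, 2000.0),
            pixel_size_um=4.0,
            n_segments=200,
            diameter_range_um=(8.0, 16.0),
            length_range_um=(60.0, 120.0),
            perfused_fraction=0.5,
            duration_s=1.0,
            frame_rate_hz=1.0,
            noise_sd=0.0,
        )
        _, fov = generate_vessel_field(params, seed=9)
        n_perfused = sum(s.perfused for s in fov.segments)
        # 3 sigma of Binomial(200, 0.5)
        assert abs(n_perfused - 100) <= 3 * math.sqrt(200 * 0.25)

    def test_too_small_field_raises(self):
        params = VesselFieldParams(
            field_size_um=(30.0, 30.0),
            n_segments=2,
            diameter_range_um=(20.0, 20.0),
            noise_sd=0.0,
            duration_s=1.0,
            frame_rate_hz=1.0,
        )
        with pytest.raises(GenerationError):
            generate_vessel_field(params, seed=0)

    def test_unresolvable_diameter_rejected(self):
        with pytest.raises(ConfigurationError):
            VesselFieldParams(pixel_size_um=4.0, diameter_range_um=(6.0, 12.0))

    def test_identical_seed_bit_identical_stack(self):
        params = VesselFieldParams(
            n_segments=2, duration_s=1.0, frame_rate_hz=5.0, noise_sd=3.0
        )
        s1, _ = generate_vessel_field(params, seed=21)
        s2, _ = generate_vessel_field(params, seed=21)
        assert np.array_equal(s1, s2)


class TestPermeabilityTraceGenerator:
    def test_zero_slope_fixed_point_gives_constant_trace(self):
        # P = (1-HT) * (V/S) / K makes the ramp slope exactly zero
        p_fixed = 0.81 * 2.5 / 9.1e3 * 1e-4
        tr = generate_permeability_trace(p_fixed, noise_sd=0.0)
        assert np.ptp(tr.intensities) == pytest.approx(0.0, abs=1e-9)
        assert tr.intensities[0] == tr.I0

    def test_duration_must_cover_two_intervals(self):
        with pytest.raises(ConfigurationError):
            generate_permeability_trace(1e-7, sample_interval_s=400.0)

    def test_sampling_grid(self):
        tr = generate_permeability_trace(1e-7)
        assert tr.times_s[0] == 0.0
        assert tr.times_s[-1] == 600.0
        assert len(tr.times_s) == 21
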