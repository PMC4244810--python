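"""Synthetic-microscope properties: population statistics, growth truth,
mask rendering, determinism."""

import numpy as np
import pytest
from skimage.measure import label as sk_label, regionprops

from microlapse.simulate import (FateRecord, PositionRenderer, SimulationParams,
                                 colony_area_truth, paa_like_params,
                                 render_frame, sample_population,
                                 simulate_experiment)
from tests.conftest import make_record, render_position_stacks


class TestPopulation:
    def test_zero_grower_fraction(self):
        params = SimulationParams(seed=1, grower_fraction=0.0)
        recs = sample_population(params)
        assert recs and all(r.fate in ("elongater", "non_grower") for r in recs)

    def test_default_population_in_reported_ranges(self):
        # 49 fields, 0-14 founders each, 200-500 in total
        params = SimulationParams(seed=2)
        recs = sample_population(params)
        per_field = {}
        for r in recs:
            per_field[r.position] = per_field.get(r.position, 0) + 1
        assert 200 <= len(recs) <= 500
        assert max(per_field.values()) <= 14
        assert set(per_field) <= set(params.position_ids())
        assert len(params.position_ids()) == 49

    def test_fate_fraction_matches_binomial(self):
        from microlapse.simulate import _sample_fates
        params = SimulationParams(seed=3, grower_fraction=0.4)
        rng = np.random.default_rng(3)
        fates = _sample_fates(params, rng, 10_000)
        frac = np.mean([f == "grower" for f in fates])
        se = np.sqrt(0.4 * 0.6 / 10_000)
        assert abs(frac - 0.4) <= 3 * se

    def test_lag_and_mu_distributions(self):
        from scipy.stats import truncnorm
        from microlapse.simulate import _sample_lag, _sample_mu
        params = SimulationParams(seed=4)
        rng = np.random.default_rng(4)
        lags = _sample_lag(params, rng, 10_000)
        mus = _sample_mu(params, rng, 10_000)
        # median of the shifted log-normal is shift + median parameter
        med_expect = params.lag.shift + params.lag.median
        assert np.median(lags) == pytest.approx(med_expect, rel=0.05)
        a = (params.mu.lower - params.mu.mean) / params.mu.sd
        b = (params.mu.upper - params.mu.mean) / params.mu.sd
        tn = truncnorm(a, b, loc=params.mu.mean, scale=params.mu.sd)
        assert np.mean(mus) == pytest.approx(tn.mean(), abs=3 * tn.std() / 100)
        assert np.all((mus >= params.mu.lower) & (mus <= params.mu.upper))

    def test_placement_respects_separation(self):
        params = SimulationParams(seed=6)
        recs = sample_population(params)
        by_pos = {}
        for r in recs:
            by_pos.setdefault(r.position, []).append(r.centroid)
        for pts in by_pos.values():
            for i in range(len(pts)):
                for j in range(i + 1, len(pts)):
                    d = np.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1])
                    assert d >= params.min_separation

    def test_overcrowded_field_raises(self):
        params = SimulationParams(seed=1, field_shape=(64, 64), margin=10,
                                  min_separation=40.0,
                                  founders_per_field_mean=14.0)
        with pytest.raises(ValueError, match="density"):
            sample_population(params)


class TestGrowthTruth:
    def test_time_zero_identity_all_fates(self):
        for fate in ("grower", "elongater", "non_grower"):
            rec = make_record(fate=fate)
            assert colony_area_truth(rec, 0.0) == pytest.approx(rec.a0, rel=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            colony_area_truth(make_record(), -0.5)

    def test_lag_holds_growth_then_releases(self):
        # the adjustment function gives a soft lag: the area stays near A0
        # through mid-lag, sits near 2*A0 at t = lag itself, and is well
        # into exponential expansion a few generations later
        rec = make_record(lag=10.0, mu_max=0.5, ymax=10.34)
        assert colony_area_truth(rec, 5.0) <= 1.10 * rec.a0
        assert colony_area_truth(rec, 10.0) <= 2.2 * rec.a0
        late = colony_area_truth(rec, 10.0 + 3.0 / rec.mu_max)
        assert late > 5 * rec.a0

    def test_fastest_default_grower_plateau_scale(self):
        # mature microcolonies reach ~3.1e4 pixels by 35 h
        params = SimulationParams(seed=8)
        growers = [r for r in sample_population(params) if r.fate == "grower"]
        top = max(colony_area_truth(r, 35.0) for r in growers)
        assert 2.8e4 <= top <= 3.3e4

    def test_non_grower_constant(self):
        rec = make_record(fate="non_grower")
        t = np.linspace(0, 48, 25)
        assert np.allclose(colony_area_truth(rec, t), rec.a0)

    def test_elongater_capped_below_dividing_threshold(self):
        rec = make_record(fate="elongater", elongater_cap=1.8, ramp_hours=6.0)
        areas = colony_area_truth(rec, np.linspace(0, 48, 49))
        assert areas[-1] == pytest.approx(1.8 * rec.a0, rel=1e-6)
        assert np.max(areas) / rec.a0 < 4.0


class TestRendering:
    def test_truth_mask_matches_area_curve_exactly(self, small_params):
        # S-type, centered, no clipping: mask pixel count == round(truth)
        params = small_params.model_copy(update={"field_shape": (360, 360),
                                                 "horizon": 30.0, "dt": 3.0})
        rec = make_record(centroid=(180.0, 180.0), lag=2.0, mu_max=0.45)
        rend = PositionRenderer([rec], params)
        for t in params.frame_times:
            n = int(rend.truth_mask(0, float(t)).sum())
            assert n == round(colony_area_truth(rec, float(t)))

    def test_truth_mask_monotone_for_growers(self, small_params):
        rec = make_record(centroid=(48.0, 48.0), ymax=7.5)
        rend = PositionRenderer([rec], small_params)
        counts = [int(rend.truth_mask(0, float(t)).sum())
                  for t in np.linspace(0, 12, 13)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_non_grower_masks_identical_across_time(self, small_params):
        rec = make_record(fate="non_grower", centroid=(48.0, 48.0))
        rend = PositionRenderer([rec], small_params)
        assert np.array_equal(rend.truth_mask(0, 0.0), rend.truth_mask(0, 12.0))

    def test_elongation_phase_extends_long_axis(self):
        # before lateral expansion the rendered blob elongates ~2-3x in length
        params = SimulationParams(seed=1, field_shape=(200, 200))
        rec = make_record(centroid=(100.0, 100.0), lag=0.0, mu_max=0.3,
                          elongation_factor=2.5, axis_angle=0.3)
        rend = PositionRenderer([rec], params)
        m0 = rend.truth_mask(0, 0.0)
        len0 = regionprops(sk_label(m0))[0].axis_major_length
        # time at which area = 2.5 * a0 (end of the elongation phase)
        t_end = np.log(2.5) / rec.mu_max
        m1 = rend.truth_mask(0, float(t_end))
        len1 = regionprops(sk_label(m1))[0].axis_major_length
        assert 2.0 <= len1 / len0 <= 3.5

    def test_r_type_holes_interior_and_sized(self):
        from scipy.ndimage import binary_fill_holes
        params = SimulationParams(seed=2, field_shape=(420, 420))
        rec = make_record(centroid=(210.0, 210.0), morphology="R",
                          hole_fraction=0.2, ymax=10.0, lag=1.0, mu_max=0.5)
        rend = PositionRenderer([rec], params)
        mask = rend.truth_mask(0, 40.0)
        filled = binary_fill_holes(mask)
        hole_px = int(filled.sum() - mask.sum())
        assert hole_px > 0
        frac = hole_px / filled.sum()
        assert 0.08 <= frac <= 0.3  # near the configured 0.2

    def test_render_determinism_and_channels(self, small_params):
        rec = make_record(centroid=(48.0, 48.0))
        img1, masks1 = render_frame([rec], 6.0, "brightfield", small_params, seed=3)
        img2, masks2 = render_frame([rec], 6.0, "brightfield", small_params, seed=3)
        assert np.array_equal(img1, img2)
        assert np.array_equal(masks1[0], masks2[0])
        with pytest.raises(ValueError):
            render_frame([rec], 6.0, "gfp", small_params)

    def test_pi_channel_lights_up_after_staining(self, small_params):
        rec = make_record(fate="non_grower", centroid=(48.0, 48.0),
                          pi_positive_time=6.0)
        params = small_params.model_copy(deep=True)
        params.intensity.pi_background_sd = 0.0
        rend = PositionRenderer([rec], params)
        before, _ = rend.render(4.0, "pi")
        after, _ = rend.render(8.0, "pi")
        cell = rend.truth_mask(0, 8.0)
        assert before[cell].max() < 20
        assert np.all(after[cell] == params.intensity.pi_positive)

    def test_merge_fixture_masks_overlap(self):
        params = SimulationParams(seed=1, field_shape=(256, 256))
        a = make_record(0, centroid=(128.0, 113.0), lag=1.0, mu_max=0.6)
        b = make_record(1, centroid=(128.0, 143.0), lag=1.0, mu_max=0.6,
                        shape_seed=2)
        rend = PositionRenderer([a, b], params)
        overlaps = [bool((rend.truth_mask(0, t) & rend.truth_mask(1, t)).any())
                    for t in np.arange(0.0, 30.0)]
        assert not overlaps[0] and any(overlaps)

    def test_mixed_position_records_rejected(self, small_params):
        a = make_record(0, position="r0c0")
        b = make_record(1, position="r0c1")
        with pytest.raises(ValueError):
            PositionRenderer([a, b], small_params)


class TestExperiment:
    def test_simulate_experiment_layout_and_determinism(self, small_params):
        ds, recs = simulate_experiment(small_params)
        n_t = len(small_params.frame_times)
        assert len(ds.positions) == 4
        assert ds.frame_times[0] == 0.0
        assert len(ds.frames) == 4 * n_t * 2
        ds2, recs2 = simulate_experiment(small_params)
        assert [r.to_dict() for r in recs] == [r.to_dict() for r in recs2]
        assert all(np.array_equal(ds.frames[k], ds2.frames[k]) for k in ds.frames)

    def test_fate_record_invariants_enforced(self):
        with pytest.raises(ValueError):
            make_record(fate="grower", mu_max=0.0)
        with pytest.raises(ValueError):
            make_record(morphology="S", hole_fraction=0.1)
        with pytest.raises(ValueError):
            make_record(hole_fraction=0.5, morphology="R")
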