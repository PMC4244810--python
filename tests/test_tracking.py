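"""Lineage linking, merge censoring and founder classification."""

import numpy as np
import pytest

from microlapse.config import AnalysisConfig
from microlapse.segmentation import measure_objects, segment_brightfield
from microlapse.simulate import PositionRenderer, SimulationParams
from microlapse.tracking import (build_growth_series, classify_founders,
                                 link_frames, register_founders)
from tests.conftest import make_record


def _segment_stack(bf, cfg):
    return [segment_brightfield(f, cfg) for f in bf]


def _noise_free(params):
    p = params.model_copy(deep=True)
    p.intensity.background_sd = 0.0
    p.intensity.pi_background_sd = 0.0
    return p


class TestRegistration:
    def test_empty_mask_empty_registry(self, cfg):
        founders = register_founders(np.zeros((32, 32), np.int32), [])
        assert founders == []

    def test_fourteen_founders_centroids_within_2px(self, cfg):
        # densest field reported: 14 cells at time zero
        params = _noise_free(SimulationParams(seed=1, field_shape=(512, 512),
                                              min_separation=40.0))
        recs = [make_record(i, centroid=(70.0 + 55.0 * (i // 4), 70.0 + 105.0 * (i % 4)),
                            shape_seed=i) for i in range(14)]
        rend = PositionRenderer(recs, params)
        img, _ = rend.render(0.0, "brightfield")
        mask = segment_brightfield(img, cfg)
        founders = register_founders(mask, measure_objects(mask, np.zeros_like(img, float), cfg))
        assert len(founders) == 14
        truth = sorted(r.centroid for r in recs)
        for f, t in zip(founders, truth):
            assert abs(f.centroid[0] - t[0]) <= 2 and abs(f.centroid[1] - t[1]) <= 2

    def test_id_assignment_deterministic(self, cfg):
        params = _noise_free(SimulationParams(seed=2, field_shape=(256, 256)))
        recs = [make_record(i, centroid=c, shape_seed=i)
                for i, c in enumerate([(60.0, 60.0), (60.0, 180.0), (180.0, 120.0)])]
        rend = PositionRenderer(recs, params)
        img, _ = rend.render(0.0, "brightfield")
        m = segment_brightfield(img, cfg)
        f1 = register_founders(m, measure_objects(m, np.zeros_like(img, float), cfg))
        f2 = register_founders(m, measure_objects(m, np.zeros_like(img, float), cfg))
        assert [f.founder_id for f in f1] == [f.founder_id for f in f2]
        assert [f.centroid for f in f1] == [f.centroid for f in f2]


class TestLinking:
    def test_single_colony_spans_all_frames(self, cfg):
        params = _noise_free(SimulationParams(seed=3, field_shape=(300, 300),
                                              horizon=24.0, dt=2.0))
        rec = make_record(centroid=(150.0, 150.0), lag=1.0, mu_max=0.4)
        rend = PositionRenderer([rec], params)
        bf = [rend.render(float(t), "brightfield")[0] for t in params.frame_times]
        masks = _segment_stack(bf, cfg)
        (lin,) = link_frames(masks)
        assert lin.censored_at_frame is None and lin.lost_at_frame is None
        series = build_growth_series(lin, params.frame_times)
        assert len(series.times) == len(params.frame_times)
        assert np.all(np.diff(series.areas) >= 0)

    def test_non_grower_constant_series(self, cfg):
        params = _noise_free(SimulationParams(seed=4, field_shape=(128, 128),
                                              horizon=12.0, dt=2.0))
        rec = make_record(fate="non_grower", centroid=(64.0, 64.0))
        rend = PositionRenderer([rec], params)
        bf = [rend.render(float(t), "brightfield")[0] for t in params.frame_times]
        (lin,) = link_frames(_segment_stack(bf, cfg))
        areas = lin.observed_areas()
        assert len(set(areas)) == 1

    def test_merge_censors_both_at_contact_frame(self, cfg):
        """Two colonies seeded to collide: censoring at first mask contact,
        and pre-merge areas identical to a solo (no-merge) control render."""
        from scipy.ndimage import label as ndi_label
        params = _noise_free(SimulationParams(seed=5, field_shape=(300, 300),
                                              horizon=30.0, dt=1.0))
        a = make_record(0, centroid=(150.0, 130.0), lag=1.0, mu_max=0.5, shape_seed=1)
        b = make_record(1, centroid=(150.0, 170.0), lag=1.0, mu_max=0.5, shape_seed=2)
        rend = PositionRenderer([a, b], params)
        times = params.frame_times

        # truth contact frame: first frame where the union is one component
        contact = None
        for i, t in enumerate(times):
            union = rend.truth_mask(0, float(t)) | rend.truth_mask(1, float(t))
            if ndi_label(union, structure=np.ones((3, 3)))[1] == 1:
                contact = i
                break
        assert contact is not None and contact > 0

        bf = [rend.render(float(t), "brightfield")[0] for t in times]
        lins = link_frames(_segment_stack(bf, cfg))
        assert all(l.censored_at_frame == contact for l in lins)
        assert lins[0].merged_with == [1] and lins[1].merged_with == [0]

        # solo control: founder a alone, same shape seed -> identical masks
        rend_a = PositionRenderer([a], params)
        bf_a = [rend_a.render(float(t), "brightfield")[0] for t in times]
        (solo,) = link_frames(_segment_stack(bf_a, cfg))
        assert lins[0].observed_areas() == solo.observed_areas()[:contact]

    def test_colony_hitting_merged_blob_is_censored(self, cfg):
        # A and B merge early; C later touches the merged blob and must be
        # censored too, not silently absorb it.
        params = _noise_free(SimulationParams(seed=6, field_shape=(360, 360),
                                              horizon=36.0, dt=2.0))
        a = make_record(0, centroid=(180.0, 120.0), lag=0.5, mu_max=0.6, shape_seed=1)
        b = make_record(1, centroid=(180.0, 155.0), lag=0.5, mu_max=0.6, shape_seed=2)
        c = make_record(2, centroid=(180.0, 240.0), lag=0.5, mu_max=0.6, shape_seed=3)
        rend = PositionRenderer([a, b, c], params)
        bf = [rend.render(float(t), "brightfield")[0] for t in params.frame_times]
        lins = link_frames(_segment_stack(bf, cfg))
        assert lins[0].censored_at_frame is not None
        assert lins[2].censored_at_frame is not None
        assert lins[2].censored_at_frame >= lins[0].censored_at_frame

    def test_censoring_safety_under_truncation(self, cfg):
        # areas before the merge are identical whether or not later frames
        # (and hence the merge) exist at all
        params = _noise_free(SimulationParams(seed=7, field_shape=(300, 300),
                                              horizon=30.0, dt=1.0))
        a = make_record(0, centroid=(150.0, 130.0), lag=1.0, mu_max=0.5, shape_seed=1)
        b = make_record(1, centroid=(150.0, 170.0), lag=1.0, mu_max=0.5, shape_seed=2)
        rend = PositionRenderer([a, b], params)
        bf = [rend.render(float(t), "brightfield")[0] for t in params.frame_times]
        masks = _segment_stack(bf, cfg)
        full = link_frames(masks)
        cut = full[0].censored_at_frame
        trunc = link_frames(masks[:cut])
        assert trunc[0].censored_at_frame is None
        assert trunc[0].observed_areas() == full[0].observed_areas()

    def test_frame_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            link_frames([np.ones((8, 8), np.int32), np.ones((9, 9), np.int32)],
                        founders=[], measures_t0=[])


class TestClassification:
    def _classify(self, params, recs, cfg):
        rend = PositionRenderer(recs, params)
        bf = [rend.render(float(t), "brightfield")[0] for t in params.frame_times]
        pi0 = rend.render(0.0, "pi")[0]
        masks = _segment_stack(bf, cfg)
        founders = register_founders(
            masks[0], measure_objects(masks[0], pi0.astype(float), cfg))
        lins = link_frames(masks, founders=founders)
        return classify_founders(lins, founders, cfg), founders

    def test_constant_area_is_non_dividing(self, cfg):
        params = _noise_free(SimulationParams(seed=8, field_shape=(128, 128),
                                              horizon=12.0, dt=2.0))
        cls, _ = self._classify(params, [make_record(fate="non_grower",
                                                     centroid=(64.0, 64.0))], cfg)
        assert cls[0].label_class == "non_dividing"
        assert cls[0].max_area_ratio == pytest.approx(1.0)

    def test_elongater_stays_non_dividing(self, cfg):
        # the elongater cap (<= 2x area) sits below the 4x dividing threshold
        params = _noise_free(SimulationParams(seed=9, field_shape=(128, 128),
                                              horizon=24.0, dt=2.0))
        rec = make_record(fate="elongater", centroid=(64.0, 64.0),
                          elongater_cap=2.0, ramp_hours=6.0)
        cls, _ = self._classify(params, [rec], cfg)
        assert cls[0].label_class == "non_dividing"
        assert cls[0].max_area_ratio < 4.0

    def test_grower_reaching_plateau_is_dividing(self, cfg):
        params = _noise_free(SimulationParams(seed=10, field_shape=(460, 460),
                                              horizon=40.0, dt=2.0))
        rec = make_record(centroid=(230.0, 230.0), lag=1.0, mu_max=0.5,
                          ymax=10.34)  # ~31000 px from ~30 px
        cls, _ = self._classify(params, [rec], cfg)
        assert cls[0].label_class == "dividing"
        assert cls[0].max_area_ratio > 100

    def test_fate_recovery_on_noise_free_experiment(self, cfg):
        # >= 99% of founders classified to their ground-truth fate
        from microlapse.pipeline import simulate_and_analyze
        params = _noise_free(SimulationParams(
            seed=11, grid_shape=(2, 2), field_shape=(512, 512), horizon=30.0,
            dt=3.0, founders_per_field_mean=4.0, grower_fraction=0.6))
        summary, table, records = simulate_and_analyze(params, cfg)
        truth = {}
        by_pos: dict[str, list] = {}
        for r in records:
            by_pos.setdefault(r.position, []).append(r)
        for pos, recs in by_pos.items():
            for i, r in enumerate(sorted(recs, key=lambda r: r.centroid)):
                truth[f"{pos}:{i}"] = r.fate
        assert len(table) == len(records)
        hits = sum((row.label_class == "dividing") == (truth[row.founder_id] == "grower")
                   for row in table.itertuples())
        assert hits / len(table) >= 0.99
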