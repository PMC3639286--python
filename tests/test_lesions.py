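"""Lesion detection, sizing, enhancement classification, tracking."""

import numpy as np
import pytest

from metsperf.errors import RegionError
from metsperf.geometry import AcquisitionGeometry
from metsperf.lesions import (LesionRecord, LesionTrack, assign_region,
                              classify_enhancement, detect_lesions,
                              match_lesions)
from metsperf.phantom import build_anatomy, seed_lesions, simulate_mri, week5_preset

GEO = AcquisitionGeometry()


def _synthetic_slice(lesion_px, value=1.5, shape=(64, 64)):
    """Uniform brain disc at 1.0 with given lesion pixels set to ``value``."""
    img = np.full((*shape, 1), 0.05)
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    brain = (rows - shape[0] / 2) ** 2 + (cols - shape[1] / 2) ** 2 <= (shape[0] * 0.45) ** 2
    img[..., 0][brain] = 1.0
    for r, c in lesion_px:
        img[r, c, 0] = value
    return img, brain[..., None]


class TestDetection:
    def test_single_lesion_count_and_area(self):
        # a 15-pixel blob at 78 um: area = 15 * 0.078^2 = 0.0913 mm^2
        px = [(30 + dr, 30 + dc) for dr in range(3) for dc in range(5)]
        img, mask = _synthetic_slice(px)
        recs = detect_lesions(img, mask, GEO)
        assert len(recs) == 1
        assert recs[0].area_mm2 == pytest.approx(15 * 0.078 ** 2, rel=1e-9)
        assert recs[0].area_mm2 == pytest.approx(0.0913, abs=5e-4)

    def test_subresolution_lesion_ignored(self):
        # 3 px -> equivalent diameter ~ 2 px = 156 um, below the 310 um floor
        img, mask = _synthetic_slice([(30, 30), (30, 31), (31, 30)])
        assert detect_lesions(img, mask, GEO) == []

    def test_clean_image_yields_nothing(self):
        img, mask = _synthetic_slice([])
        assert detect_lesions(img, mask, GEO) == []

    def test_empty_mask_raises(self):
        img, mask = _synthetic_slice([])
        with pytest.raises(ValueError):
            detect_lesions(img, np.zeros_like(mask), GEO)

    def test_zero_noise_phantom_perfect_recall_no_false_positives(self, anatomy):
        preset = week5_preset(anat_noise_sd=0.0)
        lesions = seed_lesions(anatomy, preset, week=5, seed=21, n_lesions=40)
        img = simulate_mri(anatomy, lesions, preset, "T2w", seed=0)
        recs = detect_lesions(img, anatomy.brain_mask, GEO)
        assert len(recs) == len(lesions)
        truth = {(l.slice_index, round(l.centroid[0]), round(l.centroid[1]))
                 for l in lesions}
        found = {(r.slice_index, round(r.centroid[0]), round(r.centroid[1]))
                 for r in recs}
        assert found == truth

    def test_area_median_relative_error_under_10pct(self, anatomy):
        """Measured in-plane areas are unbiased at default contrast/noise."""
        preset = week5_preset()
        errs = []
        for s in range(10):
            lesions = seed_lesions(anatomy, preset, week=5, seed=300 + s,
                                   n_lesions=50)
            img = simulate_mri(anatomy, lesions, preset, "T2w", seed=400 + s)
            recs = detect_lesions(img, anatomy.brain_mask, GEO)
            by_key = {}
            for l in lesions:
                by_key[(l.slice_index, round(l.centroid[0]), round(l.centroid[1]))] = l
            for r in recs:
                l = by_key.get((r.slice_index, round(r.centroid[0]),
                                round(r.centroid[1])))
                if l is not None:
                    errs.append(abs(r.area_mm2 - l.area_mm2) / l.area_mm2)
        assert len(errs) > 400
        assert np.median(errs) < 0.10


class TestEnhancement:
    def _record(self, px, s=0):
        rows = np.array([p[0] for p in px])
        cols = np.array([p[1] for p in px])
        return LesionRecord(id=0, animal="a0", week=5, slice_index=s,
                            rows=rows, cols=cols, area_mm2=0.1,
                            centroid=(rows.mean(), cols.mean()))

    def test_isointense_lesion_classed_none(self):
        px = [(30 + dr, 20 + dc) for dr in range(4) for dc in range(4)]
        img, _ = _synthetic_slice(px, value=1.0)
        cls, frac = classify_enhancement(self._record(px), img, midline=32)
        assert cls == "none" and frac == 0.0

    def test_fully_enhancing_lesion(self):
        px = [(30 + dr, 20 + dc) for dr in range(4) for dc in range(4)]
        img, _ = _synthetic_slice(px, value=1.4)
        cls, frac = classify_enhancement(self._record(px), img, midline=32)
        assert cls == "full" and frac == 1.0

    def test_partial_enhancement_fraction(self):
        px = [(30 + dr, 20 + dc) for dr in range(4) for dc in range(4)]
        img, _ = _synthetic_slice(px[:8], value=1.4)   # half the lesion enhances
        cls, frac = classify_enhancement(self._record(px), img, midline=32)
        assert cls == "partial" and frac == pytest.approx(0.5)

    def test_missing_reference_deferred(self):
        px = [(30, 2), (30, 3)]
        img, _ = _synthetic_slice(px, value=1.4, shape=(64, 64))
        cls, _ = classify_enhancement(self._record(px), img, midline=2)
        assert cls == "deferred"

    def test_phantom_truth_classes_recovered_at_zero_noise(self, anatomy):
        preset = week5_preset(anat_noise_sd=0.0)
        lesions = seed_lesions(anatomy, preset, week=5, seed=31, n_lesions=60)
        t2 = simulate_mri(anatomy, lesions, preset, "T2w", seed=0)
        t1 = simulate_mri(anatomy, lesions, preset, "T1w_post", seed=0)
        recs = detect_lesions(t2, anatomy.brain_mask, GEO)
        all_masks = np.zeros(t1.shape, bool)
        for r in recs:
            all_masks[r.rows, r.cols, r.slice_index] = True
        truth = {(l.slice_index, round(l.centroid[0]), round(l.centroid[1])): l
                 for l in lesions}
        checked = 0
        for r in recs:
            l = truth[(r.slice_index, round(r.centroid[0]), round(r.centroid[1]))]
            cls, _ = classify_enhancement(r, t1, int(anatomy.midline[r.slice_index]),
                                          exclude_masks=all_masks)
            if cls != "deferred":
                assert cls == l.enh_class
                checked += 1
        assert checked >= 50


class TestRegionAssignment:
    def _anatomy_stub(self):
        geo = AcquisitionGeometry(matrix=64, dsc_matrix=32, n_slices=2,
                                  n_dsc_slices=1)
        from metsperf.phantom import BrainLabelMap
        labels = np.zeros((64, 64, 2), np.int16)
        labels[:, :32, :] = 1           # cortex left
        labels[:, 32:, :] = 4           # hippocampus right
        return BrainLabelMap(labels=labels, midline=np.array([32, 32]),
                             geometry=geo)

    def _rec(self, px):
        rows = np.array([p[0] for p in px])
        cols = np.array([p[1] for p in px])
        return LesionRecord(id=0, animal="a0", week=5, slice_index=0,
                            rows=rows, cols=cols, area_mm2=0.1,
                            centroid=(rows.mean(), cols.mean()))

    def test_fully_inside(self):
        rec = self._rec([(10, c) for c in range(5, 10)])
        assert assign_region(rec, self._anatomy_stub()) == 1

    def test_majority_rule(self):
        px = [(10, c) for c in range(27, 32)] + [(11, c) for c in range(32, 35)]
        rec = self._rec(px)                         # 5 cortex vs 3 hippocampus
        assert assign_region(rec, self._anatomy_stub()) == 1

    def test_tie_broken_by_centroid(self):
        px = [(10, c) for c in range(30, 32)] + [(10, c) for c in range(32, 34)]
        rec = self._rec(px)
        rec.centroid = (10.0, 33.0)                 # centroid in hippocampus
        assert assign_region(rec, self._anatomy_stub()) == 4

    def test_background_lesion_raises(self):
        anatomy = self._anatomy_stub()
        anatomy.labels[:, :, :] = 0
        with pytest.raises(RegionError):
            assign_region(self._rec([(1, 1)]), anatomy)


class TestTracking:
    def _rec(self, rid, centroid, s=0, week=3):
        return LesionRecord(id=rid, animal="a0", week=week, slice_index=s,
                            rows=np.array([int(centroid[0])]),
                            cols=np.array([int(centroid[1])]),
                            area_mm2=0.1, centroid=centroid)

    def test_identical_centroids_matched(self):
        tracks, log = match_lesions([self._rec(0, (10.0, 10.0))],
                                    [self._rec(0, (10.0, 10.0), week=4)], GEO)
        assert len(tracks) == 1 and tracks[0].weeks == [3, 4]
        assert log == []

    def test_distant_lesions_start_new_tracks(self):
        r_px = 0.5 / GEO.pixel_size_mm
        tracks, log = match_lesions([self._rec(0, (10.0, 10.0))],
                                    [self._rec(0, (10.0, 10.0 + 2 * r_px), week=4)],
                                    GEO)
        assert len(tracks) == 2
        assert all(len(t.weeks) == 1 for t in tracks)
        assert len(log) == 1

    def test_contested_match_goes_to_nearest(self):
        a = [self._rec(0, (10.0, 10.0)), self._rec(1, (10.0, 12.0))]
        b = [self._rec(0, (10.0, 11.6), week=4)]
        tracks, log = match_lesions(a, b, GEO)
        two_week = [t for t in tracks if len(t.weeks) == 2]
        assert len(two_week) == 1 and two_week[0].record_ids[0] == 1
        assert any("unmatched" in line for line in log)

    def test_track_week_ordering_enforced(self):
        with pytest.raises(ValueError):
            LesionTrack(track_id=0, weeks=[4, 3], record_ids=[0, 1])
        with pytest.raises(ValueError):
            LesionTrack(track_id=0, weeks=[3, 3], record_ids=[0, 1])
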