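import itertools
import math

import numpy as np
import pytest

from pigparts.core import FrameAnnotation, PartType, PigAnnotation, Point2D
from pigparts.decoder import (AssociationMode, DecoderConfig, PartDetections,
                              association_distance, build_distance_matrix, decode,
                              detect_peaks, form_instances, hungarian_assign,
                              sample_association, smooth_maps, subpixel_refine)
from pigparts.encoder import encode_frame
from pigparts.matching import annotation_to_instances, cross_check_match
from pigparts.scenes import round_trip_frames


class TestSmoothing:
    def test_constant_preserved(self):
        maps = np.full((16, 20, 30), 0.7)
        np.testing.assert_allclose(smooth_maps(maps), maps)

    def test_impulse_becomes_plateau(self):
        maps = np.zeros((16, 21, 21))
        maps[3, 10, 10] = 1.0
        sm = smooth_maps(maps)
        np.testing.assert_allclose(sm[3, 8:13, 8:13], 1.0 / 25.0)
        assert sm[3, 10, 14] == 0.0

    def test_linear_ramp_interior_preserved(self):
        ramp = np.tile(np.arange(30.0), (20, 1))
        maps = np.broadcast_to(ramp, (16, 20, 30)).copy()
        sm = smooth_maps(maps)
        np.testing.assert_allclose(sm[:, 5:15, 5:25], maps[:, 5:15, 5:25])


class TestPeaks:
    CFG = DecoderConfig(detection_threshold=0.25)

    def test_zero_map_no_peaks(self):
        assert detect_peaks(np.zeros((50, 50)), self.CFG) == []

    def test_single_gaussian_peak(self):
        yy, xx = np.mgrid[0:100, 0:120]
        m = np.exp(-((xx - 60) ** 2 + (yy - 40) ** 2) / (2 * 8.0 ** 2))
        assert detect_peaks(m, self.CFG) == [(60, 40)]

    def test_two_kernels_match_exhaustive_scan(self):
        yy, xx = np.mgrid[0:80, 0:120]
        m = np.maximum(
            np.exp(-((xx - 30) ** 2 + (yy - 40) ** 2) / (2 * 6.0 ** 2)),
            np.exp(-((xx - 60) ** 2 + (yy - 40) ** 2) / (2 * 6.0 ** 2)))
        got = set(detect_peaks(m, self.CFG))
        # independent oracle: brute-force windowed scan
        expected = set()
        w = self.CFG.peak_window // 2
        for y in range(m.shape[0]):
            for x in range(m.shape[1]):
                if m[y, x] < 0.25:
                    continue
                window = m[max(0, y - w):y + w + 1, max(0, x - w):x + w + 1]
                if m[y, x] >= window.max():
                    expected.add((x, y))
        assert got == expected == {(30, 40), (60, 40)}

    def test_plateau_deduplicated_lexicographically(self):
        m = np.zeros((40, 40))
        m[20:22, 10:13] = 0.9  # 2x3 tied plateau
        assert detect_peaks(m, self.CFG) == [(10, 20)]


class TestSubpixel:
    def test_symmetric_stays_integer(self):
        m = np.array([[0, 0, 0], [0.5, 1.0, 0.5], [0, 0, 0]]).T
        pt = subpixel_refine(m, (1, 1))
        assert pt.x == 1.0

    def test_parabola_vertex(self):
        m = np.zeros((3, 3))
        m[1, 0], m[1, 1], m[1, 2] = 0.5, 1.0, 0.9
        pt = subpixel_refine(m, (1, 1))
        assert pt.x == pytest.approx(1.0 + (0.5 - 0.9) / (2 * (0.5 - 2.0 + 0.9)))
        assert pt.x == pytest.approx(1 + 1.0 / 3.0)

    def test_border_peak_unrefined(self):
        m = np.zeros((5, 5))
        m[0, 0] = 1.0
        pt = subpixel_refine(m, (0, 0))
        assert (pt.x, pt.y) == (0.0, 0.0)

    def test_non_negative_curvature_guard(self):
        m = np.zeros((3, 5))
        m[1] = [0.0, 1.0, 1.0, 1.0, 0.0]  # flat top: curvature 0 at center
        pt = subpixel_refine(m, (2, 1))
        assert pt.x == 2.0


class TestAssociationSampling:
    def test_constant_offset_points_to_partner(self):
        assoc = np.zeros((12, 100, 100))
        assoc[8] = -30.0  # s->t x offset
        est = sample_association(assoc, Point2D(50.0, 50.0), (8, 9))
        assert (est.x, est.y) == (80.0, 50.0)

    def test_zero_offset_returns_source(self):
        assoc = np.zeros((12, 50, 50))
        est = sample_association(assoc, Point2D(20.5, 30.25), (0, 1))
        assert (est.x, est.y) == (20.5, 30.25)

    def test_bilinear_between_columns(self):
        assoc = np.zeros((12, 20, 30))
        assoc[8, :, 10] = 10.0
        assoc[8, :, 11] = 20.0
        est = sample_association(assoc, Point2D(10.5, 5.0), (8, 9))
        assert est.x == pytest.approx(10.5 - 15.0)

    @pytest.mark.parametrize("fe,be,expected", [(0, 0, 0.0), (4, 2, 3.0)])
    def test_association_distance(self, fe, be, expected):
        p, q = Point2D(0.0, 0.0), Point2D(100.0, 0.0)
        p_to_q = Point2D(100.0 + fe, 0.0)
        q_to_p = Point2D(0.0, be)
        assert association_distance(p, p_to_q, q, q_to_p) == pytest.approx(expected)
        # symmetry under swapping roles
        assert association_distance(q, q_to_p, p, p_to_q) == pytest.approx(expected)


class TestDistanceMatrix:
    def test_exact_encoding_gives_zero(self, single_pig_frame):
        maps = encode_frame(single_pig_frame)
        from pigparts.decoder import detect_parts

        parts = detect_parts(maps.part_maps, DecoderConfig())
        mat = build_distance_matrix(parts[PartType.SHOULDER], parts[PartType.TAIL],
                                    maps.assoc_maps, (PartType.SHOULDER, PartType.TAIL))
        assert mat.shape == (1, 1)
        assert mat[0, 0] == pytest.approx(0.0, abs=0.2)

    def test_empty_parts_empty_matrix(self):
        empty = PartDetections()
        one = PartDetections(points=[Point2D(5.0, 5.0)], peaks=[1.0])
        mat = build_distance_matrix(empty, one, np.zeros((12, 10, 10)),
                                    (PartType.SHOULDER, PartType.TAIL))
        assert mat.shape == (0, 1)
        assert hungarian_assign(mat) == []

    def test_entries_match_scalar_recomputation(self):
        rng = np.random.default_rng(5)
        assoc = rng.normal(0.0, 5.0, size=(12, 60, 60))
        ps = PartDetections(points=[Point2D(*rng.uniform(5, 50, 2)) for _ in range(3)],
                            peaks=[1.0] * 3)
        qs = PartDetections(points=[Point2D(*rng.uniform(5, 50, 2)) for _ in range(4)],
                            peaks=[1.0] * 4)
        mat = build_distance_matrix(ps, qs, assoc, (PartType.SHOULDER, PartType.TAIL))
        for i, p in enumerate(ps.points):
            for j, q in enumerate(qs.points):
                fwd = sample_association(assoc, p, (8, 9))
                bwd = sample_association(assoc, q, (10, 11))
                expected = 0.5 * (math.hypot(fwd.x - q.x, fwd.y - q.y)
                                  + math.hypot(bwd.x - p.x, bwd.y - p.y))
                assert mat[i, j] == pytest.approx(expected)


class TestHungarian:
    def test_diagonal_preferred(self):
        assert set(hungarian_assign(np.array([[1.0, 10.0], [10.0, 1.0]]))) == {(0, 0), (1, 1)}

    def test_singleton(self):
        assert hungarian_assign(np.array([[7.0]])) == [(0, 0)]

    def test_matches_brute_force_minimum(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n, m = rng.integers(1, 6, size=2)
            d = rng.uniform(0, 10, size=(n, m))
            got = sum(d[i, j] for i, j in hungarian_assign(d))
            k = int(min(n, m))
            mat = d if n <= m else d.T
            best = min(sum(mat[i, c] for i, c in enumerate(cols))
                       for cols in itertools.permutations(range(mat.shape[1]), k))
            assert got == pytest.approx(best)


class TestInstances:
    def _parts(self, shoulders, tails, lears=(), rears=()):
        def pd(pts):
            return PartDetections(points=[Point2D(*p) for p in pts], peaks=[0.9] * len(pts))

        return {PartType.SHOULDER: pd(shoulders), PartType.TAIL: pd(tails),
                PartType.LEFT_EAR: pd(lears), PartType.RIGHT_EAR: pd(rears)}

    def test_two_pairs_two_instances(self):
        parts = self._parts([(10, 10), (50, 50)], [(30, 10), (70, 50)])
        out = form_instances(parts, st_pairs=[(0, 0), (1, 1)], ls_pairs=[], rs_pairs=[])
        assert len(out) == 2
        assert all(i.confidence == pytest.approx(0.9) for i in out.instances)

    def test_lone_parts_never_form_instances(self):
        parts = self._parts([(10, 10)], [])
        out = form_instances(parts, st_pairs=[], ls_pairs=[], rs_pairs=[])
        assert len(out) == 0

    def test_ear_to_instanceless_shoulder_dropped(self):
        parts = self._parts([(10, 10), (90, 90)], [(30, 10)], lears=[(88, 80)])
        # shoulder 1 has no tail partner; its ear assignment must vanish
        out = form_instances(parts, st_pairs=[(0, 0)], ls_pairs=[(0, 1)], rs_pairs=[])
        assert len(out) == 1
        assert out.instances[0].left_ear is None


class TestDecode:
    def test_empty_frame_decodes_empty(self):
        maps = encode_frame(FrameAnnotation(image_size=(64, 64)))
        assert len(decode(maps)) == 0

    def test_round_trip_five_pigs(self):
        frame = round_trip_frames(1, seed=7, n_pigs_range=(5, 5))[0]
        dets = decode(encode_frame(frame))
        rep = cross_check_match(annotation_to_instances(frame), dets.instances)
        assert rep.tp == 5 and rep.fp == 0

    def test_detection_count_monotone_in_threshold(self, two_pig_frame):
        maps = encode_frame(two_pig_frame)
        counts = [len(decode(maps, DecoderConfig(detection_threshold=t)))
                  for t in (0.1, 0.5, 0.9, 0.99)]
        assert counts == sorted(counts, reverse=True)

    def test_translation_equivariance(self):
        frame = round_trip_frames(1, seed=3, n_pigs_range=(3, 3))[0]
        dx, dy = 7, -5
        shifted = FrameAnnotation(
            image_size=frame.image_size,
            pigs=[PigAnnotation(
                shoulder=Point2D(p.shoulder.x + dx, p.shoulder.y + dy),
                tail=Point2D(p.tail.x + dx, p.tail.y + dy),
                left_ear=None if p.left_ear is None else Point2D(p.left_ear.x + dx, p.left_ear.y + dy),
                right_ear=None if p.right_ear is None else Point2D(p.right_ear.x + dx, p.right_ear.y + dy),
                instance_id=p.instance_id) for p in frame.pigs])
        d0 = decode(encode_frame(frame))
        d1 = decode(encode_frame(shifted))
        assert len(d0) == len(d1)
        s0 = sorted((i.shoulder.x, i.shoulder.y) for i in d0.instances)
        s1 = sorted((i.shoulder.x, i.shoulder.y) for i in d1.instances)
        for (x0, y0), (x1, y1) in zip(s0, s1):
            assert x1 - x0 == pytest.approx(dx, abs=1e-6)
            assert y1 - y0 == pytest.approx(dy, abs=1e-6)
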