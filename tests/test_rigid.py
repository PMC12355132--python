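"""Keypoints, matching, robust similarity fitting and serial chaining."""

import numpy as np
import pytest

from histo25d.image import SectionImage
from histo25d.rigid import (
    DegenerateFitError,
    InsufficientMatchesError,
    KeypointSet,
    detect_keypoints,
    estimate_similarity,
    match_keypoints,
    register_stack_serial,
)
from histo25d.transforms import SimilarityTransform2D, transform_points


def _random_keypoints(rng, m=40, d=16):
    return KeypointSet(positions=rng.random((m, 2)) * 200,
                       descriptors=rng.normal(size=(m, d)))


class TestDetect:
    def test_constant_image_yields_no_keypoints(self):
        img = SectionImage(np.full((64, 64, 3), 80, dtype=np.uint8))
        assert len(detect_keypoints(img)) == 0

    def test_phantom_section_yields_many_keypoints(self, small_stack):
        kp = detect_keypoints(small_stack.sections[0])
        assert len(kp) > 50

    def test_detection_is_deterministic(self, small_stack):
        a = detect_keypoints(small_stack.sections[1])
        b = detect_keypoints(small_stack.sections[1])
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.descriptors, b.descriptors)

    def test_mask_restricts_positions(self, small_stack):
        truth = small_stack.tissue_truth[0]
        kp = detect_keypoints(small_stack.sections[0], mask=truth)
        xs = kp.positions[:, 0].astype(int)
        ys = kp.positions[:, 1].astype(int)
        assert truth[ys, xs].all()


class TestMatch:
    def test_identical_sets_match_identically(self, rng):
        a = _random_keypoints(rng)
        m = match_keypoints(a, a)
        assert len(m) == len(a)
        np.testing.assert_array_equal(m.pairs[:, 0], m.pairs[:, 1])

    def test_permutation_recovered_against_bruteforce(self, rng):
        a = _random_keypoints(rng, m=30)
        perm = rng.permutation(30)
        b = KeypointSet(positions=a.positions[perm],
                        descriptors=a.descriptors[perm])
        m = match_keypoints(a, b)
        # brute-force nearest neighbour oracle
        d2 = ((a.descriptors[:, None] - b.descriptors[None]) ** 2).sum(-1)
        expected = {(i, int(np.argmin(d2[i]))) for i in range(30)}
        assert {(int(i), int(j)) for i, j in m.pairs} == expected
        # and the permutation itself
        assert all(perm[j] == i for i, j in m.pairs)

    def test_ambiguous_descriptor_dropped_by_ratio(self):
        a = KeypointSet(positions=np.zeros((1, 2)),
                        descriptors=np.array([[1.0, 0.0]]))
        b = KeypointSet(positions=np.zeros((3, 2)),
                        descriptors=np.array([[0.9, 0.1], [0.9, -0.1],
                                              [-5.0, 5.0]]))
        m = match_keypoints(a, b, ratio=0.75)
        assert len(m) == 0   # two equidistant neighbours fail the ratio test

    def test_empty_set_gives_empty_matchset(self, rng):
        a = _random_keypoints(rng)
        assert len(match_keypoints(a, KeypointSet.empty(d=16))) == 0

    def test_one_to_one_on_both_sides(self, rng):
        a = _random_keypoints(rng, m=25)
        b = _random_keypoints(rng, m=20)
        m = match_keypoints(a, b, ratio=0.95)
        assert len(set(m.pairs[:, 0])) == len(m)
        assert len(set(m.pairs[:, 1])) == len(m)


class TestEstimate:
    def _correspondences(self, rng, t, n=40, outliers=0):
        src = rng.random((n, 2)) * 300
        dst = transform_points(src, t)
        if outliers:
            idx = rng.choice(n, size=outliers, replace=False)
            dst[idx] += rng.uniform(30, 80, size=(outliers, 2))
        a = KeypointSet(positions=src, descriptors=np.eye(n))
        b = KeypointSet(positions=dst, descriptors=np.eye(n))
        m = match_keypoints(a, b, ratio=1.0)
        return m, a, b

    def test_identity_recovered(self, rng):
        t = SimilarityTransform2D.identity()
        m, a, b = self._correspondences(rng, t)
        est = estimate_similarity(m, a, b, seed=0)
        assert abs(est.theta) < 1e-9 and abs(est.scale - 1) < 1e-9
        assert abs(est.tx) < 1e-9 and abs(est.ty) < 1e-9

    def test_noiseless_parameters_recovered_exactly(self, rng):
        t = SimilarityTransform2D(theta=np.radians(10), scale=1.02, tx=5, ty=-3)
        m, a, b = self._correspondences(rng, t)
        est = estimate_similarity(m, a, b, seed=0)
        assert est.theta == pytest.approx(t.theta, abs=1e-10)
        assert est.scale == pytest.approx(t.scale, abs=1e-10)
        assert est.tx == pytest.approx(t.tx, abs=1e-8)
        assert est.ty == pytest.approx(t.ty, abs=1e-8)

    def test_robust_to_gross_outliers(self, rng):
        t = SimilarityTransform2D(theta=np.radians(-7), scale=0.99, tx=11, ty=6)
        m, a, b = self._correspondences(rng, t, n=50, outliers=10)
        est = estimate_similarity(m, a, b, seed=0)
        assert abs(np.degrees(est.theta - t.theta)) < 0.5
        assert abs(est.scale - t.scale) < 0.01
        assert np.hypot(est.tx - t.tx, est.ty - t.ty) < 1.0
        assert m.inlier_flags.sum() >= 35

    def test_no_reflection_emitted(self, rng):
        t = SimilarityTransform2D(theta=2.5, scale=1.5, tx=-20, ty=4)
        m, a, b = self._correspondences(rng, t)
        est = estimate_similarity(m, a, b, seed=0)
        assert np.linalg.det(est.linear) > 0

    def test_too_few_pairs_rejected(self, rng):
        t = SimilarityTransform2D.identity()
        m, a, b = self._correspondences(rng, t, n=2)
        with pytest.raises(InsufficientMatchesError):
            estimate_similarity(m, a, b)

    def test_coincident_points_degenerate(self):
        a = KeypointSet(positions=np.ones((5, 2)), descriptors=np.eye(5))
        m = match_keypoints(a, a, ratio=1.0)
        with pytest.raises(DegenerateFitError):
            estimate_similarity(m, a, a)


class TestSerialRegistration:
    def test_identical_sections_give_identity_chain(self, small_stack):
        sec = small_stack.sections[0]
        stack = [sec] * 4
        transforms = register_stack_serial(stack, seed=0)
        for t in transforms:
            assert abs(np.degrees(t.theta)) < 0.05
            assert abs(t.scale - 1) < 0.001
            assert np.hypot(t.tx, t.ty) < 0.1

    def test_chain_equals_pairwise_composition(self, small_stack):
        """Serial transform for section 2 composes the two pairwise fits."""
        secs = small_stack.sections[:3]
        chain = register_stack_serial(secs, seed=0)
        t10 = register_stack_serial(secs[:2], seed=0)[1]
        t21 = register_stack_serial(secs[1:3], seed=0)[1]
        composed = t10 @ t21
        probes = np.array([[60.0, 60.0], [130.0, 70.0], [90.0, 140.0]])
        np.testing.assert_allclose(transform_points(probes, chain[2]),
                                   transform_points(probes, composed), atol=1.5)

    def test_single_section_rejected(self, small_stack):
        with pytest.raises(ValueError):
            register_stack_serial(small_stack.sections[:1])

    def test_failure_names_the_pair(self, small_stack):
        blank = SectionImage(np.full_like(small_stack.sections[0].data, 255),
                             mpp=0.5)
        stack = [small_stack.sections[0], small_stack.sections[1], blank]
        with pytest.raises((InsufficientMatchesError, DegenerateFitError),
                           match=r"\(2 -> 1\)"):
            register_stack_serial(stack, seed=0)

    def test_fall_through_keeps_previous_link(self, small_stack):
        blank = SectionImage(np.full_like(small_stack.sections[0].data, 255),
                             mpp=0.5)
        stack = [small_stack.sections[0], small_stack.sections[1], blank]
        transforms = register_stack_serial(stack, seed=0, fall_through=True)
        assert transforms[2] == transforms[1]

    def test_registration_is_deterministic(self, small_stack):
        a = register_stack_serial(small_stack.sections, seed=0)
        b = register_stack_serial(small_stack.sections, seed=0)
        assert all(x.to_dict() == y.to_dict() for x, y in zip(a, b))
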