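"""Matcher: distances, ratio test, KD-tree/BBF search and match quality."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

import echotrack as et
from echotrack.matching import (
    KDTree,
    MatchConfig,
    bbf_nearest2,
    build_kdtree,
    euclidean_distance,
    match_images,
    ratio_test,
    reverse_match_check,
)
from echotrack.phantom import Rotation, Translation


class TestEuclideanDistance:
    def test_identity_and_pythagoras(self):
        assert euclidean_distance([1, 2, 3], [1, 2, 3]) == 0.0
        assert euclidean_distance([0, 3, 4], [0, 0, 0]) == pytest.approx(5.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-10, 10), min_size=4, max_size=4),
           st.lists(st.floats(-10, 10), min_size=4, max_size=4))
    def test_symmetry(self, a, b):
        assert euclidean_distance(a, b) == pytest.approx(euclidean_distance(b, a))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance([1, 2], [1, 2, 3])


class TestRatioTest:
    @pytest.mark.parametrize("d1,d2,eta,ok", [
        (2.0, 10.0, 0.44, True),    # r = 0.2 < 0.44
        (4.5, 10.0, 0.44, False),   # r = 0.45 >= 0.44
        (4.4, 10.0, 0.44, False),   # r = 0.44: boundary fails (strict <)
        (0.0, 5.0, 0.44, True),     # exact duplicate of one point
        (0.0, 0.0, 0.44, False),    # ambiguous duplicate
    ])
    def test_threshold_cases(self, d1, d2, eta, ok):
        assert ratio_test(d1, d2, eta) is ok


class TestKDTree:
    def test_single_descriptor_tree(self):
        tree = build_kdtree(np.array([[1.0, 2.0, 3.0]]))
        d1, d2, i1, i2 = bbf_nearest2(tree, np.array([1.0, 2.0, 3.0]), 10)
        assert d1 == 0.0 and i1 == 0
        assert np.isinf(d2)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            build_kdtree(np.empty((0, 128)))

    def test_depth_bound_under_median_splits(self):
        rng = np.random.default_rng(0)
        for n in (2, 17, 64, 200):
            tree = KDTree(rng.random((n, 16)), leaf_size=1)
            assert tree.depth() <= int(np.ceil(np.log2(n))) + 1

    def test_identical_points_return_zero_distance(self):
        data = np.ones((5, 8))
        tree = build_kdtree(data)
        d1, _, i1, _ = bbf_nearest2(tree, np.ones(8), 10)
        assert d1 == 0.0 and 0 <= i1 < 5

    def test_stored_descriptor_query_hits_itself(self):
        rng = np.random.default_rng(1)
        data = rng.random((50, 16))
        tree = build_kdtree(data)
        d1, _, i1, _ = bbf_nearest2(tree, data[31], max_checks=50)
        assert d1 == 0.0 and i1 == 31

    def test_exhaustive_bbf_equals_brute_force(self):
        # with max_checks >= n the search is exact: both neighbours and both
        # distances agree with an independent exact tree (scipy cKDTree)
        rng = np.random.default_rng(2)
        data = rng.random((200, 32))
        queries = rng.random((50, 32))
        tree = build_kdtree(data)
        oracle = cKDTree(data)
        d_true, i_true = oracle.query(queries, k=2)
        for q, dt, it in zip(queries, d_true, i_true):
            d1, d2, i1, i2 = bbf_nearest2(tree, q, max_checks=200)
            assert i1 == it[0] and i2 == it[1]
            assert d1 == pytest.approx(dt[0], abs=1e-12)
            assert d2 == pytest.approx(dt[1], abs=1e-12)

    def test_limited_checks_agree_on_descriptor_data(self, speckle_frame,
                                                     features):
        # brute-force oracle: >= 95% nearest-neighbour agreement at
        # max_checks = 50 on 200 stored descriptors
        frame = speckle_frame(seed=3, size=256, density=0.12, blur=1.2)
        moved = et.add_noise(
            et.warp_frame(frame, Translation((0.6, 0.3)).displacement_field(
                frame.shape, 1)), "gaussian", 0.02, 7)
        _, _, data = features(frame)
        _, _, queries = features(moved)
        data, queries = data[:200], queries[:100]
        assert len(data) >= 100 and len(queries) >= 50
        tree = build_kdtree(data)
        brute = cdist(queries, data).argmin(axis=1)
        agree = sum(bbf_nearest2(tree, q, 50)[2] == brute[i]
                    for i, q in enumerate(queries))
        assert agree >= 0.95 * len(queries)


class TestMatchImages:
    def test_identical_sets_match_themselves(self):
        rng = np.random.default_rng(4)
        descs = rng.random((20, 128))
        descs /= np.linalg.norm(descs, axis=1, keepdims=True)
        pairs = et.match_images(descs, descs)
        assert len(pairs) == 20
        for p in pairs:
            assert p.index_a == p.index_b
            assert p.d_min == 0.0 and p.r == 0.0

    def test_only_uncorrupted_pair_survives(self):
        # constructed set: corrupt all but one descriptor with large noise
        rng = np.random.default_rng(5)
        a = rng.random((10, 128))
        a /= np.linalg.norm(a, axis=1, keepdims=True)
        b = a + 0.8 * rng.random((10, 128))
        b[4] = a[4]
        b /= np.linalg.norm(b, axis=1, keepdims=True)
        pairs = et.match_images(a, b, MatchConfig(search_mode="brute_force"))
        assert [(p.index_a, p.index_b) for p in pairs] == [(4, 4)]

    def test_accepted_pairs_satisfy_ratio_invariant(self, speckle_frame, features):
        frame = speckle_frame(seed=6)
        moved = et.warp_frame(frame, Translation((1.0, 0.5)).displacement_field(
            frame.shape, 1))
        _, _, da = features(frame)
        _, _, db = features(moved)
        cfg = MatchConfig()
        for p in et.match_images(da, db, cfg):
            assert p.d_min <= p.d_min2
            assert p.r < cfg.ratio_threshold

    def test_ratio_threshold_monotonicity(self, speckle_frame, features):
        frame = speckle_frame(seed=6)
        moved = et.warp_frame(frame, Translation((1.0, 0.5)).displacement_field(
            frame.shape, 1))
        _, _, da = features(frame)
        _, _, db = features(moved)
        loose = {(p.index_a, p.index_b)
                 for p in et.match_images(da, db, MatchConfig(ratio_threshold=0.44))}
        tight = {(p.index_a, p.index_b)
                 for p in et.match_images(da, db, MatchConfig(ratio_threshold=0.2))}
        assert tight <= loose

    def test_brute_force_and_exhaustive_bbf_agree(self, speckle_frame, features):
        frame = speckle_frame(seed=7)
        moved = et.warp_frame(frame, Translation((0.8, 0.0)).displacement_field(
            frame.shape, 1))
        _, _, da = features(frame)
        _, _, db = features(moved)
        brute = et.match_images(da, db, MatchConfig(search_mode="brute_force"))
        bbf = et.match_images(da, db, MatchConfig(search_mode="kdtree_bbf",
                                                  bbf_max_checks=len(db)))
        assert [(p.index_a, p.index_b) for p in brute] == \
               [(p.index_a, p.index_b) for p in bbf]

    def test_geometric_precision_on_rotated_phantom(self, speckle_frame, features):
        frame = speckle_frame(seed=21, size=192, density=0.12, blur=1.2)
        rot = Rotation(degrees_per_frame=10.0)
        moved = et.warp_frame(frame, rot.displacement_field(frame.shape, 1))
        _, ka, da = features(frame)
        _, kb, db = features(moved)
        pairs = et.match_images(da, db)
        assert len(pairs) >= 10
        pa = np.array([ka[p.index_a].position for p in pairs])
        pb = np.array([kb[p.index_b].position for p in pairs])
        truth = rot.transform_points(pa, frame.shape, 1)
        err = np.hypot(*(pb - truth).T)
        assert np.mean(err <= 2.0) >= 0.9

    def test_single_descriptor_in_b_gives_empty_result(self):
        rng = np.random.default_rng(8)
        assert et.match_images(rng.random((5, 128)), rng.random((1, 128))) == []


class TestReverseMatch:
    def test_identical_sets_give_equal_counts(self):
        rng = np.random.default_rng(9)
        descs = rng.random((15, 128))
        f, r = reverse_match_check(descs, descs)
        assert f == r == 15

    def test_disjoint_clouds_yield_few_matches(self):
        # null oracle: unrelated random descriptors rarely pass the ratio test
        rng = np.random.default_rng(10)
        a = rng.random((40, 128))
        b = rng.random((40, 128)) + 5.0
        f, r = reverse_match_check(a, b)
        assert f <= 2 and r <= 2

    def test_forward_reverse_symmetry_on_phantom_pairs(self, speckle_frame,
                                                       features):
        # the two directions give nearly equal mean match counts
        fwd, rev = [], []
        for seed in range(8):
            spec = et.PhantomSpec(height=192, width=192, speckle_density=0.12,
                                  blur_sigma=1.2, seed=seed,
                                  noise_kind="gaussian", noise_level=0.02)
            seq = et.make_sequence(spec, Translation((0.7, 0.4)), 2)
            _, _, da = features(seq.frames[0])
            _, _, db = features(seq.frames[1])
            f, r = reverse_match_check(da, db)
            fwd.append(f)
            rev.append(r)
        mf, mr = np.mean(fwd), np.mean(rev)
        assert abs(mf - mr) / max(mf, mr) < 0.1
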