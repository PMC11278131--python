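"""Six-step recurrence extractor: hand oracles and structural invariants."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

from spatialrqa.patch import ImagePatch
from spatialrqa.shrqa import (
    AttributeVector,
    CellSequence,
    ShrqaConfig,
    ShrqaExtractor,
    StateTrajectory,
    dwt2_haar,
    embed_trajectory,
    hilbert_flatten,
    hilbert_order,
    ifs_project,
    quadtree_partition,
    quantify_recurrence,
    shrqa_features,
)
from spatialrqa.texture import TextureSpec, generate_texture_patch


def gray(arr):
    return ImagePatch(pixels=np.asarray(arr, dtype=float), mode="GRAY")


# ---------------------------------------------------------------------------
# independent brute-force oracle for the recurrence measures


def brute_force_measures(seq, n_cells, run_min=2):
    """Direct pair/run/gap counting, independent of the implementation."""
    T = len(seq)
    out = np.zeros((n_cells, 7))
    for c in range(n_cells):
        visits = [t for t, s in enumerate(seq) if s == c]
        k = len(visits)
        if k == 0:
            continue
        out[c, 0] = k / T
        pairs = sum(
            1
            for i in range(T)
            for j in range(i + 1, T)
            if seq[i] == c and seq[j] == c
        )
        if k >= 2:
            out[c, 1] = (pairs / (T * (T - 1) / 2)) / (k / T)
            gaps = [visits[i + 1] - visits[i] for i in range(k - 1)]
            out[c, 4] = sum(gaps) / len(gaps)
            counts = Counter(gaps)
            out[c, 5] = -sum(
                (v / len(gaps)) * math.log(v / len(gaps)) for v in counts.values()
            )
        runs, t = [], 0
        while t < T:
            if seq[t] == c:
                length = 1
                while t + length < T and seq[t + length] == c:
                    length += 1
                runs.append(length)
                t += length
            else:
                t += 1
        runs = [r for r in runs if r >= run_min]
        if runs:
            out[c, 2] = sum(runs) / len(runs)
            counts = Counter(runs)
            out[c, 3] = -sum(
                (v / len(runs)) * math.log(v / len(runs)) for v in counts.values()
            )
        n_from = sum(1 for t in range(T - 1) if seq[t] == c)
        if n_from:
            out[c, 6] = (
                sum(1 for t in range(T - 1) if seq[t] == c and seq[t + 1] == c) / n_from
            )
    return out.ravel()


class TestHaar:
    def test_level_zero_is_identity(self):
        patch = gray(np.random.default_rng(0).random((8, 8)))
        assert dwt2_haar(patch, 0) is patch

    def test_constant_2x2_reduces_to_same_value(self):
        out = dwt2_haar(gray(np.full((2, 2), 0.37)), 1)
        assert out.pixels.shape == (1, 1)
        assert out.pixels[0, 0] == pytest.approx(0.37)

    def test_4x4_level1_equals_block_means(self):
        arr = np.arange(16, dtype=float).reshape(4, 4) / 16.0
        out = dwt2_haar(gray(arr), 1)
        expected = np.array(
            [
                [arr[:2, :2].mean(), arr[:2, 2:].mean()],
                [arr[2:, :2].mean(), arr[2:, 2:].mean()],
            ]
        )
        np.testing.assert_allclose(out.pixels, expected, atol=1e-12)

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ValueError, match="power of 2"):
            dwt2_haar(gray(np.zeros((6, 6))), 1)


class TestHilbert:
    def test_single_pixel(self):
        vec = hilbert_flatten(gray([[0.5]]))
        assert len(vec) == 1

    @pytest.mark.parametrize("side", [2, 4, 8, 16])
    def test_bijection_and_adjacency(self, side):
        """Every pixel visited exactly once; consecutive steps 4-adjacent."""
        order = side.bit_length() - 1
        rows, cols = hilbert_order(order)
        assert len(set(zip(rows.tolist(), cols.tolist()))) == side * side
        steps = np.abs(np.diff(rows)) + np.abs(np.diff(cols))
        assert (steps == 1).all()

    def test_flatten_follows_curve(self):
        arr = np.arange(16, dtype=float).reshape(4, 4) / 16.0
        vec = hilbert_flatten(gray(arr))
        rows, cols = hilbert_order(2)
        np.testing.assert_array_equal(vec.values, arr[rows, cols])

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            hilbert_flatten(gray(np.zeros((2, 4))))


class TestEmbedding:
    def test_constant_vector_gives_identical_points(self):
        traj = embed_trajectory(AttributeVector(np.full(10, 0.3), 0), 2, 1)
        assert traj.n_points == 9
        assert (traj.points == 0.3).all()

    def test_alternating_vector(self):
        v = np.array([0.0, 1.0] * 5)
        traj = embed_trajectory(AttributeVector(v, 0), 2, 1)
        expected = np.array([[0.0, 1.0], [1.0, 0.0]] * 5)[:9]
        np.testing.assert_array_equal(traj.points, expected)

    def test_too_short_vector_rejected(self):
        with pytest.raises(ValueError):
            embed_trajectory(AttributeVector(np.array([0.1]), 0), 2, 1)


class TestQuadtree:
    def test_depth_two_has_sixteen_cells(self):
        traj = StateTrajectory(points=np.array([[0.1, 0.1]]))
        assert quadtree_partition(traj, 2).n_cells == 16

    def test_origin_quadrant_is_symbol_zero(self):
        traj = StateTrajectory(points=np.array([[0.1, 0.1]]))
        assert quadtree_partition(traj, 1).symbols[0] == 0

    def test_boundary_one_maps_to_last_cell(self):
        traj = StateTrajectory(points=np.array([[1.0, 1.0], [0.999, 0.999]]))
        cells = quadtree_partition(traj, 2)
        assert cells.symbols[0] == 15
        assert cells.symbols[1] == 15

    def test_uniform_grid_counts_match_enumeration(self):
        xs = np.linspace(0, 1, 10)
        pts = np.array([(a, b) for a in xs for b in xs])
        cells = quadtree_partition(StateTrajectory(points=pts), 2)
        counts = np.bincount(cells.symbols, minlength=16)
        # independent enumeration: per-axis quarter membership
        axis = np.minimum((xs * 4).astype(int), 3)
        expected = np.zeros(16, dtype=int)
        for a in axis:
            for b in axis:
                sym = 0
                for level in (1, 0):
                    sym = sym * 4 + 2 * ((a >> level) & 1) + ((b >> level) & 1)
                expected[sym] += 1
        np.testing.assert_array_equal(counts, expected)
        assert counts.min() >= 4 and counts.max() <= 9

    def test_out_of_range_points_rejected(self):
        with pytest.raises(ValueError):
            quadtree_partition(StateTrajectory(points=np.array([[1.2, 0.5]])), 2)


class TestIFS:
    def test_single_symbol_hand_iteration(self):
        # symbol 6 -> digits (1, 2); from (0.5, 0.5):
        # digit 1 (corner (0,1)): (0.25, 0.25) + (0, 0.5) = (0.25, 0.75)
        # digit 2 (corner (1,0)): (0.125, 0.375) + (0.5, 0) = (0.625, 0.375)
        plot = ifs_project(CellSequence(symbols=[6], depth=2))
        np.testing.assert_allclose(plot.points[0], [0.625, 0.375], atol=1e-12)

    def test_constant_symbol_converges_to_fixed_point(self):
        plot = ifs_project(CellSequence(symbols=[15] * 30, depth=2))
        # symbol 15 repeats corner (1,1): fixed point is (1,1)
        errs = np.linalg.norm(plot.points - np.array([1.0, 1.0]), axis=1)
        assert errs[-1] < 1e-8
        # geometric contraction: each symbol shrinks the error by 1/4
        ratios = errs[1:10] / errs[:9]
        np.testing.assert_allclose(ratios, 0.25, atol=1e-9)

    def test_points_stay_in_unit_square(self):
        rng = np.random.default_rng(5)
        cells = CellSequence(symbols=rng.integers(0, 16, 200), depth=2)
        pts = ifs_project(cells).points
        assert pts.min() >= 0.0 and pts.max() <= 1.0

    def test_shared_suffix_contraction(self):
        rng = np.random.default_rng(6)
        suffix = rng.integers(0, 16, 5).tolist()
        a = ifs_project(CellSequence(symbols=[3, 7] + suffix, depth=2))
        b = ifs_project(CellSequence(symbols=[12] + suffix, depth=2))
        dist = np.linalg.norm(a.points[-1] - b.points[-1])
        assert dist <= 4.0 ** (-5) * np.sqrt(2) + 1e-12

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ifs_project(CellSequence(symbols=[], depth=2))


class TestRecurrenceMeasures:
    def test_degenerate_single_cell_sequence(self):
        T = 7
        fv = quantify_recurrence(CellSequence(symbols=[3] * T, depth=2))
        m = fv.values.reshape(16, 7)
        np.testing.assert_allclose(m[3], [1.0, 1.0, T, 0.0, 1.0, 0.0, 1.0])
        others = np.delete(m, 3, axis=0)
        assert (others == 0).all()

    def test_alternating_sequence_cell_zero(self):
        fv = quantify_recurrence(CellSequence(symbols=[0, 1, 0, 1, 0, 1], depth=1))
        m = fv.values.reshape(4, 7)
        assert m[0, 0] == pytest.approx(0.5)  # occupancy
        assert m[0, 6] == 0.0  # self-transition
        assert m[0, 4] == pytest.approx(2.0)  # mean recurrence time

    @given(
        st.lists(st.integers(0, 15), min_size=2, max_size=60),
    )
    def test_occupancy_sums_to_one(self, symbols):
        fv = quantify_recurrence(CellSequence(symbols=symbols, depth=2))
        occ = fv.values.reshape(16, 7)[:, 0]
        assert occ.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_on_short_sequences(self):
        """Exhaustive cross-check against direct counting (lengths 2-5)."""
        for length in range(2, 6):
            for seq in itertools.product(range(4), repeat=length):
                fv = quantify_recurrence(CellSequence(symbols=list(seq), depth=1))
                np.testing.assert_allclose(
                    fv.values, brute_force_measures(seq, 4), atol=1e-12
                )

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            quantify_recurrence(CellSequence(symbols=[1], depth=2))


class TestFullPipeline:
    def test_256_patch_gives_112_features(self):
        patch = generate_texture_patch(TextureSpec(size_px=256, seed=0))
        fv = shrqa_features(patch, ShrqaConfig())
        assert len(fv) == 112
        assert fv.feature_names[0] == "cell0_occupancy"
        assert fv.feature_names[-1] == "cell15_self_transition"

    def test_deterministic(self):
        patch = generate_texture_patch(TextureSpec(size_px=64, seed=4))
        cfg = ShrqaConfig(patch_size_px=64)
        a = shrqa_features(patch, cfg)
        b = shrqa_features(patch, cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_orientation_sensitive(self):
        patch = generate_texture_patch(TextureSpec(size_px=64, seed=8, jitter=0.4))
        rotated = ImagePatch(pixels=np.rot90(patch.pixels).copy(), mode="RGB")
        cfg = ShrqaConfig(patch_size_px=64)
        a = shrqa_features(patch, cfg)
        b = shrqa_features(rotated, cfg)
        assert not np.allclose(a.values, b.values)

    def test_size_mismatch_rejected(self):
        patch = generate_texture_patch(TextureSpec(size_px=64, seed=1))
        with pytest.raises(ValueError, match="config expects"):
            shrqa_features(patch, ShrqaConfig(patch_size_px=256))


class TestExtractorEstimator:
    def test_transform_shape_and_names(self, seeded_patches):
        ext = ShrqaExtractor()
        X = ext.fit_transform(seeded_patches[:4])
        assert X.shape == (4, 112)
        assert list(ext.get_feature_names_out())[:2] == [
            "cell0_occupancy",
            "cell0_recurrence_rate",
        ]

    def test_sklearn_clone_and_params(self):
        ext = ShrqaExtractor(quadtree_depth=1, run_min=3)
        cloned = clone(ext)
        assert cloned.get_params()["quadtree_depth"] == 1
        assert cloned.get_params()["run_min"] == 3
        assert cloned.fit().n_features_out_ == 4 * 7

    def test_accepts_raw_arrays(self):
        rng = np.random.default_rng(0)
        imgs = rng.integers(0, 256, size=(3, 64, 64, 3), dtype=np.uint8)
        X = ShrqaExtractor().fit_transform(list(imgs))
        assert X.shape == (3, 112)
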