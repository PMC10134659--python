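"""Distance-band weights and autocovariate: hand oracles and invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import autologit as al
from autologit.exceptions import ValidationError


class TestBuildWeights:
    def test_collinear_toy_pairs_and_counts(self, toy_weights):
        # d(0,1)=1, d(1,2)=1, d(0,2)=2 -> w = 1, 1, 0.5 plus mirrors
        pairs = toy_weights.pairs().set_index(["i", "j"])["w"]
        assert pairs[(0, 1)] == pytest.approx(1.0)
        assert pairs[(1, 2)] == pytest.approx(1.0)
        assert pairs[(0, 2)] == pytest.approx(0.5)
        assert len(pairs) == 6  # symmetric storage
        assert toy_weights.neighbor_counts.tolist() == [2, 2, 2]

    def test_symmetry(self, toy_weights):
        m = toy_weights.matrix
        assert (abs(m - m.T)).max() == 0

    def test_band_excludes_far_pair(self):
        pts = pd.DataFrame({"x": [0.0, 10.0], "y": [0.0, 0.0]})
        with pytest.warns(UserWarning, match="isolated"):
            w = al.build_weights(pts, radius=5.0)
        assert w.matrix.nnz == 0
        assert w.isolated.all()

    def test_two_points_within_band(self):
        pts = pd.DataFrame({"x": [0.0, 2.0], "y": [0.0, 0.0]})
        w = al.build_weights(pts, radius=5.0)
        assert w.matrix.nnz == 2
        assert w.pairs()["w"].tolist() == [0.5, 0.5]

    def test_coincident_points_error_names_pair(self):
        pts = pd.DataFrame({"unit_id": ["a", "b", "c"], "x": [0.0, 0.0, 3.0], "y": [0.0] * 3})
        with pytest.raises(ValidationError, match="'a'.*'b'|'b'.*'a'"):
            al.build_weights(pts, radius=5.0)

    def test_jitter_breaks_ties(self):
        pts = pd.DataFrame({"x": [0.0, 0.0, 3.0], "y": [0.0] * 3})
        jit = al.jitter_points(pts, scale=0.5, seed=0)
        w = al.build_weights(jit, radius=5.0)
        assert (w.pairs()["w"] > 0).all()

    def test_default_radius_leaves_no_isolated_units(self):
        rng = np.random.default_rng(3)
        pts = pd.DataFrame(rng.uniform(0, 1000, (40, 2)), columns=["x", "y"])
        w = al.build_weights(pts)
        assert not w.isolated.any()

    def test_nonfinite_coordinates_rejected(self):
        pts = pd.DataFrame({"x": [0.0, np.nan], "y": [0.0, 1.0]})
        with pytest.raises(ValidationError, match="non-finite"):
            al.build_weights(pts, radius=5.0)

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValidationError, match="at least 2"):
            al.build_weights(pd.DataFrame({"x": [0.0], "y": [0.0]}), radius=1.0)


class TestAutocovariate:
    def test_hand_computation_on_toy(self, toy_weights):
        # endpoint: (1*y1 + 0.5*y2)/1.5 = 0.5/1.5 = 1/3; middle: (1+1)/2 = 1
        ac = al.autocovariate(toy_weights, [1, 0, 1])
        assert ac == pytest.approx([1 / 3, 1.0, 1 / 3])

    def test_constant_outcome_gives_constant_one(self, toy_weights):
        assert al.autocovariate(toy_weights, [1, 1, 1]) == pytest.approx([1, 1, 1])

    def test_single_neighbor_equals_neighbor_outcome(self):
        pts = pd.DataFrame({"x": [0.0, 2.0], "y": [0.0, 0.0]})
        w = al.build_weights(pts, radius=5.0)
        assert al.autocovariate(w, [1, 0]) == pytest.approx([0.0, 1.0])

    def test_isolated_unit_gets_prevalence_fallback(self):
        pts = pd.DataFrame({"x": [0.0, 1.0, 100.0], "y": [0.0] * 3})
        with pytest.warns(UserWarning):
            w = al.build_weights(pts, radius=5.0)
        with pytest.warns(UserWarning, match="fallback"):
            ac = al.autocovariate(w, [1, 0, 1])
        assert ac[2] == pytest.approx(2 / 3)

    def test_length_mismatch_and_nonbinary_rejected(self, toy_weights):
        with pytest.raises(ValidationError, match="length"):
            al.autocovariate(toy_weights, [1, 0])
        with pytest.raises(ValidationError, match="binary"):
            al.autocovariate(toy_weights, [1, 0, 0.5])

    @settings(deadline=None, max_examples=25)
    @given(
        angle=st.floats(0, 2 * np.pi),
        dx=st.floats(-1e4, 1e4),
        dy=st.floats(-1e4, 1e4),
        seed=st.integers(0, 100),
    )
    def test_rigid_motion_invariance(self, angle, dx, dy, seed):
        """Autocovariate depends only on pairwise distances."""
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 100, (12, 2))
        y = rng.integers(0, 2, 12).astype(float)
        if y.sum() == 0:
            y[0] = 1.0
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        xy2 = xy @ rot.T + np.array([dx, dy])
        w1 = al.build_weights(xy, radius=60.0)
        w2 = al.build_weights(xy2, radius=60.0)
        np.testing.assert_allclose(
            al.autocovariate(w1, y), al.autocovariate(w2, y), atol=1e-9
        )

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 1000))
    def test_convex_combination_bounds(self, seed):
        """For each unit, autocov lies within [min, max] of neighbour y."""
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 50, (15, 2))
        y = rng.integers(0, 2, 15).astype(float)
        y[0] = 1.0  # ensure both classes plausible
        y[1] = 0.0
        w = al.build_weights(xy, radius=30.0)
        ac = al.autocovariate(w, y)
        m = w.matrix
        for i in range(15):
            nbrs = m.indices[m.indptr[i] : m.indptr[i + 1]]
            if len(nbrs):
                assert y[nbrs].min() - 1e-12 <= ac[i] <= y[nbrs].max() + 1e-12

    def test_distance_scaling_invariance(self):
        """Doubling all distances with radius doubled rescales weights
        uniformly within each unit's normalisation, leaving autocov fixed."""
        rng = np.random.default_rng(7)
        xy = rng.uniform(0, 100, (20, 2))
        y = rng.integers(0, 2, 20).astype(float)
        w1 = al.build_weights(xy, radius=40.0)
        w2 = al.build_weights(2.0 * xy, radius=80.0)
        np.testing.assert_allclose(
            al.autocovariate(w1, y), al.autocovariate(w2, y), atol=1e-12
        )
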