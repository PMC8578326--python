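"""Distance matrices, the LoTRA code transform and threshold calibration."""

import numpy as np
import pytest

from lotra import (
    CodeMatrix,
    DistanceMatrix,
    EmbeddingParams,
    Neighborhood3x3,
    Trajectory,
    calibrate_epsilon,
    code_band_mask,
    delay_embed,
    distance_matrix,
    lbp_code,
    lotra_transform,
    recurrence_matrix,
    recurrence_rate,
)
from lotra.core import NEIGHBOR_OFFSETS

from _oracles import naive_distance_matrix, naive_lbp, random_symmetric_distances


class TestDistanceMatrix:
    def test_one_dimensional_example(self):
        D = distance_matrix(Trajectory(points=np.array([0.0, 3.0, 7.0])))
        np.testing.assert_array_equal(D.values, [[0, 3, 7], [3, 0, 4], [7, 4, 0]])

    def test_zero_diagonal_and_symmetry(self, rng):
        D = distance_matrix(Trajectory(points=rng.normal(size=(15, 3))))
        assert np.all(np.diagonal(D.values) == 0)
        np.testing.assert_array_equal(D.values, D.values.T)

    def test_matches_bruteforce(self, rng):
        pts = rng.normal(size=(10, 4))
        D = distance_matrix(Trajectory(points=pts))
        np.testing.assert_allclose(D.values, naive_distance_matrix(pts), atol=1e-12)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            distance_matrix(Trajectory(points=np.array([0.0, 1.0])))


class TestLbpCode:
    def test_all_ties_give_255(self):
        assert lbp_code(Neighborhood3x3(center=2.0, neighbors=(2.0,) * 8)) == 255

    def test_dominant_center_gives_0(self):
        assert lbp_code(Neighborhood3x3(center=9.0, neighbors=(1.0,) * 8)) == 0

    @pytest.mark.parametrize("position, expected", [(0, 1), (7, 128)])
    def test_positional_weights(self, position, expected):
        neighbors = [0.0] * 8
        neighbors[position] = 5.0
        assert lbp_code(Neighborhood3x3(center=1.0, neighbors=tuple(neighbors))) == expected

    def test_enumeration_covers_all_256_codes(self):
        codes = set()
        for pattern in range(256):
            neighbors = tuple(2.0 if pattern & (1 << b) else 0.0 for b in range(8))
            codes.add(lbp_code(Neighborhood3x3(center=1.0, neighbors=neighbors)))
        assert codes == set(range(256))


class TestLotraTransform:
    def test_constant_signal_codes_all_255(self):
        D = DistanceMatrix(values=np.zeros((6, 6)))
        C = lotra_transform(D)
        assert np.all(C.codes == 255)

    def test_line_of_identity_codes_all_255(self, rng):
        D = distance_matrix(Trajectory(points=rng.normal(size=(12, 2))))
        C = lotra_transform(D)
        assert np.all(np.diagonal(C.codes) == 255)

    def test_matches_bruteforce_oracle(self, rng):
        m = random_symmetric_distances(rng, 20)
        C = lotra_transform(DistanceMatrix(values=m))
        np.testing.assert_array_equal(C.codes, naive_lbp(m))

    def test_output_shape_and_offset(self, rng):
        D = distance_matrix(Trajectory(points=rng.normal(size=(9, 2))))
        C = lotra_transform(D)
        assert C.codes.shape == (7, 7)
        assert C.index_offset == 1

    def test_code_range_and_dtype(self, rng):
        C = lotra_transform(DistanceMatrix(values=random_symmetric_distances(rng, 25)))
        assert np.issubdtype(C.codes.dtype, np.integer)
        assert C.codes.min() >= 0 and C.codes.max() <= 255

    def test_too_small_errors(self):
        with pytest.raises(ValueError, match="too small"):
            lotra_transform(DistanceMatrix(values=np.zeros((2, 2))))

    def test_transpose_is_bit_permutation(self, rng):
        # For symmetric D, the code at (j, i) is the code at (i, j) with each
        # neighbor's offset transposed: bit order 0..7 maps to 0,7,6,5,4,3,2,1.
        transposed_bit = {
            b: NEIGHBOR_OFFSETS.index((dj, di))
            for b, (di, dj) in enumerate(NEIGHBOR_OFFSETS)
        }
        for _ in range(10):
            m = random_symmetric_distances(rng, 10)
            codes = lotra_transform(DistanceMatrix(values=m)).codes
            permuted = np.zeros_like(codes)
            for b, pb in transposed_bit.items():
                permuted |= (((codes >> b) & 1) << pb).astype(codes.dtype)
            np.testing.assert_array_equal(codes.T, permuted)


class TestCodeBandMask:
    def test_full_band_is_all_ones(self, rng):
        C = lotra_transform(DistanceMatrix(values=random_symmetric_distances(rng, 8)))
        assert np.all(code_band_mask(C, 0, 255).entries == 1)

    def test_high_curvature_band_zeroes_the_diagonal(self, rng):
        D = distance_matrix(Trajectory(points=rng.normal(size=(10, 2))))
        mask = code_band_mask(lotra_transform(D))
        assert np.all(np.diagonal(mask.entries) == 0)

    def test_degenerate_band_on_constant_signal(self):
        C = lotra_transform(DistanceMatrix(values=np.zeros((5, 5))))
        assert np.all(code_band_mask(C, 255, 255).entries == 1)

    def test_inverted_band_errors(self):
        C = CodeMatrix(codes=np.full((3, 3), 100))
        with pytest.raises(ValueError, match="invalid code band"):
            code_band_mask(C, 200, 100)


class TestRecurrenceMatrix:
    def test_epsilon_above_max_gives_all_ones(self, rng):
        D = distance_matrix(Trajectory(points=rng.normal(size=(8, 2))))
        B = recurrence_matrix(D, float(D.values.max()))
        assert recurrence_rate(B) == 1.0

    def test_epsilon_zero_keeps_diagonal_only(self, rng):
        D = distance_matrix(Trajectory(points=rng.normal(size=(8, 2))))
        B = recurrence_matrix(D, 0.0)
        np.testing.assert_array_equal(B.entries, np.eye(8, dtype=np.uint8))

    def test_small_worked_example(self):
        D = DistanceMatrix(values=np.array([[0, 3, 7], [3, 0, 4], [7, 4, 0]], dtype=float))
        B = recurrence_matrix(D, 3.5)
        expected = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]])
        np.testing.assert_array_equal(B.entries, expected)
        assert recurrence_rate(B) == pytest.approx(5 / 9)

    def test_rr_monotone_in_epsilon(self, rng):
        D = distance_matrix(Trajectory(points=rng.normal(size=(30, 2))))
        grid = np.linspace(0, D.values.max() * 1.1, 25)
        rates = [recurrence_rate(recurrence_matrix(D, e)) for e in grid]
        assert np.all(np.diff(rates) >= 0)


class TestCalibrateEpsilon:
    def test_target_one_hits_full_matrix(self, rng):
        D = distance_matrix(Trajectory(points=rng.normal(size=(12, 2))))
        cal = calibrate_epsilon(D, 0.999)
        assert cal.epsilon == pytest.approx(D.values.max())
        assert cal.achieved_rr == 1.0

    def test_sine_gait_band(self, sine_t15_distances):
        cal = calibrate_epsilon(sine_t15_distances, 0.045)
        assert 0.04 <= cal.achieved_rr <= 0.05

    def test_self_consistency(self, rng):
        D = distance_matrix(Trajectory(points=rng.normal(size=(40, 3))))
        cal = calibrate_epsilon(D, 0.07)
        assert recurrence_rate(recurrence_matrix(D, cal.epsilon)) == pytest.approx(
            cal.achieved_rr, abs=0
        )

    def test_unreachable_target_errors(self, rng):
        D = distance_matrix(Trajectory(points=rng.normal(size=(10, 2))))
        with pytest.raises(ValueError, match="below attainable minimum"):
            calibrate_epsilon(D, 0.01)


def test_three_sine_delays_yield_distinct_code_histograms(sine):
    """The t=15/20/3 embeddings are distinguishable by their LoTRA codes."""
    occupancies = {}
    hists = {}
    for t in (15, 20, 3):
        traj = delay_embed(sine, EmbeddingParams(delay=t, dimension=2))
        codes = lotra_transform(distance_matrix(traj)).codes
        hists[t] = np.bincount(codes.ravel(), minlength=256) / codes.size
        band = (codes >= 64) & (codes <= 191)
        occupancies[t] = band.mean()
    for a, b in [(15, 20), (15, 3), (20, 3)]:
        chi2 = np.sum(
            (hists[a] - hists[b]) ** 2 / np.where(hists[a] + hists[b] == 0, 1, hists[a] + hists[b])
        )
        assert chi2 > 0
        assert abs(occupancies[a] - occupancies[b]) > 0.01
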