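"""Raw-data correction, Bragg-pixel veto and CSR compression kernels."""

import numpy as np
import pytest
import scipy.sparse
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import ssxpipe as s


def _raw_from_words(words):
    return s.RawFrame(words=np.asarray(words, dtype=np.uint16))


class TestCorrectFrame:
    def test_direct_arithmetic(self):
        t = s.make_calibration((1, 1), (40.0, 2.0, 0.5), (900.0, 800.0, 700.0), 0.0, 0)
        out = s.correct_frame(_raw_from_words([[1000]]), t)
        assert out.values[0, 0] == np.float32(2.5)

    def test_vectorized_agrees_bitwise_with_scalar_oracle(self, tables):
        rng = np.random.default_rng(31)
        words = rng.integers(0, 2**16, tables.shape, dtype=np.uint16)
        raw = _raw_from_words(words)
        vec = s.correct_frame(raw, tables)
        ref, ops = s.scalar_correct_frame(raw, tables)
        assert np.array_equal(vec.values, ref.values, equal_nan=True)
        valid = int(np.count_nonzero((words >> 14) != 0b10))
        assert ops.subtractions == ops.divisions == valid

    def test_all_gain_levels_use_their_own_coefficients(self, flat_tables):
        words = np.array(
            [[(0b00 << 14) | 1100, (0b01 << 14) | 1100, (0b11 << 14) | 1100]],
            dtype=np.uint16,
        )
        t = s.make_calibration(
            (1, 3), (40.0, 2.0, 0.5), (1000.0, 800.0, 700.0), 0.0, 0
        )
        out = s.correct_frame(s.RawFrame(words=words), t)
        np.testing.assert_array_equal(
            out.values, np.array([[2.5, 150.0, 800.0]], dtype=np.float32)
        )

    def test_reserved_bit_pattern_masked_to_nan(self, flat_tables):
        words = np.full(flat_tables.shape, (0b10 << 14) | 500, dtype=np.uint16)
        out = s.correct_frame(s.RawFrame(words=words), flat_tables)
        assert np.all(np.isnan(out.values))
        with pytest.raises(s.ValidationError):
            s.correct_frame(s.RawFrame(words=words), flat_tables, invalid="error")

    def test_shape_mismatch_rejected(self, flat_tables):
        with pytest.raises(s.ShapeMismatchError):
            s.correct_frame(_raw_from_words(np.zeros((2, 2))), flat_tables)

    def test_negative_energies_not_clipped(self, flat_tables):
        words = np.full(flat_tables.shape, 900, dtype=np.uint16)  # below pedestal
        out = s.correct_frame(s.RawFrame(words=words), flat_tables)
        assert np.all(out.values == np.float32((900 - 1000) / 40.0))


class TestCountAndVeto:
    def test_zero_frame_counts_nothing(self):
        e = s.EnergyFrame(values=np.zeros((4, 4), np.float32))
        assert s.count_peak_pixels(e, 1.0) == 0

    def test_threshold_below_minimum_counts_all(self):
        e = s.EnergyFrame(values=np.zeros((4, 4), np.float32))
        assert s.count_peak_pixels(e, -1e30) == 16

    def test_count_matches_nested_loop_oracle(self, scene):
        energy = scene[0]
        thr = 10.0
        oracle = sum(
            1
            for r in range(energy.shape[0])
            for c in range(energy.shape[1])
            if energy.values[r, c] > thr
        )
        assert s.count_peak_pixels(energy, thr) == oracle

    def test_nan_pixels_never_count(self):
        vals = np.full((3, 3), 100.0, np.float32)
        vals[1, 1] = np.nan
        assert s.count_peak_pixels(s.EnergyFrame(values=vals), 0.0) == 8

    def test_reject_and_vacuous_accept(self):
        zeros = s.EnergyFrame(values=np.zeros((4, 4), np.float32))
        assert s.veto(zeros, s.VetoConfig(1.0, 1)) == (False, 0)
        assert s.veto(zeros, s.VetoConfig(1.0, 0))[0] is True

    def test_veto_agrees_with_brute_force_pipeline_recomputation(self, tables):
        """10 spots of amplitude 100, threshold 50, min 5: full-chain oracle."""
        energy, _ = s.generate_peaks_image(
            tables.shape, 10, 100.0, 1.2, 1.0, seed=55
        )
        raw = s.encode_raw(energy, tables)
        corrected = s.correct_frame(raw, tables)
        accept, count = s.veto(corrected, s.VetoConfig(50.0, 5))
        oracle_count = 0
        for r in range(corrected.shape[0]):
            for c in range(corrected.shape[1]):
                if corrected.values[r, c] > 50.0:
                    oracle_count += 1
        assert count == oracle_count
        assert accept == (oracle_count >= 5)

    def test_count_non_increasing_in_threshold(self, scene):
        energy = scene[0]
        counts = [
            s.count_peak_pixels(energy, t) for t in np.linspace(-5, 120, 30)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_accepted_set_shrinks_as_min_pixels_grows(self, tables):
        frames = [
            s.correct_frame(
                s.encode_raw(
                    s.generate_peaks_image(tables.shape, n, 100.0, 1.2, 1.0, seed=i)[0],
                    tables,
                ),
                tables,
            )
            for i, n in enumerate([0, 2, 5, 10, 20])
        ]
        prev = None
        for min_pix in [0, 5, 50, 200, 10**6]:
            accepted = {
                i
                for i, e in enumerate(frames)
                if s.veto(e, s.VetoConfig(50.0, min_pix))[0]
            }
            if prev is not None:
                assert accepted <= prev
            prev = accepted


class TestCSR:
    def test_worked_dense_example(self):
        dense = np.array([[0, 5, 0, 0], [0, 0, 0, 7], [0, 0, 0, 0]], np.float32)
        csr = s.csr_compress(s.EnergyFrame(values=dense), 0.0, capacity=10)
        assert csr.indptr.tolist() == [0, 1, 2, 2]
        assert csr.indices.tolist() == [1, 3]
        assert csr.data.tolist() == [5.0, 7.0]

    def test_all_zero_frame(self):
        csr = s.csr_compress(s.EnergyFrame(values=np.zeros((3, 4), np.float32)), 0.0, 5)
        assert csr.indptr.tolist() == [0, 0, 0, 0]
        assert csr.nnz == 0
        assert np.all(s.csr_decompress(csr).values == 0)

    def test_round_trip_equals_direct_thresholding(self, scene):
        energy = scene[0]
        thr = 20.0
        csr = s.csr_compress(energy, thr, capacity=energy.values.size)
        dense = s.csr_decompress(csr).values
        oracle = np.where(energy.values > thr, energy.values, 0.0).astype(np.float32)
        assert np.array_equal(dense, oracle)

    def test_matches_scipy_sparse_construction(self, scene):
        """Independent cross-check against scipy's CSR of the masked image."""
        energy = scene[0]
        thr = 15.0
        csr = s.csr_compress(energy, thr, capacity=energy.values.size)
        ref = scipy.sparse.csr_matrix(
            np.where(energy.values > thr, energy.values, 0.0).astype(np.float32)
        )
        assert np.array_equal(csr.indptr, ref.indptr.astype(np.int64))
        assert np.array_equal(csr.indices, ref.indices.astype(np.int32))
        assert np.array_equal(csr.data, ref.data)

    def test_capacity_overflow_names_required_capacity(self):
        vals = np.ones((4, 4), np.float32)
        with pytest.raises(s.CapacityOverflowError) as exc:
            s.csr_compress(s.EnergyFrame(values=vals), 0.0, capacity=3)
        assert exc.value.required == 16
        assert exc.value.capacity == 3
        assert "16" in str(exc.value)

    def test_nnz_conservation(self, scene):
        energy = scene[0]
        thr = 30.0
        retained = int(np.count_nonzero(energy.values > thr))
        csr = s.csr_compress(energy, thr, capacity=energy.values.size)
        assert csr.nnz == csr.indptr[-1] == retained

    def test_nan_pixels_never_stored(self):
        vals = np.full((2, 3), 9.0, np.float32)
        vals[0, 1] = np.nan
        csr = s.csr_compress(s.EnergyFrame(values=vals), 0.0, capacity=6)
        assert csr.nnz == 5

    def test_compress_decompress_idempotent(self, scene):
        csr = s.csr_compress(scene[0], 10.0, capacity=scene[0].values.size)
        again = s.csr_compress(s.csr_decompress(csr), 10.0, capacity=scene[0].values.size)
        assert np.array_equal(csr.indptr, again.indptr)
        assert np.array_equal(csr.indices, again.indices)
        assert np.array_equal(csr.data, again.data)

    def test_structural_validation_rejects_bad_indptr(self):
        with pytest.raises(s.ValidationError):
            s.CSRImage(
                shape=(2, 2),
                indptr=np.array([0, 2, 1], np.int64),
                indices=np.array([0], np.int32),
                data=np.array([1.0], np.float32),
                capacity=4,
            )

    @settings(max_examples=40, derandomize=True)
    @given(
        dense=hnp.arrays(
            np.float32,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=1, max_side=12),
            elements=st.floats(-10, 10, width=32),
        ),
        thr=st.floats(-5, 5, width=32),
    )
    def test_round_trip_property(self, dense, thr):
        e = s.EnergyFrame(values=dense)
        csr = s.csr_compress(e, float(thr), capacity=dense.size)
        back = s.csr_decompress(csr).values
        assert np.array_equal(back, np.where(dense > thr, dense, 0.0))
        assert csr.nnz == int(np.count_nonzero(dense > thr))
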