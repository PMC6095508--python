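"""Quantisation, stream coding, HDF5 container and rate control."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sparsimg as sp
from sparsimg import (
    CorruptContainerError,
    DomainSpec,
    PartitionSpec,
    PhantomSpec,
    QuantizerSpec,
    QuantizedDecomposition,
    SparseImageCode,
    decode_image,
    decode_streams,
    dequantize_magnitude,
    encode_image,
    encode_streams,
    generate_phantom,
    map_index_to_pair,
    map_pair_to_index,
    quantize_block,
    read_container,
    tune_delta,
    write_container,
)
from sparsimg.pursuit import BlockDecomposition


QS = QuantizerSpec(0.5, 1.3)  # theta = 0.65


class TestIndexMap:
    def test_first_pair_maps_to_one(self):
        assert map_pair_to_index(1, 1, 10) == 1

    def test_hand_evaluated_example(self):
        assert map_pair_to_index(2, 3, 10) == 13

    def test_bijection_exhaustive(self):
        seen = set()
        for lx in range(1, 8):
            for ly in range(1, 8):
                o = map_pair_to_index(lx, ly, 7)
                assert map_index_to_pair(o, 7) == (lx, ly)
                seen.add(o)
        assert seen == set(range(1, 50))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            map_pair_to_index(1, 11, 10)
        with pytest.raises(ValueError):
            map_index_to_pair(0, 10)


class TestQuantizer:
    def test_negative_coefficient_magnitude_and_sign(self):
        dec = BlockDecomposition([(1, 1)], np.array([-1.0]), 0.0, "x")
        qd = quantize_block(dec, QS, My=10)
        assert list(qd.magnitudes) == [1]  # ceil((1.0 - 0.65)/0.5) = ceil(0.7)
        assert list(qd.signs) == [1]

    def test_below_threshold_dropped(self):
        dec = BlockDecomposition([(1, 1)], np.array([0.6]), 0.0, "x")
        assert quantize_block(dec, QS, My=10).k == 0

    def test_boundary_magnitude_quantises_to_zero_and_is_dropped(self):
        dec = BlockDecomposition([(1, 1)], np.array([0.65]), 0.0, "x")
        assert quantize_block(dec, QS, My=10).k == 0

    def test_indices_sorted_with_consistent_reordering(self):
        dec = BlockDecomposition(
            [(2, 5), (1, 3), (1, 9)], np.array([1.5, -2.0, 3.0]), 0.0, "x"
        )
        qd = quantize_block(dec, QS, My=10)
        assert list(qd.indices) == [3, 9, 15]
        assert list(qd.signs) == [1, 0, 0]
        # magnitudes follow their indices: coefficients -2.0, 3.0, 1.5
        expect = [int(np.ceil((abs(c) - 0.65) / 0.5)) for c in (-2.0, 3.0, 1.5)]
        assert list(qd.magnitudes) == expect

    def test_dequantize_hand_values(self):
        assert dequantize_magnitude(1, QS) == pytest.approx(0.9)
        assert dequantize_magnitude(1, QuantizerSpec(1.0, 1.3)) == pytest.approx(1.8)
        with pytest.raises(ValueError):
            dequantize_magnitude(0, QS)

    @given(st.floats(min_value=0.66, max_value=1e4), st.floats(min_value=1e-3, max_value=5.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_reconstruction_within_half_delta(self, c_abs, delta):
        q = QuantizerSpec(delta, 1.3)
        m = sp.codec.quantize_magnitude(c_abs, q)
        if m >= 1:
            assert abs(dequantize_magnitude(m, q) - c_abs) <= delta / 2 + 1e-9

    def test_invalid_delta_rejected(self):
        with pytest.raises(ValueError):
            QuantizerSpec(0.0)


def qd(indices, mags=None, signs=None, bid=0):
    indices = np.asarray(indices, dtype=np.int64)
    if mags is None:
        mags = np.ones(len(indices), dtype=np.int64)
    if signs is None:
        signs = np.zeros(len(indices), dtype=np.uint8)
    return QuantizedDecomposition(indices, mags, signs, bid)


class TestStreams:
    def test_hand_traced_index_stream(self):
        code = encode_streams([qd([7]), qd([3, 10])], 2)
        assert list(code.st_ind) == [7, 0, 3, 7]

    def test_empty_first_block_convention(self):
        code = encode_streams([qd([]), qd([5])], 2)
        assert list(code.st_ind) == [0, 5]
        blocks = decode_streams(code)
        assert blocks[0].k == 0 and list(blocks[1].indices) == [5]

    def test_decode_inverts_hand_trace(self):
        code = SparseImageCode(
            np.array([7, 0, 3, 7]), np.array([2, 1, 4]), np.array([0, 1, 0]),
            {"Q": 2},
        )
        blocks = decode_streams(code)
        assert list(blocks[0].indices) == [7]
        assert list(blocks[1].indices) == [3, 10]
        assert list(blocks[1].magnitudes) == [1, 4]

    @given(st.lists(st.lists(st.integers(1, 500), unique=True, max_size=12), min_size=1, max_size=9), st.integers(0, 10_000))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_round_trip_on_random_valid_inputs(self, raw_blocks, seed):
        rng = np.random.default_rng(seed)
        blocks = []
        for bi, idx in enumerate(raw_blocks):
            idx = np.sort(np.asarray(idx, dtype=np.int64))
            blocks.append(
                qd(idx, rng.integers(1, 99, len(idx)), rng.integers(0, 2, len(idx)), bi)
            )
        code = encode_streams(blocks, len(blocks))
        # separator and positivity invariants
        assert int(np.count_nonzero(code.st_ind == 0)) == len(blocks) - 1
        assert np.all(code.st_ind[code.st_ind != 0] >= 1)
        back = decode_streams(code)
        for a, b in zip(blocks, back):
            assert np.array_equal(a.indices, b.indices)
            assert np.array_equal(a.magnitudes, b.magnitudes)
            assert np.array_equal(a.signs, b.signs)

    def test_separator_count_mismatch_detected(self):
        code = encode_streams([qd([7]), qd([3, 10])], 2)
        code.header["Q"] = 3
        with pytest.raises(CorruptContainerError):
            decode_streams(code)

    def test_index_overflow_detected(self):
        code = encode_streams([qd([7, 4000])], 1)
        code.header["max_index"] = 100
        with pytest.raises(CorruptContainerError):
            decode_streams(code)

    def test_non_ascending_indices_rejected_at_source(self):
        with pytest.raises(ValueError):
            qd([5, 5])
        with pytest.raises(ValueError):
            qd([5, 3])


def encode_phantom(seed, delta=0.05, domain="pixel", size=(32, 32)):
    img, _ = generate_phantom(PhantomSpec("atoms", size, seed=seed))
    pspec = PartitionSpec(size, 16)
    dspec = DomainSpec.pixel() if domain == "pixel" else DomainSpec.wavelet(levels=2)
    code = encode_image(img, pspec, dspec, None, QuantizerSpec(delta), target_psnr=60.0)
    return img, pspec, dspec, code


class TestImageCodec:
    def test_container_round_trip_bitwise(self, tmp_path):
        _, _, _, code = encode_phantom(0)
        p = tmp_path / "c.h5"
        write_container(code, p)
        back = read_container(p)
        assert np.array_equal(back.st_ind, code.st_ind)
        assert np.array_equal(back.st_cf, code.st_cf)
        assert np.array_equal(back.st_sg, code.st_sg)
        assert back.header["Q"] == code.header["Q"]
        # write -> read -> write is byte-stable on the stream payload
        p2 = tmp_path / "c2.h5"
        write_container(back, p2)
        b2 = read_container(p2)
        for a, b in ((back.st_ind, b2.st_ind), (back.st_cf, b2.st_cf), (back.st_sg, b2.st_sg)):
            assert np.array_equal(a, b)

    def test_container_adds_no_loss(self, tmp_path):
        img, _, _, code = encode_phantom(1)
        direct = decode_image(code, round_to_depth=False)
        p = tmp_path / "c.h5"
        write_container(code, p)
        via_file = decode_image(read_container(p), round_to_depth=False)
        assert np.array_equal(direct, via_file)

    def test_exactly_representable_image_decodes_sharp(self):
        # coefficients >> theta and a tiny step: quantisation error vanishes
        img, _, _, code = encode_phantom(2, delta=1e-3)
        decoded = decode_image(code, round_to_depth=False)
        assert sp.psnr(img, decoded) > 60.0

    def test_quantization_never_adds_coefficients(self, smooth128, pspec128):
        res = sp.approximate_image(smooth128, pspec128, DomainSpec.pixel(), None, 45.0)
        for delta in (0.5, 2.0, 8.0):
            code = encode_image(
                smooth128, pspec128, DomainSpec.pixel(), None,
                QuantizerSpec(delta), approx=res,
            )
            assert code.n_coefficients <= res.total_coefficients

    def test_bpp_decreases_with_lower_quality(self, smooth128, pspec128):
        codes = []
        for target in (50.0, 42.0, 36.0):
            rc = tune_delta(smooth128, pspec128, DomainSpec.pixel(), None, target)
            codes.append(sp.bits_per_pixel(rc.code))
        assert codes[0] >= codes[1] >= codes[2]

    def test_truncated_file_raises_corrupt_error(self, tmp_path):
        _, _, _, code = encode_phantom(3)
        p = tmp_path / "c.h5"
        write_container(code, p)
        data = p.read_bytes()
        p.write_bytes(data[: len(data) // 3])
        with pytest.raises(CorruptContainerError):
            read_container(p)


class TestRateControl:
    def test_target_psnr_reached_within_tolerance(self, smooth128, pspec128):
        rc = tune_delta(smooth128, pspec128, DomainSpec.pixel(), None, 45.0)
        assert rc.converged
        assert abs(rc.achieved_psnr - 45.0) <= 0.1

    def test_decoded_quality_monotone_in_delta(self, smooth128, pspec128):
        approx = sp.approximate_image(smooth128, pspec128, DomainSpec.pixel(), None, 45.0)
        vals = []
        for delta in np.geomspace(0.5, 50.0, 10):
            code = encode_image(
                smooth128, pspec128, DomainSpec.pixel(), None,
                QuantizerSpec(delta), approx=approx,
            )
            vals.append(sp.psnr(smooth128, decode_image(code, round_to_depth=False)))
        assert all(vals[i + 1] <= vals[i] + 0.05 for i in range(len(vals) - 1))

    def test_tiny_delta_recovers_unquantised_quality(self, smooth128, pspec128):
        approx = sp.approximate_image(smooth128, pspec128, DomainSpec.pixel(), None, 45.0)
        code = encode_image(
            smooth128, pspec128, DomainSpec.pixel(), None,
            QuantizerSpec(1e-4), approx=approx,
        )
        quant_psnr = sp.psnr(smooth128, decode_image(code, round_to_depth=False))
        assert abs(quant_psnr - approx.achieved_psnr) <= 0.05

    def test_unreachable_target_reported_not_raised(self, smooth128, pspec128):
        # the unquantised approximation at a 30 dB budget cannot reach 80 dB
        approx = sp.approximate_image(
            smooth128, pspec128, DomainSpec.pixel(), None, 30.0, psnr_margin=0.0,
            max_atoms=2,
        )
        rc = tune_delta(
            smooth128, pspec128, DomainSpec.pixel(), None, 80.0, approx=approx
        )
        assert not rc.converged
        assert rc.achieved_psnr < 80.0
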