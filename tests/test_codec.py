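"""End-to-end codec: bit packing, stream coding, segmentation, round trips."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnacodec import (
    CodecConfig,
    ConstraintParams,
    SidecarMetadata,
    audit_pool,
    baseline_two_bit_decode,
    baseline_two_bit_encode,
    bits_to_bytes,
    bytes_to_bits,
    decode_file,
    encode_file,
    encode_stream,
    gc_content,
    is_risk_free,
    read_pool_fasta,
    scan_frequencies,
    segment_payloads,
    select_codebook_params,
    write_pool_fasta,
)
from dnacodec.codec import EncodedRecord
from dnacodec.primer_weights import build_optimized_codebook


class TestBitPacking:
    @pytest.mark.parametrize(
        "data,bits",
        [(b"\x00", "00000000"), (b"\xa5", "10100101"), (b"", "")],
    )
    def test_examples(self, data, bits):
        assert bytes_to_bits(data) == bits
        assert bits_to_bytes(bits, len(bits)) == data

    @given(st.binary(max_size=200))
    @settings(max_examples=50, derandomize=True)
    def test_round_trip(self, data):
        bits = bytes_to_bits(data)
        assert bits_to_bytes(bits, len(bits)) == data

    def test_bit_count_mismatch(self):
        with pytest.raises(ValueError):
            bits_to_bytes("0101", 8)
        with pytest.raises(ValueError):
            bits_to_bytes("010101010", 9)  # not a whole byte


class TestStreamCoding:
    def test_single_string_stream(self):
        table = scan_frequencies("000000", 3)
        from dnacodec import PrimerLibrary

        cb = build_optimized_codebook(table, 2, PrimerLibrary([]))
        assert encode_stream("000000", cb) == "ACAC"

    def test_empty_stream(self):
        table = scan_frequencies("000", 3)
        from dnacodec import PrimerLibrary

        cb = build_optimized_codebook(table, 2, PrimerLibrary([]))
        assert encode_stream("", cb) == ""

    def test_unknown_block_rejected(self):
        table = scan_frequencies("000000", 3)
        from dnacodec import PrimerLibrary

        cb = build_optimized_codebook(table, 2, PrimerLibrary([]))
        with pytest.raises(ValueError):
            encode_stream("111", cb)

    def test_output_gc_within_window(self, params):
        rng = random.Random(4)
        bits = "".join(rng.choice("01") for _ in range(3000))
        _, _, table = select_codebook_params(bits)
        from dnacodec import PrimerLibrary, pad_stream

        cb = build_optimized_codebook(table, 2 if table.q <= 8 else 4, PrimerLibrary([]))
        dna = encode_stream(pad_stream(bits, table.l0), cb)
        assert params.gc_min <= gc_content(dna) <= params.gc_max


class TestSegmentation:
    def test_chunk_lengths(self):
        chunks = segment_payloads("A" * 450, 200)
        assert [len(c) for c in chunks] == [200, 200, 50]

    def test_exact_fit(self):
        assert segment_payloads("A" * 200, 200) == ["A" * 200]

    def test_concatenation_identity(self):
        seq = "ACGT" * 123
        assert "".join(segment_payloads(seq, 37)) == seq

    def test_minimum_payload_length(self):
        with pytest.raises(ValueError):
            segment_payloads("ACGT", 10)


class TestRoundTrip:
    @pytest.mark.parametrize("size", [1, 3, 17, 256, 4096])
    def test_byte_exact_round_trip(self, size, small_library):
        rng = random.Random(size)
        data = rng.randbytes(size)
        records, sidecar = encode_file(data, small_library)
        assert decode_file(records, sidecar) == data

    def test_compressible_file_round_trip(self, small_library):
        data = bytes([7, 7, 7, 13] * 800)
        records, sidecar = encode_file(data, small_library)
        assert decode_file(records, sidecar) == data
        assert sidecar.density["density"] > 2.0  # regular data beats 2 bits/nt

    def test_shuffled_records_decode_identically(self, small_library):
        data = random.Random(99).randbytes(2000)
        records, sidecar = encode_file(data, small_library)
        shuffled = list(records)
        random.Random(1).shuffle(shuffled)
        assert decode_file(shuffled, sidecar) == data

    def test_missing_record_is_a_distinct_error(self, small_library):
        data = random.Random(5).randbytes(2000)
        records, sidecar = encode_file(data, small_library)
        with pytest.raises(ValueError, match="missing record"):
            decode_file(records[:-1], sidecar)

    def test_corrupt_sidecar_rejected(self):
        with pytest.raises(ValueError, match="corrupt sidecar"):
            SidecarMetadata.from_json("{not json")

    def test_empty_file_rejected(self, small_library):
        with pytest.raises(ValueError):
            encode_file(b"", small_library)

    def test_round_trip_across_config_corners(self, small_library):
        data = random.Random(7).randbytes(600)
        for cfg in (
            CodecConfig(payload_nt=20),
            CodecConfig(payload_nt=500),
            CodecConfig(scan_min=5, scan_max=12),
            CodecConfig(max_interleave_iters=1),
        ):
            records, sidecar = encode_file(data, small_library, cfg)
            assert decode_file(records, sidecar) == data


class TestPoolProperties:
    def test_non_residual_payloads_are_risk_free(self, small_library, params):
        data = random.Random(21).randbytes(3000)
        records, _ = encode_file(data, small_library)
        for r in records:
            if not r.residual_risk:
                assert is_risk_free(r.payload, small_library, params)

    def test_achieved_density_never_exceeds_theoretical(self, small_library, params):
        data = random.Random(31).randbytes(3000)
        records, sidecar = encode_file(data, small_library)
        report = audit_pool(records, small_library, params, sidecar)
        agg = report["aggregate"]
        assert agg["achieved_density"] <= agg["theoretical_density"] + 1e-9

    def test_fasta_and_sidecar_byte_identical_across_runs(self, tmp_path, small_library):
        data = random.Random(41).randbytes(1500)
        outputs = []
        for run in range(2):
            records, sidecar = encode_file(data, small_library)
            pool = tmp_path / f"pool{run}.fasta"
            write_pool_fasta(records, pool)
            outputs.append((pool.read_bytes(), sidecar.to_json()))
        assert outputs[0] == outputs[1]

    def test_pool_fasta_round_trip(self, tmp_path, small_library):
        data = random.Random(51).randbytes(800)
        records, sidecar = encode_file(data, small_library)
        pool = tmp_path / "pool.fasta"
        write_pool_fasta(records, pool)
        again = read_pool_fasta(pool, sidecar)
        assert decode_file(again, sidecar) == data


class TestAudit:
    def _mk(self, index, payload):
        return EncodedRecord(index, payload, 0, 0, False)

    def test_clean_pool_has_zero_pairing_fraction(self, small_library, params):
        records = [self._mk(i, "ACGTACGTAC") for i in range(4)]
        report = audit_pool(records, small_library, params)
        assert report["aggregate"]["pairing_fraction"] == 0.0

    def test_one_risky_record_among_four(self, params):
        from dnacodec import PrimerLibrary

        lib = PrimerLibrary([("P1", "AATTGACGTATTGCTCGACC")])
        records = [self._mk(i, "ACGTACGTAC") for i in range(3)]
        records.append(self._mk(3, "ATGCTCGACCAT"))  # carries the 3' 8-mer
        report = audit_pool(records, lib, params)
        assert report["aggregate"]["pairing_fraction"] == pytest.approx(0.25)

    def test_aggregate_gc_is_length_weighted_mean(self, small_library, params):
        records = [self._mk(0, "ACGTAC"), self._mk(1, "GCGCATATGCGCAT")]
        report = audit_pool(records, small_library, params)
        total = sum(len(r.payload) for r in records)
        expected = sum(gc_content(r.payload) * len(r.payload) for r in records) / total
        assert report["aggregate"]["gc_mean"] == pytest.approx(expected)


class TestBaseline:
    def test_direct_table(self):
        assert baseline_two_bit_encode(bytes([0b00011011])) == "ACGT"

    def test_density_is_exactly_two(self):
        data = random.Random(61).randbytes(128)
        seq = baseline_two_bit_encode(data)
        assert 8 * len(data) / len(seq) == pytest.approx(2.0)

    def test_round_trip(self):
        data = random.Random(71).randbytes(333)
        assert baseline_two_bit_decode(baseline_two_bit_encode(data)) == data
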