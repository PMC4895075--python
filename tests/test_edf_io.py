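"""EDF reader/writer: round trips, size law, brute-force decode, errors."""

import io

import numpy as np
import pytest

from cloudwave import edf_io
from cloudwave.edf_io import ChannelSpec, DataRecordBlock, read_header, read_records, write_edf
from cloudwave.errors import CalibrationError, EDFFormatError, TruncationError

from conftest import make_header, random_recording


def brute_force_decode(payload: bytes):
    """Independent two-byte little-endian two's-complement decoder."""
    out = []
    for i in range(0, len(payload), 2):
        lo, hi = payload[i], payload[i + 1]
        v = lo + 256 * hi
        out.append(v - 65536 if v >= 32768 else v)
    return out


def write_to_bytes(header, specs, block) -> bytes:
    sink = io.BytesIO()
    edf_io.write_edf(header, specs, block, sink)
    return sink.getvalue()


class TestHeaderParsing:
    def test_header_bytes_scales_with_channel_count(self):
        specs = [ChannelSpec(label=f"C{i}", samples_per_record=2) for i in range(3)]
        header = make_header(3, 2)
        block = DataRecordBlock.from_channel_arrays(
            specs, [np.zeros(4, dtype=np.int64)] * 3
        )
        h, _ = read_header(write_to_bytes(header, specs, block))
        assert h.header_bytes == 1024  # 256 * (1 + 3)

    def test_duration_and_record_count_parse_identically(self, tmp_path):
        header = make_header(1, 300, 1.0)
        spec = ChannelSpec(label="C0", samples_per_record=4)
        block = DataRecordBlock.from_channel_arrays(
            [spec], [np.zeros(1200, dtype=np.int64)]
        )
        h, s = read_header(write_to_bytes(header, [spec], block))
        assert h.record_duration == 1.0
        assert h.n_data_records == 300
        assert s[0].samples_per_record == 4

    @pytest.mark.parametrize("seed", range(20))
    def test_write_read_round_trip_recovers_every_field(self, seed):
        header, specs, block = random_recording(np.random.default_rng(seed))
        h, s = read_header(write_to_bytes(header, specs, block))
        assert h == header
        assert s == specs

    def test_truncated_header_names_missing_field(self):
        with pytest.raises(EDFFormatError, match="start_date"):
            read_header(b" " * 170)

    def test_non_numeric_field_reports_byte_offset(self):
        header, specs, block = random_recording(np.random.default_rng(3), 2, 2)
        raw = bytearray(write_to_bytes(header, specs, block))
        raw[236:244] = b"oops    "  # n_data_records field
        with pytest.raises(EDFFormatError, match="236"):
            read_header(bytes(raw))

    def test_degenerate_digital_range_identifies_channel(self):
        header, specs, block = random_recording(np.random.default_rng(4), 2, 2)
        raw = write_to_bytes(header, specs, block)
        spec = specs[0]
        bad = ChannelSpec(**{**spec.__dict__, "digital_min": 5, "digital_max": 5})
        with pytest.raises(CalibrationError, match="channel 0"):
            read_header(write_to_bytes(header, [bad] + specs[1:], block))

    def test_non_ascii_header_byte_rejected(self):
        header, specs, block = random_recording(np.random.default_rng(5), 1, 1)
        raw = bytearray(write_to_bytes(header, specs, block))
        raw[10] = 0xE9
        with pytest.raises(EDFFormatError, match="non-ASCII"):
            read_header(bytes(raw))

    def test_unknown_record_count_inferred_from_payload(self, tmp_path):
        header, specs, block = random_recording(np.random.default_rng(6), 2, 10)
        path = tmp_path / "r.edf"
        write_edf(header, specs, block, path)
        known, _ = read_header(path)
        raw = bytearray(path.read_bytes())
        raw[236:244] = b"-1      "
        path.write_bytes(bytes(raw))
        inferred, _ = read_header(path)
        assert inferred.n_data_records == known.n_data_records

    def test_unknown_count_with_ragged_payload_is_an_error(self, tmp_path):
        rng = np.random.default_rng(8)
        header, specs, block = random_recording(rng, 2, 10)
        while block.n_records == 0 or edf_io.record_size_bytes(specs) < 3:
            header, specs, block = random_recording(rng, 2, 10)
        path = tmp_path / "r.edf"
        write_edf(header, specs, block, path)
        raw = bytearray(path.read_bytes())
        raw[236:244] = b"-1      "
        path.write_bytes(bytes(raw[:-1]))  # chop one byte off the payload
        with pytest.raises(EDFFormatError, match="whole number"):
            read_header(path)

    def test_two_digit_year_pivot(self):
        import datetime
        header, specs, block = random_recording(np.random.default_rng(9), 1, 0)
        for year, expected in [(1985, 1985), (1999, 1999), (2000, 2000), (2084, 2084)]:
            header.start_date = datetime.date(year, 6, 15)
            h, _ = read_header(write_to_bytes(header, specs, block))
            assert h.start_date.year == expected


class TestRecordDecoding:
    def test_empty_range_yields_empty_block(self):
        header, specs, block = random_recording(np.random.default_rng(10), 2, 5)
        raw = write_to_bytes(header, specs, block)
        out = read_records(raw, header, specs, 0, 0)
        assert out.n_records == 0 and out.total_samples == 0

    def test_constant_channel_decodes_to_the_written_value(self):
        spec = ChannelSpec(label="C0", samples_per_record=3)
        header = make_header(1, 4)
        block = DataRecordBlock.from_channel_arrays([spec], [np.full(12, 100)])
        out = read_records(write_to_bytes(header, [spec], block), header, [spec])
        assert np.all(out.data == 100)

    @pytest.mark.parametrize("seed", range(10))
    def test_total_decoded_count_forced_by_layout(self, seed):
        header, specs, block = random_recording(np.random.default_rng(seed + 20))
        out = read_records(write_to_bytes(header, specs, block), header, specs)
        assert out.total_samples == header.n_data_records * sum(
            s.samples_per_record for s in specs
        )

    @pytest.mark.parametrize("seed", range(15))
    def test_decode_matches_independent_brute_force_decoder(self, seed):
        header, specs, block = random_recording(np.random.default_rng(seed + 40), 4, 20)
        raw = write_to_bytes(header, specs, block)
        out = read_records(raw, header, specs)
        expected = brute_force_decode(raw[header.header_bytes :])
        assert out.data.reshape(-1).tolist() == expected

    def test_partial_range_streams_only_that_range(self):
        rng = np.random.default_rng(60)
        header, specs, block = random_recording(rng, 3, 15)
        while header.n_data_records < 6:
            header, specs, block = random_recording(rng, 3, 15)
        raw = write_to_bytes(header, specs, block)
        full = read_records(raw, header, specs)
        part = read_records(raw, header, specs, first=2, count=3)
        assert np.array_equal(part.data, full.data[2:5])
        assert part.first_record_index == 2

    def test_truncated_payload_reports_last_complete_record(self):
        rng = np.random.default_rng(62)
        header, specs, block = random_recording(rng, 2, 10)
        while header.n_data_records < 5:
            header, specs, block = random_recording(rng, 2, 10)
        raw = write_to_bytes(header, specs, block)
        cut = header.header_bytes + 3 * edf_io.record_size_bytes(specs) + 1
        with pytest.raises(TruncationError) as err:
            read_records(raw[:cut], header, specs)
        assert err.value.last_complete_record == 2

    def test_negative_count_is_a_usage_error(self):
        header, specs, block = random_recording(np.random.default_rng(64), 1, 2)
        with pytest.raises(ValueError, match="count"):
            read_records(b"", header, specs, 0, -1)

    def test_out_of_range_samples_are_retained_and_tallied(self):
        spec = ChannelSpec(label="C0", samples_per_record=4,
                           digital_min=-100, digital_max=100)
        header = make_header(1, 2)
        values = np.array([0, 150, -200, 5, 7, 101, -100, 100])
        block = DataRecordBlock.from_channel_arrays([spec], [values])
        out = read_records(write_to_bytes(header, [spec], block), header, [spec])
        assert out.out_of_range.tolist() == [3]
        assert out.data.reshape(-1).tolist() == values.tolist()


class TestWriter:
    def test_payload_size_law(self):
        spec = ChannelSpec(label="C0", samples_per_record=256)
        header = make_header(1, 10)
        block = DataRecordBlock.from_channel_arrays(
            [spec], [np.zeros(2560, dtype=np.int64)]
        )
        raw = write_to_bytes(header, [spec], block)
        assert len(raw) - header.header_bytes == 10 * 2 * 256 == 5120

    def test_zero_records_writes_header_only(self):
        header, specs, _ = random_recording(np.random.default_rng(70), 2, 0)
        header.n_data_records = 0
        block = DataRecordBlock.from_channel_arrays(
            specs, [np.zeros(0, dtype=np.int64) for _ in specs]
        )
        assert len(write_to_bytes(header, specs, block)) == header.header_bytes

    @pytest.mark.parametrize("seed", range(10))
    def test_double_round_trip_is_byte_identical(self, seed):
        header, specs, block = random_recording(np.random.default_rng(seed + 80))
        first = write_to_bytes(header, specs, block)
        h, s = read_header(first)
        b = read_records(first, h, s)
        second = write_to_bytes(h, s, b)
        assert first == second

    def test_oversized_field_names_the_field(self):
        header, specs, block = random_recording(np.random.default_rng(90), 1, 1)
        header.patient_id = "x" * 81
        with pytest.raises(EDFFormatError, match="patient_id"):
            write_to_bytes(header, specs, block)

    def test_sample_outside_int16_range_rejected(self):
        spec = ChannelSpec(label="C0", samples_per_record=1)
        header = make_header(1, 1)
        block = DataRecordBlock.from_channel_arrays([spec], [np.array([40000])])
        with pytest.raises(ValueError, match="16-bit"):
            write_to_bytes(header, [spec], block)


def test_cross_validation_against_mne(tmp_path, emu_small):
    """An independent EDF implementation reads our files to the same physical values."""
    mne = pytest.importorskip("mne")
    edf_path, _, truth = emu_small
    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="ERROR")
    assert set(raw.ch_names) == set(truth.digital)
    header, specs = read_header(edf_path)
    from cloudwave.transform import CalibrationParams
    for i, spec in enumerate(specs):
        # mne resamples lower-rate channels up to the max rate; compare on
        # the original sample grid by striding.
        stride = int(raw.info["sfreq"] * header.record_duration) // spec.samples_per_record
        got = raw.get_data(picks=[spec.label])[0][::stride]
        cal = CalibrationParams.from_spec(spec)
        expected = cal.to_physical(truth.digital[spec.label])
        if spec.physical_dimension == "uV":
            expected = expected * 1e-6  # mne reports EEG in volts
        elif spec.physical_dimension == "mV":
            expected = expected * 1e-3
        assert np.allclose(got[: len(expected)], expected, atol=cal.gain)
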