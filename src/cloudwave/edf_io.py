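"""Reading and writing European Data Format (EDF) files.

EDF stores a multichannel biosignal recording as a fixed-width ASCII header
(256 bytes of study metadata plus 256 bytes per signal of channel metadata)
followed by a sequence of *data records*: for each record duration, the
samples of channel 0, then channel 1, and so on, each encoded as
little-endian signed 16-bit integers.  Files range from megabytes to
gigabytes, so record payloads are read by seekable range rather than whole
files; :func:`read_records` touches only the bytes of the requested record
range.

Only plain EDF is handled: EDF+ annotation channels, BDF's 24-bit samples
and discontinuous recordings are out of scope.
"""

from __future__ import annotations

import datetime as _dt
import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Iterable, Sequence, Union

import numpy as np

from .errors import CalibrationError, EDFFormatError, TruncationError

ByteSource = Union[str, os.PathLike, bytes, bytearray, BinaryIO]

# (field name, byte width) in on-disk order.
_MAIN_FIELDS = (
    ("version", 8),
    ("patient_id", 80),
    ("recording_id", 80),
    ("start_date", 8),
    ("start_time", 8),
    ("header_bytes", 8),
    ("reserved", 44),
    ("n_data_records", 8),
    ("record_duration", 8),
    ("n_signals", 4),
)

# Channel metadata is stored field-blocked: all labels, then all transducers, ...
_SIGNAL_FIELDS = (
    ("label", 16),
    ("transducer", 80),
    ("physical_dimension", 8),
    ("physical_min", 8),
    ("physical_max", 8),
    ("digital_min", 8),
    ("digital_max", 8),
    ("prefiltering", 80),
    ("samples_per_record", 8),
    ("reserved", 32),
)

_DIGITAL_LIMIT = 32767  # signed 16-bit sample range is [-32768, 32767]


@dataclass
class EDFHeader:
    """Study-specific metadata from the 256-byte main header."""

    version: str = "0"
    patient_id: str = ""
    recording_id: str = ""
    start_date: _dt.date = _dt.date(2000, 1, 1)
    start_time: _dt.time = _dt.time(0, 0, 0)
    header_bytes: int = 0
    n_data_records: int = -1
    record_duration: float = 1.0
    n_signals: int = 0

    @property
    def start_datetime(self) -> _dt.datetime:
        return _dt.datetime.combine(self.start_date, self.start_time)

    @property
    def total_duration(self) -> float:
        """Recording length in seconds; requires a known record count."""
        if self.n_data_records < 0:
            raise ValueError("n_data_records is unknown (-1)")
        return self.n_data_records * self.record_duration


@dataclass
class ChannelSpec:
    """Channel-specific metadata: transducer, calibration extremes, sampling."""

    label: str
    transducer: str = ""
    physical_dimension: str = ""
    physical_min: float = -1.0
    physical_max: float = 1.0
    digital_min: int = -32768
    digital_max: int = 32767
    prefiltering: str = ""
    samples_per_record: int = 1

    def sampling_rate(self, record_duration: float) -> float:
        return self.samples_per_record / record_duration


@dataclass
class DataRecordBlock:
    """Raw samples for a contiguous run of data records, in on-disk order.

    ``data`` has shape ``(n_records, record_len)`` where ``record_len`` is the
    per-record sample total over all channels; ``channel_slices[c]`` selects
    channel *c*'s block within each record.  ``out_of_range`` counts, per
    channel, decoded values outside ``[digital_min, digital_max]`` — they are
    retained, never clipped.
    """

    first_record_index: int
    n_records: int
    data: np.ndarray
    channel_slices: list[slice]
    out_of_range: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.out_of_range is None:
            self.out_of_range = np.zeros(len(self.channel_slices), dtype=np.int64)

    @property
    def total_samples(self) -> int:
        return int(self.data.size)

    def record_channel(self, record: int, channel: int) -> np.ndarray:
        """Samples of one channel within one record (record index is block-local)."""
        return self.data[record, self.channel_slices[channel]]

    @classmethod
    def from_channel_arrays(
        cls,
        specs: Sequence[ChannelSpec],
        arrays: Sequence[np.ndarray],
        first_record_index: int = 0,
    ) -> "DataRecordBlock":
        """Interleave per-channel sample streams into EDF record layout."""
        if len(arrays) != len(specs):
            raise ValueError("one array per channel required")
        sprs = [s.samples_per_record for s in specs]
        n_records = None
        for arr, spr, spec in zip(arrays, sprs, specs):
            if len(arr) % spr:
                raise ValueError(
                    f"channel {spec.label!r}: {len(arr)} samples is not a whole "
                    f"number of records of {spr}"
                )
            n = len(arr) // spr
            if n_records is None:
                n_records = n
            elif n != n_records:
                raise ValueError("channels disagree on record count")
        n_records = n_records or 0
        record_len = sum(sprs)
        data = np.empty((n_records, record_len), dtype=np.int32)
        slices = _channel_slices(specs)
        for arr, sl, spr in zip(arrays, slices, sprs):
            data[:, sl] = np.asarray(arr).reshape(n_records, spr)
        return cls(first_record_index, n_records, data, slices)


def _channel_slices(specs: Sequence[ChannelSpec]) -> list[slice]:
    slices, off = [], 0
    for s in specs:
        slices.append(slice(off, off + s.samples_per_record))
        off += s.samples_per_record
    return slices


def _open(source: ByteSource):
    """Yield (binary file, should_close). Accepts paths, bytes and file objects."""
    if isinstance(source, (str, os.PathLike)):
        return open(source, "rb"), True
    if isinstance(source, (bytes, bytearray)):
        return io.BytesIO(source), True
    return source, False


def _ascii(raw: bytes, name: str, offset: int) -> str:
    try:
        return raw.decode("ascii").rstrip()
    except UnicodeDecodeError as exc:
        raise EDFFormatError(
            f"non-ASCII byte in header field '{name}' at byte offset {offset + exc.start}"
        ) from exc


def _as_int(text: str, name: str, offset: int) -> int:
    try:
        return int(text.strip())
    except ValueError:
        raise EDFFormatError(
            f"non-numeric content {text.strip()!r} in integer field '{name}' "
            f"at byte offset {offset}"
        ) from None


def _as_float(text: str, name: str, offset: int) -> float:
    try:
        return float(text.strip())
    except ValueError:
        raise EDFFormatError(
            f"non-numeric content {text.strip()!r} in numeric field '{name}' "
            f"at byte offset {offset}"
        ) from None


def _parse_date(text: str, offset: int) -> _dt.date:
    try:
        dd, mm, yy = (int(p) for p in text.strip().split("."))
    except ValueError:
        raise EDFFormatError(
            f"malformed start_date {text!r} at byte offset {offset} "
            "(expected dd.mm.yy)"
        ) from None
    # EDF two-digit year convention: 85-99 -> 1900s, 00-84 -> 2000s.
    year = 1900 + yy if yy >= 85 else 2000 + yy
    try:
        return _dt.date(year, mm, dd)
    except ValueError as exc:
        raise EDFFormatError(f"invalid start_date {text!r}: {exc}") from None


def _parse_time(text: str, offset: int) -> _dt.time:
    try:
        hh, mi, ss = (int(p) for p in text.strip().split("."))
        return _dt.time(hh, mi, ss)
    except ValueError:
        raise EDFFormatError(
            f"malformed start_time {text!r} at byte offset {offset} "
            "(expected hh.mm.ss)"
        ) from None


def record_size_bytes(specs: Sequence[ChannelSpec]) -> int:
    """On-disk size of one data record: two bytes per sample over all channels."""
    return 2 * sum(s.samples_per_record for s in specs)


def read_header(byte_source: ByteSource) -> tuple[EDFHeader, list[ChannelSpec]]:
    """Parse the main header and all channel subheaders.

    If ``n_data_records`` is recorded as -1 (unknown) and the source is
    seekable, the true count is inferred from the payload length; a payload
    that is not a whole number of records raises :class:`EDFFormatError`.
    """
    fh, close = _open(byte_source)
    try:
        main = fh.read(256)
        offset = 0
        values: dict[str, str] = {}
        for name, width in _MAIN_FIELDS:
            if len(main) < offset + width:
                raise EDFFormatError(
                    f"truncated header: missing field '{name}' "
                    f"(need {offset + width} bytes, have {len(main)})"
                )
            values[name] = _ascii(main[offset : offset + width], name, offset)
            offset += width

        header = EDFHeader(
            version=values["version"],
            patient_id=values["patient_id"],
            recording_id=values["recording_id"],
            start_date=_parse_date(values["start_date"], 168),
            start_time=_parse_time(values["start_time"], 176),
            header_bytes=_as_int(values["header_bytes"], "header_bytes", 184),
            n_data_records=_as_int(values["n_data_records"], "n_data_records", 236),
            record_duration=_as_float(values["record_duration"], "record_duration", 244),
            n_signals=_as_int(values["n_signals"], "n_signals", 252),
        )
        if header.n_signals < 1:
            raise EDFFormatError(f"n_signals must be >= 1, got {header.n_signals}")
        if header.record_duration <= 0:
            raise EDFFormatError(
                f"record_duration must be positive, got {header.record_duration}"
            )
        if header.header_bytes != 256 * (1 + header.n_signals):
            raise EDFFormatError(
                f"header_bytes field is {header.header_bytes} but "
                f"{header.n_signals} signals require {256 * (1 + header.n_signals)}"
            )
        if header.n_data_records < -1:
            raise EDFFormatError(
                f"n_data_records must be >= 0 or -1, got {header.n_data_records}"
            )

        ns = header.n_signals
        sub = fh.read(256 * ns)
        raw: dict[str, list[str]] = {}
        offset = 256
        for name, width in _SIGNAL_FIELDS:
            block: list[str] = []
            for i in range(ns):
                lo = offset - 256
                if len(sub) < lo + width:
                    raise EDFFormatError(
                        f"truncated header: missing field '{name}' for signal {i}"
                    )
                block.append(_ascii(sub[lo : lo + width], name, offset))
                offset += width
            raw[name] = block

        field_offsets = {}
        off = 256
        for name, width in _SIGNAL_FIELDS:
            field_offsets[name] = (off, width)
            off += width * ns

        specs = []
        for i in range(ns):
            def at(name):  # byte offset of signal i's copy of a field
                base, width = field_offsets[name]
                return base + i * width

            spec = ChannelSpec(
                label=raw["label"][i],
                transducer=raw["transducer"][i],
                physical_dimension=raw["physical_dimension"][i],
                physical_min=_as_float(raw["physical_min"][i], "physical_min", at("physical_min")),
                physical_max=_as_float(raw["physical_max"][i], "physical_max", at("physical_max")),
                digital_min=_as_int(raw["digital_min"][i], "digital_min", at("digital_min")),
                digital_max=_as_int(raw["digital_max"][i], "digital_max", at("digital_max")),
                prefiltering=raw["prefiltering"][i],
                samples_per_record=_as_int(
                    raw["samples_per_record"][i], "samples_per_record", at("samples_per_record")
                ),
            )
            if spec.digital_min == spec.digital_max:
                raise CalibrationError(
                    f"channel {i} ({spec.label!r}): digital_min == digital_max "
                    f"== {spec.digital_min}; calibration is undefined"
                )
            if spec.digital_min > spec.digital_max:
                raise CalibrationError(
                    f"channel {i} ({spec.label!r}): digital_min {spec.digital_min} "
                    f"> digital_max {spec.digital_max}"
                )
            if spec.physical_min == spec.physical_max:
                raise CalibrationError(
                    f"channel {i} ({spec.label!r}): physical_min == physical_max "
                    f"== {spec.physical_min}; calibration is undefined"
                )
            if spec.samples_per_record < 1:
                raise EDFFormatError(
                    f"channel {i} ({spec.label!r}): samples_per_record must be "
                    f">= 1, got {spec.samples_per_record}"
                )
            specs.append(spec)

        if header.n_data_records == -1 and fh.seekable():
            pos = fh.tell()
            fh.seek(0, os.SEEK_END)
            payload = fh.tell() - header.header_bytes
            fh.seek(pos)
            rec_bytes = record_size_bytes(specs)
            if payload % rec_bytes:
                raise EDFFormatError(
                    f"n_data_records is -1 and payload of {payload} bytes is not "
                    f"a whole number of {rec_bytes}-byte records"
                )
            header.n_data_records = payload // rec_bytes

        return header, specs
    finally:
        if close:
            fh.close()


def read_records(
    byte_source: ByteSource,
    header: EDFHeader,
    specs: Sequence[ChannelSpec],
    first: int = 0,
    count: int | None = None,
) -> DataRecordBlock:
    """Decode ``count`` data records starting at record index ``first``.

    Only the requested byte range is read, so record ranges of arbitrarily
    large files can be streamed.  Values outside each channel's digital range
    are retained and tallied in the block's ``out_of_range`` counters.
    """
    if count is None:
        count = max(header.n_data_records - first, 0)
    if first < 0:
        raise ValueError(f"first must be >= 0, got {first}")
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    if header.n_data_records >= 0 and first + count > header.n_data_records:
        raise ValueError(
            f"record range [{first}, {first + count}) exceeds "
            f"n_data_records == {header.n_data_records}"
        )
    slices = _channel_slices(specs)
    rec_bytes = record_size_bytes(specs)
    record_len = rec_bytes // 2
    if count == 0:
        return DataRecordBlock(first, 0, np.empty((0, record_len), np.int16), slices)

    fh, close = _open(byte_source)
    try:
        fh.seek(header.header_bytes + first * rec_bytes)
        raw = fh.read(count * rec_bytes)
    finally:
        if close:
            fh.close()
    if len(raw) < count * rec_bytes:
        complete = len(raw) // rec_bytes
        raise TruncationError(
            f"payload ends inside record range [{first}, {first + count}): last "
            f"complete record index is {first + complete - 1}",
            last_complete_record=first + complete - 1,
        )
    data = np.frombuffer(raw, dtype="<i2").reshape(count, record_len)
    block = DataRecordBlock(first, count, data, slices)
    for c, (spec, sl) in enumerate(zip(specs, slices)):
        ch = data[:, sl]
        block.out_of_range[c] = int(
            np.count_nonzero((ch < spec.digital_min) | (ch > spec.digital_max))
        )
    return block


def iter_record_blocks(
    byte_source: ByteSource,
    header: EDFHeader,
    specs: Sequence[ChannelSpec],
    records_per_block: int,
) -> Iterable[DataRecordBlock]:
    """Stream the whole payload in blocks of at most ``records_per_block`` records."""
    first = 0
    total = header.n_data_records
    while first < total:
        n = min(records_per_block, total - first)
        yield read_records(byte_source, header, specs, first, n)
        first += n


def _format_text(value: str, width: int, name: str) -> bytes:
    try:
        raw = value.encode("ascii")
    except UnicodeEncodeError:
        raise EDFFormatError(f"field '{name}' contains non-ASCII characters") from None
    if len(raw) > width:
        raise EDFFormatError(
            f"field '{name}' value {value!r} exceeds its fixed width of {width} bytes"
        )
    return raw.ljust(width)


def _format_number(value, width: int, name: str) -> bytes:
    if isinstance(value, float) and value == int(value):
        text = str(int(value))
    else:
        text = repr(value) if isinstance(value, float) else str(value)
    if len(text) > width:
        raise EDFFormatError(
            f"field '{name}' value {text!r} exceeds its fixed width of {width} bytes"
        )
    return text.encode("ascii").ljust(width)


def write_edf(
    header: EDFHeader,
    specs: Sequence[ChannelSpec],
    records: DataRecordBlock,
    byte_sink: Union[str, os.PathLike, BinaryIO],
) -> int:
    """Serialize a recording; returns bytes written.

    The output reads back with exact value recovery, and a write→read→write
    cycle is byte-identical.  Fields wider than their fixed ASCII widths and
    samples outside the signed 16-bit range are rejected.
    """
    ns = len(specs)
    if header.n_signals != ns:
        raise EDFFormatError(
            f"header.n_signals == {header.n_signals} but {ns} channel specs given"
        )
    if header.n_data_records != records.n_records:
        raise ValueError(
            f"header.n_data_records == {header.n_data_records} but block holds "
            f"{records.n_records} records"
        )
    if not (1985 <= header.start_date.year <= 2084):
        raise EDFFormatError(
            f"start_date year {header.start_date.year} cannot be written as a "
            "two-digit EDF year (1985-2084)"
        )
    data = np.asarray(records.data)
    if data.size and (data.min() < -32768 or data.max() > _DIGITAL_LIMIT):
        raise ValueError("sample value outside signed 16-bit range [-32768, 32767]")

    parts = [
        _format_text(header.version or "0", 8, "version"),
        _format_text(header.patient_id, 80, "patient_id"),
        _format_text(header.recording_id, 80, "recording_id"),
        header.start_date.strftime("%d.%m.%y").encode(),
        header.start_time.strftime("%H.%M.%S").encode(),
        _format_number(256 * (1 + ns), 8, "header_bytes"),
        b" " * 44,
        _format_number(header.n_data_records, 8, "n_data_records"),
        _format_number(float(header.record_duration), 8, "record_duration"),
        _format_number(ns, 4, "n_signals"),
    ]
    for name, width in _SIGNAL_FIELDS:
        for i, s in enumerate(specs):
            qname = f"{name}[{i}]"
            if name == "reserved":
                parts.append(b" " * width)
            elif name in ("physical_min", "physical_max"):
                parts.append(_format_number(float(getattr(s, name)), width, qname))
            elif name in ("digital_min", "digital_max", "samples_per_record"):
                parts.append(_format_number(int(getattr(s, name)), width, qname))
            else:
                parts.append(_format_text(getattr(s, name), width, qname))
    blob = b"".join(parts) + data.astype("<i2").tobytes()

    if isinstance(byte_sink, (str, os.PathLike)):
        with open(byte_sink, "wb") as fh:
            fh.write(blob)
    else:
        byte_sink.write(blob)
    return len(blob)
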