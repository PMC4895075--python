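"""Epoch planning: split a recording into fixed-duration logical segments.

A recording of ``n_data_records`` records, each ``record_duration`` seconds
long, is tiled by epochs of a configurable duration (default 30 s).  The
epoch duration must be an integer multiple of the record duration so that
data records are never split; a trailing shorter epoch is emitted (flagged
``is_partial``) rather than dropped, so the plan always conserves every
sample.  Planning is pure arithmetic and fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .edf_io import ChannelSpec, DataRecordBlock, EDFHeader
from .errors import ConfigurationError

DEFAULT_EPOCH_SECONDS = 30.0


@dataclass(frozen=True)
class EpochEntry:
    segment_index: int
    first_record: int
    n_records: int
    start_time: float
    end_time: float
    is_partial: bool

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass
class EpochPlan:
    epoch_duration: float
    records_per_epoch: int
    entries: list[EpochEntry]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)


def plan_epochs(header: EDFHeader, epoch_duration: float = DEFAULT_EPOCH_SECONDS) -> EpochPlan:
    """Tile ``[0, n_data_records)`` with contiguous non-overlapping epochs.

    Raises :class:`ConfigurationError` if ``epoch_duration`` is not a positive
    integer multiple of the record duration, or the record count is unknown.
    """
    rd = header.record_duration
    if epoch_duration <= 0:
        raise ConfigurationError(f"epoch_duration must be positive, got {epoch_duration}")
    ratio = epoch_duration / rd
    records_per_epoch = round(ratio)
    if records_per_epoch < 1 or abs(ratio - records_per_epoch) > 1e-9 * max(1.0, ratio):
        raise ConfigurationError(
            f"epoch_duration ({epoch_duration} s) must be a positive integer "
            f"multiple of the EDF record_duration ({rd} s)"
        )
    if header.n_data_records < 0:
        raise ConfigurationError("cannot plan epochs: n_data_records is unknown (-1)")

    entries: list[EpochEntry] = []
    n = header.n_data_records
    first = 0
    index = 0
    while first < n:
        n_rec = min(records_per_epoch, n - first)
        entries.append(
            EpochEntry(
                segment_index=index,
                first_record=first,
                n_records=n_rec,
                start_time=first * rd,
                end_time=(first + n_rec) * rd,
                is_partial=n_rec < records_per_epoch,
            )
        )
        first += n_rec
        index += 1
    return EpochPlan(epoch_duration, records_per_epoch, entries)


@dataclass
class RawSegment:
    """Sample-oriented data for one epoch, plus per-channel sample counts."""

    entry: EpochEntry
    block: DataRecordBlock
    channel_sample_counts: list[int]


def extract_segment(
    records_reader: Callable[[int, int], DataRecordBlock],
    plan_entry: EpochEntry,
    specs: Sequence[ChannelSpec],
) -> RawSegment:
    """Read exactly the entry's record range through ``records_reader``.

    ``records_reader(first, count)`` is expected to read lazily (e.g. a
    partial application of :func:`cloudwave.edf_io.read_records`), so only
    the epoch's records are loaded.
    """
    if plan_entry.n_records <= 0:
        raise ValueError(
            f"segment {plan_entry.segment_index} has no data records"
        )
    block = records_reader(plan_entry.first_record, plan_entry.n_records)
    if block.n_records != plan_entry.n_records:
        raise ConfigurationError(
            f"reader returned {block.n_records} records for segment "
            f"{plan_entry.segment_index}, expected {plan_entry.n_records}"
        )
    counts = [plan_entry.n_records * s.samples_per_record for s in specs]
    return RawSegment(plan_entry, block, counts)
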