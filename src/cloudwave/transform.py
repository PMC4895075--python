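"""Channel-oriented layout transform and digital→physical calibration.

EDF interleaves channels inside each data record, which is hostile to
per-channel access and montage composition.  The layout transform gathers
each channel's per-record blocks into one contiguous stream — a pure
permutation that preserves every sample.  Calibration is the standard EDF
affine map from ADC integers to physical units,

    physical = physical_min + gain * (d - digital_min),
    gain     = (physical_max - physical_min) / (digital_max - digital_min),

which sends ``digital_min`` to ``physical_min`` and ``digital_max`` to
``physical_max`` exactly.  Out-of-range digital values convert linearly —
never clipped — and are tallied upstream at decode time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .edf_io import ChannelSpec, DataRecordBlock
from .errors import CalibrationError, CorruptionError
from .partition import RawSegment


@dataclass
class CalibrationParams:
    """Affine digital→physical map defined by the channel's four extremes."""

    physical_min: float
    physical_max: float
    digital_min: int
    digital_max: int
    gain: float = field(init=False)
    offset: float = field(init=False)

    def __post_init__(self):
        if self.digital_max == self.digital_min:
            raise CalibrationError("digital_min == digital_max: gain undefined")
        if self.physical_max == self.physical_min:
            raise CalibrationError("physical_min == physical_max: gain is zero")
        self.gain = (self.physical_max - self.physical_min) / (
            self.digital_max - self.digital_min
        )
        self.offset = self.physical_min - self.gain * self.digital_min

    @classmethod
    def from_spec(cls, spec: ChannelSpec) -> "CalibrationParams":
        return cls(spec.physical_min, spec.physical_max, spec.digital_min, spec.digital_max)

    def to_physical(self, d):
        """Elementwise affine conversion; accepts scalars or arrays.

        Evaluated as ``pmin*(1-r) + pmax*r`` with ``r = (d-dmin)/(dmax-dmin)``,
        which is algebraically the affine map but bit-exact at both calibration
        endpoints (r is exactly 0 or 1 there), unlike the ``pmin + gain*(d-dmin)``
        form whose rounding can miss ``physical_max`` by an ulp.
        """
        r = (np.asarray(d, dtype=np.float64) - self.digital_min) / (
            self.digital_max - self.digital_min
        )
        return self.physical_min * (1.0 - r) + self.physical_max * r

    def to_digital(self, p):
        """Inverse map, rounded to nearest integer (exact for in-range values)."""
        d = np.rint((np.asarray(p, dtype=np.float64) - self.physical_min) / self.gain) + self.digital_min
        return d.astype(np.int64)


def digital_to_physical(d, cal: CalibrationParams):
    """physical_min + gain * (d - digital_min); scalar in, scalar out."""
    out = cal.to_physical(d)
    return float(out) if np.isscalar(d) or np.ndim(out) == 0 else out


def to_channel_oriented(
    raw_segment: RawSegment | DataRecordBlock, specs: Sequence[ChannelSpec]
) -> list[np.ndarray]:
    """Gather each channel's record blocks into one contiguous integer array.

    For channel *c* the output is the concatenation, in record order, of that
    record's channel-*c* block — the layout montage composition and
    single-channel visualization need.
    """
    block = raw_segment.block if isinstance(raw_segment, RawSegment) else raw_segment
    record_len = sum(s.samples_per_record for s in specs)
    if block.data.ndim != 2 or block.data.shape[1] != record_len:
        raise CorruptionError(
            f"record length {block.data.shape[-1] if block.data.ndim else 0} does "
            f"not match channel specs total {record_len}"
        )
    out = []
    off = 0
    for spec in specs:
        out.append(np.ascontiguousarray(block.data[:, off : off + spec.samples_per_record]).reshape(-1))
        off += spec.samples_per_record
    return out


@dataclass
class ChannelSeries:
    """One channel's contiguous, physically calibrated samples for a segment."""

    label: str
    unit: str
    sampling_rate: float
    values: np.ndarray
    digital: np.ndarray | None = None  # kept only when raw emission is requested

    @property
    def n_samples(self) -> int:
        return int(len(self.values))


def build_channel_series(
    raw_segment: RawSegment,
    specs: Sequence[ChannelSpec],
    record_duration: float,
    keep_digital: bool = False,
) -> list[ChannelSeries]:
    """Layout transform + calibration: one :class:`ChannelSeries` per channel."""
    gathered = to_channel_oriented(raw_segment, specs)
    series = []
    for spec, dig in zip(specs, gathered):
        expected = raw_segment.entry.n_records * spec.samples_per_record
        if len(dig) != expected:
            raise CorruptionError(
                f"channel {spec.label!r}: gathered {len(dig)} samples, expected {expected}"
            )
        cal = CalibrationParams.from_spec(spec)
        series.append(
            ChannelSeries(
                label=spec.label,
                unit=spec.physical_dimension,
                sampling_rate=spec.sampling_rate(record_duration),
                values=cal.to_physical(dig),
                digital=np.asarray(dig) if keep_digital else None,
            )
        )
    return series
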