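"""Cloudwave Signal Format (CSF): a self-descriptive JSON signal container.

A CSF document bundles study metadata, channel metadata, and a small fixed
number of signal segments (two 30-s epochs by default) so each file can be
stored, accessed and queried independently of the source EDF.  Everything is
attribute-value JSON with nesting:

* top level — ``format_version``, ``study``, ``channels``, ``segment_count``,
  ``segments``;
* per segment — ``sequence_number``, ``start_time``, ``end_time``,
  ``absolute_start`` (ISO-8601, EDF header clock taken as naive local time),
  ``partial``, ``annotations``, and ``data``: per-channel sample arrays in
  physical units keyed by channel label (labels are de-duplicated by
  suffixing, since JSON keys must be unique).

Unknown attributes found on read are preserved and re-emitted on write, so
documents from newer format revisions survive a round trip.  The normative
schema ships with the package as ``csf_schema.json``.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .annotation import ClinicalAnnotation
from .edf_io import ChannelSpec, EDFHeader
from .transform import ChannelSeries

FORMAT_VERSION = "1.0"
DEFAULT_SEGMENTS_PER_FILE = 2

_SEGMENT_KEYS = {
    "sequence_number",
    "start_time",
    "end_time",
    "absolute_start",
    "partial",
    "annotations",
    "data",
    "digital",
}
_TOP_KEYS = {"format_version", "study", "channels", "segment_count", "segments"}


def dedupe_labels(labels: Sequence[str]) -> list[str]:
    """Make labels unique by suffixing ``_2``, ``_3``, ... on collision."""
    seen: dict[str, int] = {}
    out = []
    for label in labels:
        if label not in seen:
            seen[label] = 1
            out.append(label)
        else:
            seen[label] += 1
            candidate = f"{label}_{seen[label]}"
            while candidate in seen:
                seen[label] += 1
                candidate = f"{label}_{seen[label]}"
            seen[candidate] = 1
            out.append(candidate)
    return out


@dataclass
class SignalSegment:
    """One epoch of channel-oriented physical data plus overlapping annotations."""

    sequence_number: int
    start_time: float
    end_time: float
    absolute_start: _dt.datetime
    channels: list[ChannelSeries]
    annotations: list[ClinicalAnnotation] = field(default_factory=list)
    is_partial: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass
class CSFDocument:
    """A serializable container of consecutive signal segments and metadata."""

    study: dict
    channels: list[dict]
    segments: list[SignalSegment]
    format_version: str = FORMAT_VERSION
    extra: dict = field(default_factory=dict)

    @property
    def segment_count(self) -> int:
        return len(self.segments)


def study_metadata(header: EDFHeader, source_file: str = "") -> dict:
    return {
        "recording_id": header.recording_id,
        "patient_id": header.patient_id,
        "start_datetime": header.start_datetime.isoformat(),
        "record_duration": header.record_duration,
        "n_signals": header.n_signals,
        "source_file": source_file,
    }


def channel_metadata(specs: Sequence[ChannelSpec], record_duration: float) -> list[dict]:
    labels = dedupe_labels([s.label for s in specs])
    out = []
    for label, s in zip(labels, specs):
        out.append(
            {
                "label": label,
                "transducer": s.transducer,
                "unit": s.physical_dimension,
                "physical_min": s.physical_min,
                "physical_max": s.physical_max,
                "digital_min": s.digital_min,
                "digital_max": s.digital_max,
                "prefiltering": s.prefiltering,
                "samples_per_record": s.samples_per_record,
                "sampling_rate": s.samples_per_record / record_duration,
            }
        )
    return out


def pack_segments(
    segments: Sequence[SignalSegment],
    segments_per_file: int = DEFAULT_SEGMENTS_PER_FILE,
    study: dict | None = None,
    channels: list[dict] | None = None,
) -> list[CSFDocument]:
    """Group consecutive segments into documents of ``segments_per_file`` each.

    Every document except possibly the last holds exactly ``segments_per_file``
    segments; with *n* segments the result has ``ceil(n / segments_per_file)``
    documents.  Segments must arrive ordered by sequence number with no
    duplicates.
    """
    if segments_per_file < 1:
        raise ValueError(f"segments_per_file must be >= 1, got {segments_per_file}")
    seqs = [s.sequence_number for s in segments]
    if any(b <= a for a, b in zip(seqs, seqs[1:])):
        raise ValueError("segments must be strictly ordered by sequence_number")
    docs = []
    for i in range(0, len(segments), segments_per_file):
        docs.append(
            CSFDocument(
                study=dict(study or {}),
                channels=list(channels or []),
                segments=list(segments[i : i + segments_per_file]),
            )
        )
    return docs


def _round_values(values: np.ndarray, precision: int | None) -> list[float]:
    arr = np.asarray(values, dtype=np.float64)
    if precision is not None:
        arr = np.round(arr, precision)
    return arr.tolist()


def _segment_to_json(seg: SignalSegment, precision: int | None) -> dict:
    labels = dedupe_labels([c.label for c in seg.channels])
    data = {lbl: _round_values(c.values, precision) for lbl, c in zip(labels, seg.channels)}
    obj = {
        "sequence_number": seg.sequence_number,
        "start_time": seg.start_time,
        "end_time": seg.end_time,
        "absolute_start": seg.absolute_start.isoformat(),
        "partial": seg.is_partial,
        "annotations": [
            {
                "onset": a.onset,
                "duration": a.duration,
                "text": a.text,
                "ontology_term": a.ontology_term,
            }
            for a in seg.annotations
        ],
        "data": data,
    }
    digital = {
        lbl: np.asarray(c.digital).tolist()
        for lbl, c in zip(labels, seg.channels)
        if c.digital is not None
    }
    if digital:
        obj["digital"] = digital
    obj.update(seg.extra)
    return obj


def document_to_json(doc: CSFDocument, precision: int | None = None) -> dict:
    obj = {
        "format_version": doc.format_version,
        "study": doc.study,
        "channels": doc.channels,
        "segment_count": doc.segment_count,
        "segments": [_segment_to_json(s, precision) for s in doc.segments],
    }
    obj.update(doc.extra)
    return obj


def write_csf(
    doc: CSFDocument,
    sink: Union[str, os.PathLike],
    precision: int | None = None,
) -> None:
    """Serialize one document to UTF-8 JSON (conventionally a ``.csf`` file).

    ``precision`` limits signal values to that many decimal places; ``None``
    keeps the shortest representation that round-trips the binary float.
    """
    text = json.dumps(document_to_json(doc, precision), ensure_ascii=False)
    with open(sink, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)
        fh.write("\n")


def _segment_from_json(obj: dict, rate_by_label: dict, unit_by_label: dict) -> SignalSegment:
    annotations = [
        ClinicalAnnotation(
            onset=a["onset"],
            duration=a["duration"],
            text=a["text"],
            ontology_term=a.get("ontology_term"),
        )
        for a in obj.get("annotations", [])
    ]
    digital = obj.get("digital", {})
    channels = [
        ChannelSeries(
            label=lbl,
            unit=unit_by_label.get(lbl, ""),
            sampling_rate=rate_by_label.get(lbl, float("nan")),
            values=np.asarray(vals, dtype=np.float64),
            digital=np.asarray(digital[lbl]) if lbl in digital else None,
        )
        for lbl, vals in obj.get("data", {}).items()
    ]
    return SignalSegment(
        sequence_number=obj["sequence_number"],
        start_time=obj["start_time"],
        end_time=obj["end_time"],
        absolute_start=_dt.datetime.fromisoformat(obj["absolute_start"]),
        channels=channels,
        annotations=annotations,
        is_partial=obj.get("partial", False),
        extra={k: v for k, v in obj.items() if k not in _SEGMENT_KEYS},
    )


def read_csf(source: Union[str, os.PathLike]) -> CSFDocument:
    """Parse a CSF document; unknown attributes are kept in ``extra``."""
    with open(source, "r", encoding="utf-8") as fh:
        obj = json.load(fh)
    channels = obj.get("channels", [])
    rate_by_label = {c.get("label"): c.get("sampling_rate") for c in channels}
    unit_by_label = {c.get("label"): c.get("unit", "") for c in channels}
    return CSFDocument(
        study=obj.get("study", {}),
        channels=channels,
        segments=[
            _segment_from_json(s, rate_by_label, unit_by_label)
            for s in obj.get("segments", [])
        ],
        format_version=obj.get("format_version", FORMAT_VERSION),
        extra={k: v for k, v in obj.items() if k not in _TOP_KEYS},
    )


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    path: str  # JSON-path-like locator, e.g. "doc.csf:segments[1].end_time"
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    def add(self, severity: str, path: str, message: str) -> None:
        self.findings.append(Finding(severity, path, message))

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors


def _validate_document_obj(obj: dict, where: str, report: ValidationReport) -> None:
    for key, typ in (
        ("format_version", str),
        ("study", dict),
        ("channels", list),
        ("segment_count", int),
        ("segments", list),
    ):
        if key not in obj:
            report.add("error", f"{where}:{key}", f"missing required key '{key}'")
        elif not isinstance(obj[key], typ):
            report.add(
                "error", f"{where}:{key}",
                f"expected {typ.__name__}, got {type(obj[key]).__name__}",
            )
    segments = obj.get("segments")
    if not isinstance(segments, list):
        return
    if isinstance(obj.get("segment_count"), int) and obj["segment_count"] != len(segments):
        report.add(
            "error", f"{where}:segment_count",
            f"segment_count is {obj['segment_count']} but {len(segments)} segments present",
        )
    rate_by_label = {
        c.get("label"): c.get("sampling_rate")
        for c in obj.get("channels", [])
        if isinstance(c, dict)
    }
    prev_seq = None
    for i, seg in enumerate(segments):
        loc = f"{where}:segments[{i}]"
        if not isinstance(seg, dict):
            report.add("error", loc, "segment is not a JSON object")
            continue
        for key in ("sequence_number", "start_time", "end_time", "absolute_start", "data"):
            if key not in seg:
                report.add("error", f"{loc}.{key}", f"missing required key '{key}'")
        start, end = seg.get("start_time"), seg.get("end_time")
        if isinstance(start, (int, float)) and isinstance(end, (int, float)):
            if end <= start:
                report.add("error", f"{loc}.end_time", f"end_time {end} <= start_time {start}")
            elif not seg.get("partial", False):
                duration = end - start
                for label, vals in (seg.get("data") or {}).items():
                    rate = rate_by_label.get(label)
                    if rate is None:
                        report.add(
                            "error", f"{loc}.data.{label}",
                            "channel not declared in document channel metadata",
                        )
                        continue
                    expected = rate * duration
                    if abs(len(vals) - expected) > 1e-6:
                        report.add(
                            "error", f"{loc}.data.{label}",
                            f"{len(vals)} samples contradicts sampling_rate {rate} Hz "
                            f"x duration {duration} s == {expected}",
                        )
        seq = seg.get("sequence_number")
        if isinstance(seq, int):
            if prev_seq is not None and seq <= prev_seq:
                report.add(
                    "error", f"{loc}.sequence_number",
                    f"sequence_number {seq} not increasing after {prev_seq}",
                )
            prev_seq = seq
        absolute = seg.get("absolute_start")
        if isinstance(absolute, str):
            try:
                _dt.datetime.fromisoformat(absolute)
            except ValueError:
                report.add("error", f"{loc}.absolute_start", f"not ISO-8601: {absolute!r}")


def validate_csf(source: Union[str, os.PathLike]) -> ValidationReport:
    """Validate one ``.csf`` file, or a directory of them.

    Checks JSON well-formedness, schema conformance, per-segment invariants
    (positive duration; for non-partial segments, per-channel sample count
    equals sampling rate x duration) and, for directories, sequence-number
    continuity per source recording.  Findings carry severities; nothing is
    raised.
    """
    report = ValidationReport()
    path = Path(source)
    files = sorted(path.glob("*.csf")) if path.is_dir() else [path]
    if path.is_dir() and not files:
        report.add("warning", str(path), "no .csf files found")
        return report

    by_recording: dict[str, list[int]] = {}
    for f in files:
        where = f.name
        try:
            with open(f, "r", encoding="utf-8") as fh:
                obj = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            report.add("error", where, f"not readable as JSON: {exc}")
            continue
        if not isinstance(obj, dict):
            report.add("error", where, "top-level JSON value is not an object")
            continue
        _validate_document_obj(obj, where, report)
        study = obj.get("study") or {}
        key = study.get("source_file") or study.get("recording_id") or "?"
        for seg in obj.get("segments", []):
            if isinstance(seg, dict) and isinstance(seg.get("sequence_number"), int):
                by_recording.setdefault(key, []).append(seg["sequence_number"])

    if path.is_dir():
        for recording, seqs in by_recording.items():
            seqs = sorted(seqs)
            dupes = {s for a, s in zip(seqs, seqs[1:]) if a == s}
            for d in dupes:
                report.add("error", recording, f"duplicate sequence_number {d}")
            missing = sorted(set(range(seqs[0], seqs[-1] + 1)) - set(seqs))
            if missing:
                report.add(
                    "warning", recording,
                    f"sequence continuity gap: missing sequence_number(s) {missing}",
                )
            if seqs and seqs[0] != 0:
                report.add(
                    "warning", recording,
                    f"first sequence_number is {seqs[0]}, expected 0",
                )
    return report


# ---------------------------------------------------------------------------
# Time indexing


@dataclass
class CSFIndexEntry:
    file: str
    first_sequence: int
    last_sequence: int
    min_start_time: float
    max_end_time: float
    segments: list[tuple[int, float, float]]  # (sequence_number, start, end)


@dataclass
class CSFIndex:
    """Per-document time/sequence ranges enabling segment lookup by time."""

    entries: list[CSFIndexEntry] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "entries": [
                {
                    "file": e.file,
                    "first_sequence": e.first_sequence,
                    "last_sequence": e.last_sequence,
                    "min_start_time": e.min_start_time,
                    "max_end_time": e.max_end_time,
                    "segments": [list(s) for s in e.segments],
                }
                for e in self.entries
            ]
        }

    @classmethod
    def from_json(cls, obj: dict) -> "CSFIndex":
        return cls(
            [
                CSFIndexEntry(
                    file=e["file"],
                    first_sequence=e["first_sequence"],
                    last_sequence=e["last_sequence"],
                    min_start_time=e["min_start_time"],
                    max_end_time=e["max_end_time"],
                    segments=[(s[0], s[1], s[2]) for s in e["segments"]],
                )
                for e in obj.get("entries", [])
            ]
        )

    def save(self, path: Union[str, os.PathLike]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json(), fh)

    @classmethod
    def load(cls, path: Union[str, os.PathLike]) -> "CSFIndex":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json(json.load(fh))


def build_index(paths: Iterable[Union[str, os.PathLike]]) -> CSFIndex:
    """Index documents by reading only their segment timing metadata."""
    entries = []
    for p in paths:
        with open(p, "r", encoding="utf-8") as fh:
            obj = json.load(fh)
        segs = [
            (s["sequence_number"], s["start_time"], s["end_time"])
            for s in obj.get("segments", [])
        ]
        if not segs:
            continue
        entries.append(
            CSFIndexEntry(
                file=os.fspath(p),
                first_sequence=min(s[0] for s in segs),
                last_sequence=max(s[0] for s in segs),
                min_start_time=min(s[1] for s in segs),
                max_end_time=max(s[2] for s in segs),
                segments=segs,
            )
        )
    entries.sort(key=lambda e: e.first_sequence)
    return CSFIndex(entries)


def locate_segments(
    index: CSFIndex, query_start: float, query_end: float
) -> list[tuple[str, int]]:
    """Segments whose ``[start_time, end_time)`` intersects ``[query_start, query_end)``."""
    if query_start >= query_end:
        raise ValueError(f"query_start ({query_start}) must be < query_end ({query_end})")
    hits = []
    for entry in index.entries:
        if entry.max_end_time <= query_start or entry.min_start_time >= query_end:
            continue
        for seq, start, end in entry.segments:
            if start < query_end and end > query_start:
                hits.append((entry.file, seq))
    hits.sort(key=lambda t: t[1])
    return hits
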