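"""End-to-end orchestration: discover → read → partition → transform → CSF.

A directory of EDF recordings (with optional same-base-name ``.txt``
annotation sidecars) is converted to a directory of ``.csf`` documents plus
one time index per recording.  Files are independent units of work: they
can be processed by a pool of workers, a failure in one file never aborts
the run, and the output bytes are identical whatever the worker count or
processing order.  The two stages are logged as ``reader`` (header,
annotation and metadata extraction) and ``generator`` (partition, transform
and CSF emission); ``stage="read_only"`` runs the reader alone, which is
useful when only metadata is wanted and skips the generator's cost.
"""

from __future__ import annotations

import datetime as _dt
import logging
import os
import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import csf as csf_mod
from . import edf_io
from .annotation import (
    TermMapping,
    annotations_in_interval,
    apply_mapping,
    parse_annotations,
)
from .csf import SignalSegment, channel_metadata, study_metadata, write_csf
from .errors import CloudwaveError
from .partition import DEFAULT_EPOCH_SECONDS, extract_segment, plan_epochs
from .transform import build_channel_series

logger = logging.getLogger("cloudwave.pipeline")


@dataclass
class PipelineConfig:
    input_dir: Union[str, os.PathLike]
    output_dir: Union[str, os.PathLike]
    epoch_duration_seconds: float = DEFAULT_EPOCH_SECONDS
    segments_per_file: int = csf_mod.DEFAULT_SEGMENTS_PER_FILE
    workers: int = 1
    term_mapping_path: Optional[Union[str, os.PathLike]] = None
    emit_raw_digital: bool = False
    serialization_precision: Optional[int] = None
    stage: str = "full"  # "full" | "read_only"
    annotation_time_offset: float = 0.0

    def validate(self) -> None:
        if self.workers < 1:
            raise ValueError(f"workers must be >= 1, got {self.workers}")
        if self.stage not in ("full", "read_only"):
            raise ValueError(f"stage must be 'full' or 'read_only', got {self.stage!r}")
        if self.segments_per_file < 1:
            raise ValueError(f"segments_per_file must be >= 1, got {self.segments_per_file}")


@dataclass
class FileResult:
    file: str
    status: str  # "ok" | "failed"
    reason: Optional[str] = None
    n_segments: int = 0
    n_documents: int = 0
    documents: list[str] = field(default_factory=list)
    annotations_total: int = 0
    annotations_matched: int = 0
    annotation_rejects: int = 0
    out_of_range: dict[str, int] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)

    @property
    def annotation_match_rate(self) -> float:
        return (
            self.annotations_matched / self.annotations_total
            if self.annotations_total
            else 1.0
        )


@dataclass
class RunReport:
    files: list[FileResult] = field(default_factory=list)
    orphan_annotations: list[str] = field(default_factory=list)

    @property
    def n_ok(self) -> int:
        return sum(1 for f in self.files if f.status == "ok")

    @property
    def n_failed(self) -> int:
        return sum(1 for f in self.files if f.status == "failed")

    @property
    def exit_code(self) -> int:
        """0 if every file converted, 2 on partial success (scriptability)."""
        return 0 if self.n_failed == 0 else 2

    @property
    def total_segments(self) -> int:
        return sum(f.n_segments for f in self.files)

    @property
    def total_documents(self) -> int:
        return sum(f.n_documents for f in self.files)


def discover_inputs(
    input_dir: Union[str, os.PathLike]
) -> list[tuple[Path, Optional[Path]]]:
    """Pair each ``.edf`` with its same-base-name ``.txt`` sidecar, if any.

    Extensions match case-insensitively; recordings without a sidecar are
    returned with ``None`` and processed with zero annotations.  The list is
    sorted by file name so downstream processing order is deterministic.
    """
    input_dir = Path(input_dir)
    entries = sorted(p for p in input_dir.iterdir() if p.is_file())
    sidecars = {p.stem: p for p in entries if p.suffix.lower() == ".txt"}
    return [
        (p, sidecars.get(p.stem))
        for p in entries
        if p.suffix.lower() == ".edf"
    ]


def orphan_sidecars(input_dir: Union[str, os.PathLike]) -> list[Path]:
    """``.txt`` files with no matching ``.edf`` — reported, never processed."""
    input_dir = Path(input_dir)
    entries = [p for p in input_dir.iterdir() if p.is_file()]
    edf_stems = {p.stem for p in entries if p.suffix.lower() == ".edf"}
    return sorted(
        p for p in entries if p.suffix.lower() == ".txt" and p.stem not in edf_stems
    )


def _load_mapping(config: PipelineConfig) -> Optional[TermMapping]:
    if config.term_mapping_path is None:
        return None
    return TermMapping.from_file(config.term_mapping_path)


def process_file(
    config: PipelineConfig, edf_path: Path, sidecar: Optional[Path]
) -> FileResult:
    """Convert one recording; exceptions become a 'failed' result, never a raise."""
    result = FileResult(file=str(edf_path), status="ok")
    try:
        t0 = time.perf_counter()
        header, specs = edf_io.read_header(edf_path)
        annotations = []
        if sidecar is not None:
            parsed = parse_annotations(sidecar, time_offset=config.annotation_time_offset)
            result.annotation_rejects = len(parsed.rejects)
            annotations = parsed.annotations
        mapping = _load_mapping(config)
        if mapping is not None and annotations:
            annotations, summary = apply_mapping(annotations, mapping)
            result.annotations_matched = summary.matched
        result.annotations_total = len(annotations)
        if mapping is None:
            result.annotations_matched = len(annotations)
        result.stage_seconds["reader"] = time.perf_counter() - t0
        logger.info("reader: %s (%d signals, %d records)", edf_path.name,
                    header.n_signals, header.n_data_records)

        if config.stage == "read_only":
            return result

        t1 = time.perf_counter()
        out_dir = Path(config.output_dir)
        plan = plan_epochs(header, config.epoch_duration_seconds)
        study = study_metadata(header, source_file=edf_path.name)
        chan_meta = channel_metadata(specs, header.record_duration)
        oor = np.zeros(len(specs), dtype=np.int64)

        def reader(first: int, count: int):
            return edf_io.read_records(edf_path, header, specs, first, count)

        pending: list[SignalSegment] = []
        doc_names: list[str] = []

        def flush():
            if not pending:
                return
            doc = csf_mod.pack_segments(
                pending, len(pending), study=study, channels=chan_meta
            )[0]
            name = f"{edf_path.stem}_{len(doc_names):04d}.csf"
            write_csf(doc, out_dir / name, precision=config.serialization_precision)
            doc_names.append(name)
            pending.clear()

        for entry in plan:
            raw = extract_segment(reader, entry, specs)
            oor += raw.block.out_of_range
            series = build_channel_series(
                raw, specs, header.record_duration, keep_digital=config.emit_raw_digital
            )
            seg = SignalSegment(
                sequence_number=entry.segment_index,
                start_time=entry.start_time,
                end_time=entry.end_time,
                absolute_start=header.start_datetime
                + _dt.timedelta(seconds=entry.start_time),
                channels=series,
                annotations=annotations_in_interval(
                    annotations, entry.start_time, entry.end_time
                ),
                is_partial=entry.is_partial,
            )
            pending.append(seg)
            result.n_segments += 1
            if len(pending) == config.segments_per_file:
                flush()
        flush()

        index = csf_mod.build_index(out_dir / n for n in doc_names)
        for e in index.entries:
            e.file = Path(e.file).name
        index.save(out_dir / f"{edf_path.stem}.index.json")

        result.n_documents = len(doc_names)
        result.documents = doc_names
        labels = csf_mod.dedupe_labels([s.label for s in specs])
        result.out_of_range = {lbl: int(c) for lbl, c in zip(labels, oor)}
        result.stage_seconds["generator"] = time.perf_counter() - t1
        logger.info("generator: %s -> %d segments in %d documents",
                    edf_path.name, result.n_segments, result.n_documents)
    except Exception as exc:  # per-file fault isolation contract
        result.status = "failed"
        result.reason = f"{type(exc).__name__}: {exc}"
        logger.warning("failed: %s (%s)", edf_path.name, result.reason)
    return result


def _worker(args) -> FileResult:
    config, edf_path, sidecar = args
    return process_file(config, edf_path, sidecar)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Process every discovered recording; outputs are worker-count invariant.

    Raises only on startup problems (bad config, unreadable input directory,
    unwritable output directory); anything that goes wrong with an individual
    file lands in its :class:`FileResult` instead.
    """
    config.validate()
    input_dir = Path(config.input_dir)
    if not input_dir.is_dir():
        raise FileNotFoundError(f"input directory not found: {input_dir}")
    out_dir = Path(config.output_dir)
    if config.stage == "full":
        out_dir.mkdir(parents=True, exist_ok=True)
        if not os.access(out_dir, os.W_OK):
            raise PermissionError(f"output directory not writable: {out_dir}")
    if config.term_mapping_path is not None:
        TermMapping.from_file(config.term_mapping_path)  # fail fast on bad mapping

    pairs = discover_inputs(input_dir)
    report = RunReport(orphan_annotations=[str(p) for p in orphan_sidecars(input_dir)])
    tasks = [(config, edf, sidecar) for edf, sidecar in pairs]
    if config.workers == 1 or len(tasks) <= 1:
        results = [_worker(t) for t in tasks]
    else:
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            results = list(pool.map(_worker, tasks))
    report.files = sorted(results, key=lambda r: r.file)
    return report
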