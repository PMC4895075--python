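"""Clinical annotation sidecars: parsing, ontology mapping, interval queries.

Epilepsy monitoring units export timestamped clinical events (seizures,
spikes, artifacts) in plain-text files paired with each EDF recording.  The
default dialect here is tab-separated ``onset_seconds<TAB>duration_seconds
<TAB>text`` with ``#`` comment lines; site-specific dialects can be
registered.  Event texts can be mapped to controlled ontology terms (e.g.,
EpSO, the Epilepsy and Seizure Ontology) via a two-column lookup table —
the ontology is used purely as a controlled vocabulary, no reasoning.

Event/window overlap uses closed event intervals ``[onset, onset+duration]``
against half-open windows ``[start, end)``: an event spanning an epoch
boundary belongs to every epoch it touches, and a zero-duration event
sitting exactly on a window start belongs to that window.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence, Union

TextSource = Union[str, os.PathLike, io.TextIOBase, Iterable[str]]

_PUNCT_EDGES = re.compile(r"^[\s\.,;:!\?\"'\(\)\[\]]+|[\s\.,;:!\?\"'\(\)\[\]]+$")
_WS = re.compile(r"\s+")


@dataclass(frozen=True)
class ClinicalAnnotation:
    """A timestamped clinical event, relative to recording start (seconds)."""

    onset: float
    duration: float
    text: str
    ontology_term: str | None = None
    source_line: int = 0

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class RejectedLine:
    source_line: int
    content: str
    reason: str


@dataclass
class AnnotationParseResult:
    annotations: list[ClinicalAnnotation]
    rejects: list[RejectedLine] = field(default_factory=list)

    def __iter__(self):
        return iter(self.annotations)

    def __len__(self):
        return len(self.annotations)


def normalize_text(text: str) -> str:
    """Lowercase, collapse internal whitespace, strip edge punctuation."""
    return _WS.sub(" ", _PUNCT_EDGES.sub("", text)).lower()


def _parse_tab_line(line: str) -> tuple[float, float, str]:
    parts = line.split("\t")
    if len(parts) < 3:
        raise ValueError(
            f"expected 3 tab-separated fields (onset, duration, text), got {len(parts)}"
        )
    onset = float(parts[0])
    duration = float(parts[1])
    text = "\t".join(parts[2:]).strip()
    if not text:
        raise ValueError("empty annotation text")
    return onset, duration, text


#: Registered sidecar dialects: name -> line parser returning (onset, duration, text).
DIALECTS: dict[str, Callable[[str], tuple[float, float, str]]] = {
    "tab": _parse_tab_line,
}


def register_dialect(name: str, parser: Callable[[str], tuple[float, float, str]]) -> None:
    DIALECTS[name] = parser


def _lines(source: TextSource) -> Iterable[str]:
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as fh:
            yield from fh
    else:
        yield from source


def parse_annotations(
    text_source: TextSource,
    dialect: str = "tab",
    time_offset: float = 0.0,
) -> AnnotationParseResult:
    """Parse one annotation per non-empty, non-comment line.

    Malformed lines (wrong field count, non-numeric or negative times) are
    collected in ``rejects`` with a reason, never silently dropped.  The
    result is sorted by onset, ties broken by source line.  ``time_offset``
    (seconds) is added to every onset, for sidecars whose timestamps are not
    relative to recording start.
    """
    parser = DIALECTS[dialect]
    annotations: list[ClinicalAnnotation] = []
    rejects: list[RejectedLine] = []
    for lineno, raw in enumerate(_lines(text_source), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        try:
            onset, duration, text = parser(line)
        except ValueError as exc:
            rejects.append(RejectedLine(lineno, line, str(exc)))
            continue
        onset += time_offset
        if onset < 0:
            rejects.append(RejectedLine(lineno, line, f"negative onset {onset}"))
            continue
        if duration < 0:
            rejects.append(RejectedLine(lineno, line, f"negative duration {duration}"))
            continue
        annotations.append(
            ClinicalAnnotation(onset=onset, duration=duration, text=text, source_line=lineno)
        )
    annotations.sort(key=lambda a: (a.onset, a.source_line))
    return AnnotationParseResult(annotations, rejects)


@dataclass
class TermMapping:
    """Normalized annotation text -> ontology term identifier (IRI or CURIE)."""

    entries: dict[str, str] = field(default_factory=dict)
    ontology_name: str = ""

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]], ontology_name: str = "") -> "TermMapping":
        entries: dict[str, str] = {}
        for text, term in pairs:
            key = normalize_text(text)
            if key in entries and entries[key] != term:
                raise ValueError(
                    f"duplicate mapping key {key!r}: {entries[key]!r} vs {term!r}"
                )
            entries[key] = term
        return cls(entries, ontology_name)

    @classmethod
    def from_file(cls, path: Union[str, os.PathLike], ontology_name: str = "") -> "TermMapping":
        """Load a two-column (text, term) tab-separated table."""
        pairs = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) < 2:
                    raise ValueError(f"mapping line needs 2 tab-separated columns: {line!r}")
                pairs.append((cols[0], cols[1]))
        name = ontology_name or Path(path).stem
        return cls.from_pairs(pairs, name)

    def lookup(self, text: str) -> str | None:
        return self.entries.get(normalize_text(text))


@dataclass
class MappingSummary:
    total: int
    matched: int
    unmatched_texts: list[str] = field(default_factory=list)

    @property
    def unmatched(self) -> int:
        return self.total - self.matched

    @property
    def match_rate(self) -> float:
        return self.matched / self.total if self.total else 1.0


def apply_mapping(
    annotations: Sequence[ClinicalAnnotation], mapping: TermMapping
) -> tuple[list[ClinicalAnnotation], MappingSummary]:
    """Populate ontology terms by normalized lookup; unmatched texts are tallied."""
    out: list[ClinicalAnnotation] = []
    unmatched: list[str] = []
    for ann in annotations:
        term = mapping.lookup(ann.text)
        if term is None:
            unmatched.append(ann.text)
            out.append(ann)
        else:
            out.append(replace(ann, ontology_term=term))
    summary = MappingSummary(len(out), len(out) - len(unmatched), unmatched)
    return out, summary


def overlaps(ann: ClinicalAnnotation, start: float, end: float) -> bool:
    """Closed event interval vs half-open window intersection predicate."""
    return ann.onset < end and ann.end >= start


def annotations_in_interval(
    annotations: Sequence[ClinicalAnnotation], start: float, end: float
) -> list[ClinicalAnnotation]:
    """Annotations whose event interval intersects the window ``[start, end)``."""
    if start >= end:
        raise ValueError(f"start ({start}) must be < end ({end})")
    return [a for a in annotations if overlaps(a, start, end)]
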