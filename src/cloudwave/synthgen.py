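"""Synthetic EDF recordings with known ground truth.

Emulates the multimodal recordings of an epilepsy monitoring unit — e.g.
scalp/intracranial EEG at a few hundred Hz, ECG at a higher rate, SpO2 at
1 Hz — with heterogeneous per-channel sampling rates, per-channel
calibration ranges, known waveforms (constant, sine, uniform noise) and
timestamped clinical events written to a tab-separated sidecar.  Every
generated file carries exact ground truth (digital samples, pre-quantization
physical samples, events), so each pipeline stage can be checked against
what was actually synthesized.  A fixed seed yields byte-identical output.

No attempt is made at physiological realism: waveforms exercise layout,
calibration and timing arithmetic, not seizure morphology.
"""

from __future__ import annotations

import datetime as _dt
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import yaml

from . import edf_io
from .edf_io import ChannelSpec, DataRecordBlock, EDFHeader
from .errors import ConfigurationError

_AMPLITUDE_TOL = 1e-9


@dataclass(frozen=True)
class Constant:
    value: float  # physical units

    def evaluate(self, t: np.ndarray, rng) -> np.ndarray:
        return np.full_like(t, self.value, dtype=np.float64)


@dataclass(frozen=True)
class Sine:
    frequency: float  # Hz
    amplitude: float  # physical units, peak
    phase: float = 0.0  # radians
    mean: float = 0.0  # physical units

    def evaluate(self, t: np.ndarray, rng) -> np.ndarray:
        return self.mean + self.amplitude * np.sin(2 * np.pi * self.frequency * t + self.phase)


@dataclass(frozen=True)
class UniformNoise:
    low: float
    high: float

    def evaluate(self, t: np.ndarray, rng) -> np.ndarray:
        return rng.uniform(self.low, self.high, size=t.shape)


Waveform = Union[Constant, Sine, UniformNoise]


@dataclass
class SynthChannel:
    label: str
    unit: str
    physical_min: float
    physical_max: float
    sampling_rate: float  # Hz
    waveform: Waveform
    digital_min: int = -32768
    digital_max: int = 32767
    transducer: str = "synthetic"

    def to_spec(self, record_duration: float) -> ChannelSpec:
        return ChannelSpec(
            label=self.label,
            transducer=self.transducer,
            physical_dimension=self.unit,
            physical_min=self.physical_min,
            physical_max=self.physical_max,
            digital_min=self.digital_min,
            digital_max=self.digital_max,
            prefiltering="",
            samples_per_record=int(round(self.sampling_rate * record_duration)),
        )


@dataclass
class SynthEvent:
    onset: float
    duration: float
    text: str


@dataclass
class SynthSpec:
    """Recipe for one synthetic recording; all validation is up front."""

    duration: float  # seconds
    channels: list[SynthChannel]
    events: list[SynthEvent] = field(default_factory=list)
    record_duration: float = 1.0
    seed: int = 0
    patient_id: str = "X X X X"
    recording_id: str = "Startdate 02.JAN.24 synthetic"
    start_datetime: _dt.datetime = _dt.datetime(2024, 1, 2, 10, 0, 0)

    def validate(self) -> None:
        if self.record_duration <= 0:
            raise ConfigurationError("record_duration must be positive")
        n_rec = self.duration / self.record_duration
        if abs(n_rec - round(n_rec)) > 1e-9 or round(n_rec) < 1:
            raise ConfigurationError(
                f"duration ({self.duration} s) must be a positive multiple of "
                f"record_duration ({self.record_duration} s)"
            )
        for ch in self.channels:
            spr = ch.sampling_rate * self.record_duration
            if abs(spr - round(spr)) > 1e-9 or round(spr) < 1:
                raise ConfigurationError(
                    f"channel {ch.label!r}: sampling_rate x record_duration "
                    f"({spr}) must be a positive integer"
                )

    @property
    def n_records(self) -> int:
        return int(round(self.duration / self.record_duration))


@dataclass
class GroundTruth:
    """Exact per-channel truth retained alongside the written files."""

    spec: SynthSpec
    digital: dict[str, np.ndarray]  # label -> quantized integer samples
    physical: dict[str, np.ndarray]  # label -> pre-quantization physical samples
    events: list[SynthEvent]
    seed: int

    def quantization_step(self, label: str) -> float:
        ch = next(c for c in self.spec.channels if c.label == label)
        return (ch.physical_max - ch.physical_min) / (ch.digital_max - ch.digital_min)


def _synthesize_channel(
    ch: SynthChannel, duration: float, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the waveform in physical units and inverse-calibrate to integers."""
    n = int(round(ch.sampling_rate * duration))
    t = np.arange(n, dtype=np.float64) / ch.sampling_rate
    phys = ch.waveform.evaluate(t, rng)
    lo, hi = float(phys.min(initial=0)), float(phys.max(initial=0))
    if lo < ch.physical_min - _AMPLITUDE_TOL or hi > ch.physical_max + _AMPLITUDE_TOL:
        raise ConfigurationError(
            f"channel {ch.label!r}: waveform range [{lo}, {hi}] exceeds physical "
            f"range [{ch.physical_min}, {ch.physical_max}]"
        )
    gain = (ch.physical_max - ch.physical_min) / (ch.digital_max - ch.digital_min)
    digital = np.rint((phys - ch.physical_min) / gain).astype(np.int64) + ch.digital_min
    return digital, phys


def generate(
    spec: SynthSpec,
    out_dir: Union[str, os.PathLike],
    basename: str = "synthetic",
) -> tuple[Path, Path, GroundTruth]:
    """Write ``<basename>.edf`` and ``<basename>.txt``; return paths + truth."""
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    digital: dict[str, np.ndarray] = {}
    physical: dict[str, np.ndarray] = {}
    arrays = []
    for ch in spec.channels:
        d, p = _synthesize_channel(ch, spec.duration, rng)
        digital[ch.label] = d
        physical[ch.label] = p
        arrays.append(d)

    specs = [ch.to_spec(spec.record_duration) for ch in spec.channels]
    header = EDFHeader(
        version="0",
        patient_id=spec.patient_id,
        recording_id=spec.recording_id,
        start_date=spec.start_datetime.date(),
        start_time=spec.start_datetime.time(),
        header_bytes=256 * (1 + len(specs)),
        n_data_records=spec.n_records,
        record_duration=spec.record_duration,
        n_signals=len(specs),
    )
    block = DataRecordBlock.from_channel_arrays(specs, arrays)

    edf_path = out_dir / f"{basename}.edf"
    edf_io.write_edf(header, specs, block, edf_path)

    ann_path = out_dir / f"{basename}.txt"
    with open(ann_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# onset_seconds<TAB>duration_seconds<TAB>text\n")
        for ev in spec.events:
            fh.write(f"{ev.onset}\t{ev.duration}\t{ev.text}\n")

    truth = GroundTruth(spec, digital, physical, list(spec.events), spec.seed)
    return edf_path, ann_path, truth


def emu_small_spec(seed: int = 0) -> SynthSpec:
    """Default small fixture: 3 heterogeneous-rate channels, 300 s, 2 events.

    Mirrors the modality mix of a monitoring-unit recording (EEG + ECG +
    SpO2) at rates small enough for fast tests yet exercising heterogeneous
    per-record sample counts and annotation/epoch overlap.
    """
    return SynthSpec(
        duration=300.0,
        record_duration=1.0,
        seed=seed,
        channels=[
            SynthChannel(
                label="EEG Fp1",
                unit="uV",
                physical_min=-200.0,
                physical_max=200.0,
                sampling_rate=256.0,
                waveform=Sine(frequency=10.0, amplitude=50.0),
            ),
            SynthChannel(
                label="ECG",
                unit="mV",
                physical_min=-5.0,
                physical_max=5.0,
                sampling_rate=512.0,
                waveform=Sine(frequency=1.2, amplitude=1.5),
            ),
            SynthChannel(
                label="SpO2",
                unit="%",
                physical_min=0.0,
                physical_max=100.0,
                sampling_rate=1.0,
                waveform=Constant(97.0),
            ),
        ],
        events=[
            SynthEvent(onset=45.0, duration=30.0, text="Seizure"),
            SynthEvent(onset=120.5, duration=0.0, text="Spike"),
        ],
    )


# ---------------------------------------------------------------------------
# Spec files (YAML) for the CLI


_WAVEFORM_TYPES = {"constant": Constant, "sine": Sine, "uniform_noise": UniformNoise}


def _waveform_from_dict(obj: dict) -> Waveform:
    kind = obj.get("type")
    cls = _WAVEFORM_TYPES.get(kind)
    if cls is None:
        raise ConfigurationError(
            f"unknown waveform type {kind!r}; expected one of {sorted(_WAVEFORM_TYPES)}"
        )
    kwargs = {k: v for k, v in obj.items() if k != "type"}
    return cls(**kwargs)


def load_spec(path: Union[str, os.PathLike]) -> SynthSpec:
    """Load a recording recipe from a YAML file (see docs for the layout)."""
    with open(path, "r", encoding="utf-8") as fh:
        obj = yaml.safe_load(fh)
    channels = [
        SynthChannel(
            label=c["label"],
            unit=c.get("unit", ""),
            physical_min=float(c["physical_min"]),
            physical_max=float(c["physical_max"]),
            sampling_rate=float(c["sampling_rate"]),
            waveform=_waveform_from_dict(c["waveform"]),
            digital_min=int(c.get("digital_min", -32768)),
            digital_max=int(c.get("digital_max", 32767)),
        )
        for c in obj["channels"]
    ]
    events = [
        SynthEvent(float(e["onset"]), float(e.get("duration", 0.0)), str(e["text"]))
        for e in obj.get("events", [])
    ]
    spec = SynthSpec(
        duration=float(obj["duration"]),
        record_duration=float(obj.get("record_duration", 1.0)),
        channels=channels,
        events=events,
        seed=int(obj.get("seed", 0)),
    )
    if "start_datetime" in obj:
        spec.start_datetime = _dt.datetime.fromisoformat(str(obj["start_datetime"]))
    return spec
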