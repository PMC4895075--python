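"""Shared fixtures: synthetic recordings generated fresh at test time."""

import numpy as np
import pytest

from cloudwave.edf_io import ChannelSpec, DataRecordBlock, EDFHeader
from cloudwave.synthgen import (
    Constant,
    Sine,
    SynthChannel,
    SynthEvent,
    SynthSpec,
    UniformNoise,
    emu_small_spec,
    generate,
)


@pytest.fixture(scope="session")
def emu_small(tmp_path_factory):
    """The default small fixture recording: 3 channels, 300 s, 2 events."""
    out = tmp_path_factory.mktemp("emu_small")
    edf_path, ann_path, truth = generate(emu_small_spec(seed=7), out, basename="emu_small")
    return edf_path, ann_path, truth


def random_synth_spec(rng: np.random.Generator, max_channels: int = 3,
                      max_duration: float = 24.0) -> SynthSpec:
    """A small randomized recording with heterogeneous rates and calibrations."""
    record_duration = float(rng.choice([0.5, 1.0, 2.0]))
    n_records = int(rng.integers(3, max(4, int(max_duration / record_duration)) + 1))
    channels = []
    for c in range(int(rng.integers(1, max_channels + 1))):
        rate = float(rng.choice([1, 2, 4, 8, 16, 32])) / record_duration
        pmin = float(rng.uniform(-500, -1))
        pmax = float(rng.uniform(1, 500))
        dmin = int(rng.integers(-32768, -1))
        dmax = int(rng.integers(1, 32767))
        kind = rng.integers(0, 3)
        if kind == 0:
            wf = Constant(float(rng.uniform(pmin, pmax)))
        elif kind == 1:
            amp = float(rng.uniform(0.1, min(-pmin, pmax) * 0.9))
            wf = Sine(frequency=float(rng.uniform(0.05, max(0.25, rate / 4))), amplitude=amp)
        else:
            lo = float(rng.uniform(pmin, 0))
            wf = UniformNoise(lo, float(rng.uniform(lo, pmax)))
        channels.append(
            SynthChannel(
                label=f"CH{c}", unit="uV",
                physical_min=round(pmin, 3), physical_max=round(pmax, 3),
                sampling_rate=rate, waveform=wf,
                digital_min=dmin, digital_max=dmax,
            )
        )
    n_events = int(rng.integers(0, 4))
    total = n_records * record_duration
    events = [
        SynthEvent(
            onset=round(float(rng.uniform(0, total)), 3),
            duration=round(float(rng.uniform(0, total / 3)), 3),
            text=rng.choice(["Seizure", "Spike", "Artifact"]),
        )
        for _ in range(n_events)
    ]
    return SynthSpec(
        duration=n_records * record_duration,
        record_duration=record_duration,
        channels=channels,
        events=events,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_header(n_signals: int, n_records: int, record_duration: float = 1.0) -> EDFHeader:
    return EDFHeader(
        version="0",
        patient_id="X X X X",
        recording_id="Startdate 02.JAN.24",
        header_bytes=256 * (1 + n_signals),
        n_data_records=n_records,
        record_duration=record_duration,
        n_signals=n_signals,
    )


def random_recording(rng: np.random.Generator, max_channels: int = 4,
                     max_records: int = 20):
    """Random (header, specs, block) triple with digital samples filling records."""
    n_signals = int(rng.integers(1, max_channels + 1))
    n_records = int(rng.integers(0, max_records + 1))
    specs = []
    for c in range(n_signals):
        specs.append(
            ChannelSpec(
                label=f"C{c}",
                physical_dimension="uV",
                physical_min=float(rng.integers(-500, 0)),
                physical_max=float(rng.integers(1, 500)),
                digital_min=int(rng.integers(-32768, 0)),
                digital_max=int(rng.integers(1, 32768)),
                samples_per_record=int(rng.integers(1, 12)),
            )
        )
    header = make_header(n_signals, n_records, float(rng.choice([0.5, 1.0])))
    arrays = [
        rng.integers(-32768, 32768, size=n_records * s.samples_per_record)
        for s in specs
    ]
    block = DataRecordBlock.from_channel_arrays(specs, arrays)
    return header, specs, block
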