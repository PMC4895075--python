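# cloudwave

Convert European Data Format (EDF) electrophysiology recordings — EEG, ECG,
SpO2 and other polysomnography/monitoring-unit signals — into **Cloudwave
Signal Format (CSF)**: small, self-descriptive JSON documents of fixed-duration,
channel-oriented, physically calibrated signal segments with attached clinical
annotations.

## Why

EDF stores a recording as one monolithic binary file: a fixed-width ASCII
header followed by *data records*, each holding the interleaved 16-bit samples
of every channel for one record duration. That layout is compact but hostile to
the things downstream tools actually do — fetch one channel, compose a montage,
jump to a clinical event, or load a 30-second window of a multi-gigabyte file.
`cloudwave` performs the three standard preprocessing steps in one pipeline:

1. **Partition** the recording into logical segments (*epochs*) of fixed
   duration — 30 s by default, configurable.
2. **Transform** each segment from sample-oriented to channel-oriented layout
   and convert raw digital ADC integers `d` to physical values via the EDF
   calibration map

   ```
   p = p_min + (p_max − p_min) · (d − d_min) / (d_max − d_min)
   ```

   using each channel's digital/physical extremes from the header.
3. **Annotate** each segment with the clinical events (seizures, spikes, …)
   from the paired plain-text sidecar file, optionally mapped to controlled
   ontology terms (e.g. EpSO), and emit CSF documents — two segments per
   `.csf` file by default — plus a JSON time index per recording.

Each CSF file can then be stored, indexed and queried independently of the
source EDF. A synthetic-recording generator with exact ground truth makes the
entire pipeline testable without any patient data.

## Worked example

Generate the built-in synthetic fixture — 300 s, three channels with
heterogeneous rates (256 Hz EEG sine, 512 Hz ECG sine, 1 Hz constant SpO2)
and two clinical events — then convert and validate it:

```sh
$ cloudwave synth --out demo/in --seed 3 --name rec
wrote demo/in/rec.edf (3 channels, 300 s)
wrote demo/in/rec.txt (2 events)

$ cloudwave convert --input demo/in --output demo/out
demo/in/rec.edf: ok, 10 segments, 5 documents
1 ok, 0 failed; 10 segments in 5 CSF documents

$ cloudwave validate --input demo/out
0 error(s), 0 warning(s)
```

The 300-s recording yields 10 epochs of 30 s (`300 / 30`), packed two per
document into 5 CSF files (`rec_0000.csf` … `rec_0004.csf`) plus
`rec.index.json`, which maps recording time to documents. The 45-s seizure
event, which spans epoch boundaries, appears in every segment it overlaps
(sequence numbers 1 and 2); the instantaneous spike at 120.5 s appears exactly
once (sequence number 4).

From Python:

```python
import cloudwave

report = cloudwave.run_pipeline(cloudwave.PipelineConfig(
    input_dir="demo/in", output_dir="demo/out",
    epoch_duration_seconds=30, segments_per_file=2, workers=4,
))
doc = cloudwave.read_csf("demo/out/rec_0000.csf")
seg = doc.segments[0]                    # 30 s, channel-oriented
seg.channels[0].values                   # physical values (uV), 7680 samples
```

`--stage read_only` runs only the metadata/annotation reader, for applications
that want EDF parsing without paying for CSF generation. Files are processed
independently: a corrupt recording is reported and skipped, never aborts the
run (exit code 2 signals partial success), and output bytes are identical for
any worker count.

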