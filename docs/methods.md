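# Methods

## Processing model

A recording enters as an EDF file: a 256-byte ASCII main header, 256 bytes of
channel metadata per signal, then `n_data_records` *data records*, each the
channel-blocked concatenation of every channel's samples for one
`record_duration` (little-endian signed 16-bit). The pipeline runs two stages
per file, mirroring the natural reader/generator split:

* **reader** — parse the header and channel subheaders, parse the `.txt`
  annotation sidecar (paired by base name, extensions matched
  case-insensitively), and optionally map annotation texts to ontology terms.
  This stage is independently useful and can be run alone
  (`stage="read_only"`).
* **generator** — plan epochs, stream each epoch's record range, gather it
  into channel-oriented arrays, calibrate to physical units, attach the
  annotations overlapping the epoch, and pack consecutive segments into CSF
  documents plus a per-recording time index.

Files are the unit of work: each is processed independently (optionally by a
process pool), a failure is recorded per file and never aborts the run, and
outputs are byte-identical regardless of worker count or processing order.

## Epoch partitioning

Epochs have a fixed duration, default **30 s**, and must be an integer
multiple of the EDF record duration — this keeps data records intact and all
per-channel arithmetic integral; a non-multiple raises a configuration error
stating both values. Full epochs tile the recording from record 0; a trailing
remainder becomes a final epoch flagged `partial` with its true shorter
duration. Emitting (rather than dropping) the partial epoch is what makes the
end-to-end conservation law hold exactly: for every channel, the sum of
segment sample counts equals `n_data_records × samples_per_record`. Segment
times are offsets in seconds from recording start; absolute timestamps are
derived from the header's start date/time, treated as naive local time
(EDF carries no zone), and serialized as ISO-8601.

## Layout transform and calibration

The channel-oriented transform is a pure permutation: for channel *c*, the
per-record channel-*c* blocks are concatenated in record order. Sample
multisets per channel are preserved by construction, and the implementation is
tested against a brute-force index-arithmetic gather.

Calibration is the standard EDF affine map defined by each channel's
digital/physical extremes, with gain
`(p_max − p_min)/(d_max − d_min)`. It is evaluated as
`p_min·(1−r) + p_max·r` with `r = (d − d_min)/(d_max − d_min)`: algebraically
identical to `p_min + gain·(d − d_min)`, but bit-exact at both calibration
endpoints (where `r` is exactly 0 or 1), whereas the textbook form can miss
`p_max` by one ulp. Digital values outside `[d_min, d_max]` convert linearly —
they are never clipped — and are tallied per channel in the run report.
Re-digitizing by rounding the inverse map recovers in-range integers exactly.
Physical values are kept at full binary-float precision in memory; CSF
serialization precision is configurable (default: shortest round-trip
representation, i.e. lossless for float64).

## Annotations

The sidecar dialect is tab-separated `onset_seconds  duration_seconds  text`
with `#` comments; onsets are seconds from recording start (a configurable
offset accommodates wall-clock sources), duration 0 marks instantaneous
events. The dialect is pluggable since sites differ. Malformed lines are
collected in a rejects report with reasons, never silently dropped.

Event/epoch assignment uses closed event intervals `[onset, onset+duration]`
against half-open windows `[start, end)`: an event spanning a boundary is
duplicated into every window it touches; a zero-duration event exactly on a
window start belongs to that window, so tiling windows capture each in-range
instantaneous event exactly once.

Ontology mapping is a controlled-vocabulary lookup (no reasoning): text is
normalized by lowercasing, collapsing internal whitespace and stripping edge
punctuation, then matched against a two-column (text, term) table. Unmatched
texts are counted, not errors.

## CSF format

One JSON document per `.csf` file, with top-level keys `format_version`,
`study`, `channels`, `segment_count`, `segments`; per segment:
`sequence_number`, `start_time`, `end_time`, `absolute_start`, `partial`,
`annotations`, and `data` — per-channel physical-value arrays keyed by label
(labels de-duplicated by suffixing `_2`, `_3`, … since JSON keys must be
unique; EDF permits duplicates). Raw digital integers can additionally be
emitted under `digital` behind a flag. Default packing is **2 segments per
document**; both packing and epoch duration are configuration values.
Annotations are stored per segment, where the partitioner attached them.
Unknown attributes encountered on read are preserved and re-emitted, so
documents remain forward-compatible across format revisions. The normative
schema ships as `src/cloudwave/csf_schema.json`; the validator implements the
same checks plus cross-document sequence-continuity (gaps are warnings,
contradictions such as a sample count inconsistent with
`sampling_rate × duration` are errors). A JSON sidecar index per recording
records each document's sequence and time ranges so segments for a queried
time window are located without opening every document.

## Synthetic recordings

The generator emulates a monitoring-unit recording: multiple channels with
heterogeneous sampling rates and per-channel calibration ranges, waveforms
from {constant, sine, uniform noise}, and timestamped events written to the
sidecar. Waveforms are evaluated in physical units, inverse-calibrated and
rounded to integers, so the retained ground truth bounds recovery error by
half a quantization step (`gain/2`). One seeded generator drives all
randomness; a fixed seed gives byte-identical files. The default fixture
(`emu_small`) is 300 s, 1-s records, three channels (256 Hz EEG sine,
512 Hz ECG sine, 1 Hz constant SpO2 — chosen to exercise heterogeneous
per-record sample counts at test-friendly cost) and two events, one spanning
an epoch boundary and one instantaneous.

What passing tests on synthetic data do **not** show: robustness to real-world
EDF dialect quirks (vendor header deviations, EDF+ annotation channels, BDF),
physiological signal morphology, or wall-clock-timestamped sidecars beyond the
constant-offset model.

## Numerical and design choices

* Header ASCII fields are space-padded on write, right-trimmed on read;
  non-ASCII bytes are rejected. Two-digit years follow the 1985/2084 pivot.
* `n_data_records == -1` on read is resolved from the payload length when the
  source is seekable; a ragged payload is a format error.
* Epoch/record multiple checks use a relative tolerance of 1e-9 to absorb
  binary representation of decimal durations.
* Record ranges are read by seek+read only, so arbitrarily large files can be
  streamed epoch by epoch.
* Exit codes: 0 all files converted, 2 partial success, 1 startup error.
* Problem sizes in the test suite and acceptance script (e.g. 50 randomized
  conservation recordings of ≤ 24 s at ≤ 32 Hz; 200 gather-oracle cases;
  1000 calibration cases) were chosen as the smallest corpora that exercise
  every code path — heterogeneous rates, partial epochs, boundary-spanning
  events — while keeping the full suite in seconds.

## Known limitations

* Plain EDF only: no EDF+ embedded annotations, no BDF 24-bit samples, no
  discontinuous recordings.
* No overlapping/sliding windows, resampling, filtering or montage arithmetic
  (the channel-oriented layout preserves the per-channel access montage
  composition needs, but composition itself is out of scope).
* The `.txt` sidecar dialect is a project definition — sites with other
  formats must register a dialect parser.
* CSF is uncompressed JSON; document size is roughly 10–20 bytes per sample.
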