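{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Cloudwave Signal Format (CSF) document",
  "description": "Self-descriptive JSON container holding study metadata, channel metadata, and a fixed number of channel-oriented signal segments with clinical annotations. Unknown additional properties are permitted and must be preserved by readers.",
  "type": "object",
  "required": ["format_version", "study", "channels", "segment_count", "segments"],
  "properties": {
    "format_version": {"type": "string"},
    "study": {
      "type": "object",
      "properties": {
        "recording_id": {"type": "string"},
        "patient_id": {"type": "string"},
        "start_datetime": {"type": "string", "description": "ISO-8601, EDF header clock as naive local time"},
        "record_duration": {"type": "number", "exclusiveMinimum": 0},
        "n_signals": {"type": "integer", "minimum": 1},
        "source_file": {"type": "string"}
      }
    },
    "channels": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["label", "sampling_rate"],
        "properties": {
          "label": {"type": "string"},
          "transducer": {"type": "string"},
          "unit": {"type": "string"},
          "physical_min": {"type": "number"},
          "physical_max": {"type": "number"},
          "digital_min": {"type": "integer"},
          "digital_max": {"type": "integer"},
          "prefiltering": {"type": "string"},
          "samples_per_record": {"type": "integer", "minimum": 1},
          "sampling_rate": {"type": "number", "exclusiveMinimum": 0}
        }
      }
    },
    "segment_count": {"type": "integer", "minimum": 0},
    "segments": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["sequence_number", "start_time", "end_time", "absolute_start", "data"],
        "properties": {
          "sequence_number": {"type": "integer", "minimum": 0},
          "start_time": {"type": "number", "minimum": 0},
          "end_time": {"type": "number", "exclusiveMinimum": 0},
          "absolute_start": {"type": "string", "description": "ISO-8601"},
          "partial": {"type": "boolean"},
          "annotations": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["onset", "duration", "text"],
              "properties": {
                "onset": {"type": "number", "minimum": 0},
                "duration": {"type": "number", "minimum": 0},
                "text": {"type": "string"},
                "ontology_term": {"type": ["string", "null"]}
              }
            }
          },
          "data": {
            "type": "object",
            "description": "Per-channel physical-valued sample arrays keyed by (de-duplicated) channel label",
            "additionalProperties": {"type": "array", "items": {"type": "number"}}
          },
          "digital": {
            "type": "object",
            "description": "Optional raw digital sample arrays, same keys as data",
            "additionalProperties": {"type": "array", "items": {"type": "integer"}}
          }
        }
      }
    }
  }
}
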