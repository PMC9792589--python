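{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "orgephys pipeline report",
  "type": "object",
  "required": ["version", "seed", "stages_run", "config", "report_hash"],
  "properties": {
    "version": {"type": "string"},
    "seed": {"type": "integer"},
    "stages_run": {"type": "array", "items": {"type": "string"}},
    "config": {"type": "object"},
    "input": {
      "type": "object",
      "properties": {
        "n_channels": {"type": "integer"},
        "fs_hz": {"type": "number"},
        "duration_s": {"type": "number"},
        "state": {"enum": ["awake", "anesthetized"]}
      }
    },
    "preprocess": {
      "type": "object",
      "properties": {
        "n_included": {"type": "integer"},
        "ica": {
          "type": "object",
          "properties": {
            "n_components": {"type": "integer"},
            "removed": {"type": "array", "items": {"type": "integer"}},
            "mixing_uniformity": {"type": "array", "items": {"type": "number"}},
            "variance_removed_fraction": {"type": "number", "minimum": 0, "maximum": 1}
          }
        }
      }
    },
    "lfp": {
      "type": "object",
      "properties": {
        "n_trials": {"type": "integer"},
        "peak_amp_uv": {"type": "array"},
        "peak_delay_s": {"type": "array"},
        "delay_test": {
          "type": "object",
          "properties": {
            "observed_delta_s": {"type": "number"},
            "null_mean": {"type": "number"},
            "null_sd": {"type": "number"},
            "t": {"type": "number"},
            "p_value": {"type": "number", "minimum": 0, "maximum": 1}
          }
        }
      }
    },
    "spectra": {"type": "object"},
    "mua": {
      "type": "object",
      "properties": {
        "event_counts": {"type": "array", "items": {"type": "integer"}},
        "rates_hz": {"type": "array", "items": {"type": "number"}},
        "evoked_snr_db": {"type": "array", "items": {"type": "number"}},
        "overlap_test": {"type": "object"}
      }
    },
    "plv": {"type": "object"},
    "wall_time_s": {"type": "number"},
    "report_hash": {"type": "string", "pattern": "^[0-9a-f]{64}$"}
  }
}
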