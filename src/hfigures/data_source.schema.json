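{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "hfigures data source",
  "description": "Grouped, time-stamped health measurements with recommended and optional warning ranges. Timestamps are Unix epoch seconds (GMT).",
  "type": "object",
  "required": ["groups"],
  "properties": {
    "groups": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["label", "measurements"],
        "properties": {
          "label": {"type": "string", "minLength": 1},
          "measurements": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "object",
              "required": ["label", "recommended", "samples"],
              "properties": {
                "label": {"type": "string", "minLength": 1},
                "units": {"type": "string"},
                "recommended": {
                  "type": "object",
                  "required": ["min", "max"],
                  "properties": {
                    "min": {"type": "number"},
                    "max": {"type": "number"}
                  }
                },
                "warning": {
                  "type": "object",
                  "properties": {
                    "min": {"type": "number"},
                    "max": {"type": "number"}
                  }
                },
                "samples": {
                  "type": "array",
                  "items": {
                    "type": "object",
                    "required": ["timestamp", "value"],
                    "properties": {
                      "timestamp": {"type": "integer", "minimum": 0},
                      "value": {"type": "number"}
                    }
                  }
                }
              }
            }
          }
        }
      }
    }
  }
}
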