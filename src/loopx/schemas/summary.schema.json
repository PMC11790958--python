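{
  "additionalProperties": false,
  "properties": {
    "experiment_id": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "title": "Experiment Id"
    },
    "n_tethers": {
      "title": "N Tethers",
      "type": "integer"
    },
    "n_looped": {
      "title": "N Looped",
      "type": "integer"
    },
    "fraction_looped": {
      "title": "Fraction Looped",
      "type": "number"
    },
    "acquisition_span_s": {
      "title": "Acquisition Span S",
      "type": "number"
    },
    "rates_kbp_per_s": {
      "items": {
        "type": "number"
      },
      "title": "Rates Kbp Per S",
      "type": "array"
    }
  },
  "required": [
    "experiment_id",
    "n_tethers",
    "n_looped",
    "fraction_looped",
    "acquisition_span_s",
    "rates_kbp_per_s"
  ],
  "title": "SummaryDocument",
  "type": "object"
}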