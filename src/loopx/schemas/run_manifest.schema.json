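{
  "$defs": {
    "PipelineConfig": {
      "additionalProperties": false,
      "description": "All stage parameters; unknown keys are rejected.",
      "properties": {
        "median_radius": {
          "default": 2,
          "title": "Median Radius",
          "type": "integer"
        },
        "tophat_radius": {
          "default": 10,
          "title": "Tophat Radius",
          "type": "integer"
        },
        "band_half_width": {
          "default": 5,
          "title": "Band Half Width",
          "type": "integer"
        },
        "axis_col": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Axis Col"
        },
        "quantify_on_tophat": {
          "default": false,
          "title": "Quantify On Tophat",
          "type": "boolean"
        },
        "min_prominence": {
          "default": 0.05,
          "title": "Min Prominence",
          "type": "number"
        },
        "search_range": {
          "default": 10.0,
          "title": "Search Range",
          "type": "number"
        },
        "memory": {
          "default": 3,
          "title": "Memory",
          "type": "integer"
        },
        "min_track_length": {
          "default": 10,
          "title": "Min Track Length",
          "type": "integer"
        },
        "loop_halfwidth": {
          "default": 4,
          "title": "Loop Halfwidth",
          "type": "integer"
        },
        "savgol_order": {
          "default": 2,
          "title": "Savgol Order",
          "type": "integer"
        },
        "savgol_window": {
          "default": 50,
          "title": "Savgol Window",
          "type": "integer"
        },
        "fit_window_s": {
          "default": 5.0,
          "title": "Fit Window S",
          "type": "number"
        },
        "monotone_tol": {
          "default": 0.5,
          "title": "Monotone Tol",
          "type": "number"
        },
        "init_threshold": {
          "default": 1.0,
          "title": "Init Threshold",
          "type": "number"
        },
        "on_slipback": {
          "default": "reselect",
          "title": "On Slipback",
          "type": "string"
        },
        "acquisition_span_s": {
          "default": 1000.0,
          "title": "Acquisition Span S",
          "type": "number"
        },
        "total_dna_kbp": {
          "default": 48.5,
          "title": "Total Dna Kbp",
          "type": "number"
        },
        "frame_interval_s": {
          "default": 1.0,
          "title": "Frame Interval S",
          "type": "number"
        },
        "seed": {
          "default": 0,
          "title": "Seed",
          "type": "integer"
        },
        "output_dir": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Output Dir"
        }
      },
      "title": "PipelineConfig",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Machine-readable record of one pipeline run.",
  "properties": {
    "loopx_version": {
      "title": "Loopx Version",
      "type": "string"
    },
    "python_version": {
      "title": "Python Version",
      "type": "string"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "config_hash": {
      "title": "Config Hash",
      "type": "string"
    },
    "config": {
      "$ref": "#/$defs/PipelineConfig"
    },
    "n_tethers": {
      "title": "N Tethers",
      "type": "integer"
    },
    "n_looped": {
      "title": "N Looped",
      "type": "integer"
    },
    "n_rate_events": {
      "title": "N Rate Events",
      "type": "integer"
    },
    "excluded": {
      "additionalProperties": {
        "type": "integer"
      },
      "title": "Excluded",
      "type": "object"
    }
  },
  "required": [
    "loopx_version",
    "python_version",
    "seed",
    "config_hash",
    "config",
    "n_tethers",
    "n_looped",
    "n_rate_events",
    "excluded"
  ],
  "title": "RunManifest",
  "type": "object"
}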