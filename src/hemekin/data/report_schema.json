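{
  "$defs": {
    "ExpFitReport": {
      "properties": {
        "amplitudes": {
          "items": {
            "type": "number"
          },
          "title": "Amplitudes",
          "type": "array"
        },
        "co_uM": {
          "title": "Co Um",
          "type": "number"
        },
        "rates": {
          "items": {
            "type": "number"
          },
          "title": "Rates",
          "type": "array"
        },
        "ssr": {
          "title": "Ssr",
          "type": "number"
        }
      },
      "required": [
        "co_uM",
        "rates",
        "amplitudes",
        "ssr"
      ],
      "title": "ExpFitReport",
      "type": "object"
    },
    "LfpReport": {
      "properties": {
        "f_gem": {
          "title": "F Gem",
          "type": "number"
        },
        "fits": {
          "items": {
            "$ref": "#/$defs/ExpFitReport"
          },
          "title": "Fits",
          "type": "array"
        },
        "k_gem": {
          "title": "K Gem",
          "type": "number"
        },
        "k_on_co": {
          "title": "K On Co",
          "type": "number"
        },
        "k_on_co_intercept": {
          "title": "K On Co Intercept",
          "type": "number"
        },
        "k_on_co_se": {
          "title": "K On Co Se",
          "type": "number"
        },
        "n_components": {
          "title": "N Components",
          "type": "integer"
        },
        "phase_labels": {
          "items": {
            "type": "string"
          },
          "title": "Phase Labels",
          "type": "array"
        }
      },
      "required": [
        "n_components",
        "fits",
        "phase_labels",
        "k_on_co",
        "k_on_co_se",
        "k_on_co_intercept",
        "f_gem",
        "k_gem"
      ],
      "title": "LfpReport",
      "type": "object"
    },
    "PipelineConfig": {
      "properties": {
        "a_t": {
          "default": 0.1,
          "title": "A T",
          "type": "number"
        },
        "co_lfp": {
          "items": {
            "type": "number"
          },
          "title": "Co Lfp",
          "type": "array"
        },
        "co_sf": {
          "items": {
            "type": "number"
          },
          "title": "Co Sf",
          "type": "array"
        },
        "n_components": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "string"
            }
          ],
          "default": "auto",
          "title": "N Components"
        },
        "noise_sd": {
          "default": 0.0,
          "title": "Noise Sd",
          "type": "number"
        },
        "protein": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Protein"
        },
        "seed": {
          "default": 0,
          "title": "Seed",
          "type": "integer"
        },
        "traces_dir": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Traces Dir"
        }
      },
      "title": "PipelineConfig",
      "type": "object"
    },
    "SfPointReport": {
      "properties": {
        "a_t": {
          "title": "A T",
          "type": "number"
        },
        "co_uM": {
          "title": "Co Um",
          "type": "number"
        },
        "f_h": {
          "title": "F H",
          "type": "number"
        },
        "k_fast": {
          "title": "K Fast",
          "type": "number"
        },
        "k_obs": {
          "title": "K Obs",
          "type": "number"
        }
      },
      "required": [
        "co_uM",
        "k_fast",
        "k_obs",
        "f_h",
        "a_t"
      ],
      "title": "SfPointReport",
      "type": "object"
    },
    "SfReport": {
      "properties": {
        "f_h": {
          "title": "F H",
          "type": "number"
        },
        "k_h": {
          "title": "K H",
          "type": "number"
        },
        "k_off_h": {
          "title": "K Off H",
          "type": "number"
        },
        "k_off_h_se": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "K Off H Se"
        },
        "k_on_h": {
          "title": "K On H",
          "type": "number"
        },
        "k_on_h_se": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "K On H Se"
        },
        "points": {
          "items": {
            "$ref": "#/$defs/SfPointReport"
          },
          "title": "Points",
          "type": "array"
        }
      },
      "required": [
        "points",
        "k_on_h",
        "k_off_h",
        "k_h",
        "f_h"
      ],
      "title": "SfReport",
      "type": "object"
    },
    "TruthReport": {
      "description": "Generating parameters, present only for synthetic runs.",
      "properties": {
        "f_gem": {
          "title": "F Gem",
          "type": "number"
        },
        "k_gem": {
          "title": "K Gem",
          "type": "number"
        },
        "k_off_h": {
          "title": "K Off H",
          "type": "number"
        },
        "k_on_co": {
          "title": "K On Co",
          "type": "number"
        },
        "k_on_h": {
          "title": "K On H",
          "type": "number"
        }
      },
      "required": [
        "k_on_co",
        "k_on_h",
        "k_off_h",
        "f_gem",
        "k_gem"
      ],
      "title": "TruthReport",
      "type": "object"
    }
  },
  "properties": {
    "config": {
      "$ref": "#/$defs/PipelineConfig"
    },
    "lfp": {
      "$ref": "#/$defs/LfpReport"
    },
    "sf": {
      "$ref": "#/$defs/SfReport"
    },
    "truth": {
      "anyOf": [
        {
          "items": {
            "$ref": "#/$defs/TruthReport"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Truth"
    }
  },
  "required": [
    "config",
    "lfp",
    "sf"
  ],
  "title": "PipelineReport",
  "type": "object"
}
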