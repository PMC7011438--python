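{
  "$defs": {
    "ReferenceRegion": {
      "properties": {
        "lo": {
          "title": "Lo",
          "type": "number"
        },
        "hi": {
          "title": "Hi",
          "type": "number"
        },
        "label": {
          "title": "Label",
          "type": "string"
        }
      },
      "required": [
        "lo",
        "hi",
        "label"
      ],
      "title": "ReferenceRegion",
      "type": "object"
    },
    "Series": {
      "properties": {
        "label": {
          "title": "Label",
          "type": "string"
        },
        "times_days": {
          "items": {
            "type": "number"
          },
          "title": "Times Days",
          "type": "array"
        },
        "values": {
          "items": {
            "type": "number"
          },
          "title": "Values",
          "type": "array"
        },
        "unit": {
          "title": "Unit",
          "type": "string"
        }
      },
      "required": [
        "label",
        "times_days",
        "values",
        "unit"
      ],
      "title": "Series",
      "type": "object"
    },
    "TherapyBar": {
      "properties": {
        "start_day": {
          "title": "Start Day",
          "type": "number"
        },
        "end_day": {
          "title": "End Day",
          "type": "number"
        },
        "drug": {
          "title": "Drug",
          "type": "string"
        },
        "dose_label": {
          "default": "",
          "title": "Dose Label",
          "type": "string"
        }
      },
      "required": [
        "start_day",
        "end_day",
        "drug"
      ],
      "title": "TherapyBar",
      "type": "object"
    }
  },
  "description": "Renderable content of one patient view.",
  "properties": {
    "pseudonym": {
      "title": "Pseudonym",
      "type": "string"
    },
    "view": {
      "title": "View",
      "type": "string"
    },
    "observations": {
      "$ref": "#/$defs/Series"
    },
    "model_central": {
      "anyOf": [
        {
          "$ref": "#/$defs/Series"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "model_lower": {
      "anyOf": [
        {
          "$ref": "#/$defs/Series"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "model_upper": {
      "anyOf": [
        {
          "$ref": "#/$defs/Series"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "band_level": {
      "anyOf": [
        {
          "exclusiveMaximum": 1,
          "exclusiveMinimum": 0,
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Band Level"
    },
    "therapy_bars": {
      "items": {
        "$ref": "#/$defs/TherapyBar"
      },
      "title": "Therapy Bars",
      "type": "array"
    },
    "reference_regions": {
      "items": {
        "$ref": "#/$defs/ReferenceRegion"
      },
      "title": "Reference Regions",
      "type": "array"
    },
    "latent_series": {
      "anyOf": [
        {
          "$ref": "#/$defs/Series"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    }
  },
  "required": [
    "pseudonym",
    "view",
    "observations"
  ],
  "title": "PlotBundle",
  "type": "object"
}
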