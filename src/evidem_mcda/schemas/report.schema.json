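{
  "$defs": {
    "CriterionContribution": {
      "properties": {
        "Sx": {
          "title": "Sx",
          "type": "number"
        },
        "Vx": {
          "title": "Vx",
          "type": "number"
        },
        "Wx": {
          "title": "Wx",
          "type": "number"
        },
        "criterion": {
          "title": "Criterion",
          "type": "string"
        }
      },
      "required": [
        "criterion",
        "Wx",
        "Sx",
        "Vx"
      ],
      "title": "CriterionContribution",
      "type": "object"
    },
    "InterventionReport": {
      "properties": {
        "V": {
          "title": "V",
          "type": "number"
        },
        "V_rounded": {
          "title": "V Rounded",
          "type": "number"
        },
        "contributions": {
          "items": {
            "$ref": "#/$defs/CriterionContribution"
          },
          "title": "Contributions",
          "type": "array"
        },
        "intervention": {
          "title": "Intervention",
          "type": "string"
        },
        "n_criteria": {
          "title": "N Criteria",
          "type": "integer"
        }
      },
      "required": [
        "intervention",
        "V",
        "V_rounded",
        "n_criteria",
        "contributions"
      ],
      "title": "InterventionReport",
      "type": "object"
    },
    "RankingEntry": {
      "properties": {
        "V": {
          "title": "V",
          "type": "number"
        },
        "intervention": {
          "title": "Intervention",
          "type": "string"
        },
        "rank": {
          "title": "Rank",
          "type": "integer"
        }
      },
      "required": [
        "rank",
        "intervention",
        "V"
      ],
      "title": "RankingEntry",
      "type": "object"
    }
  },
  "description": "Full appraisal report; every numeric field is a stage output.",
  "properties": {
    "generated_at": {
      "default": "",
      "title": "Generated At",
      "type": "string"
    },
    "included_criteria": {
      "items": {
        "type": "string"
      },
      "title": "Included Criteria",
      "type": "array"
    },
    "interventions": {
      "items": {
        "$ref": "#/$defs/InterventionReport"
      },
      "title": "Interventions",
      "type": "array"
    },
    "n_panelists": {
      "title": "N Panelists",
      "type": "integer"
    },
    "normalized_weights": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Normalized Weights",
      "type": "object"
    },
    "policy": {
      "title": "Policy",
      "type": "string"
    },
    "rank_stability": {
      "anyOf": [
        {
          "additionalProperties": true,
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Rank Stability"
    },
    "ranking": {
      "items": {
        "$ref": "#/$defs/RankingEntry"
      },
      "title": "Ranking",
      "type": "array"
    },
    "schema_version": {
      "default": "1",
      "title": "Schema Version",
      "type": "string"
    },
    "seed": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Seed"
    },
    "unscored_criteria": {
      "items": {
        "type": "string"
      },
      "title": "Unscored Criteria",
      "type": "array"
    },
    "unweighted_criteria": {
      "items": {
        "type": "string"
      },
      "title": "Unweighted Criteria",
      "type": "array"
    },
    "weight_denominator": {
      "title": "Weight Denominator",
      "type": "number"
    }
  },
  "required": [
    "policy",
    "n_panelists",
    "included_criteria",
    "unweighted_criteria",
    "unscored_criteria",
    "weight_denominator",
    "normalized_weights",
    "interventions",
    "ranking"
  ],
  "title": "Report",
  "type": "object"
}
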