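{
  "$defs": {
    "FitReport": {
      "properties": {
        "loglik": {
          "title": "Loglik",
          "type": "number"
        },
        "method": {
          "title": "Method",
          "type": "string"
        },
        "converged": {
          "title": "Converged",
          "type": "boolean"
        },
        "boundary": {
          "default": false,
          "title": "Boundary",
          "type": "boolean"
        },
        "n_groups": {
          "minimum": 1,
          "title": "N Groups",
          "type": "integer"
        },
        "iterations": {
          "minimum": 0,
          "title": "Iterations",
          "type": "integer"
        },
        "beta": {
          "items": {
            "type": "number"
          },
          "title": "Beta",
          "type": "array"
        },
        "Sigma": {
          "items": {
            "items": {
              "type": "number"
            },
            "type": "array"
          },
          "title": "Sigma",
          "type": "array"
        },
        "sigma2_eps": {
          "minimum": 0,
          "title": "Sigma2 Eps",
          "type": "number"
        }
      },
      "required": [
        "loglik",
        "method",
        "converged",
        "n_groups",
        "iterations",
        "beta",
        "Sigma",
        "sigma2_eps"
      ],
      "title": "FitReport",
      "type": "object"
    },
    "PartitionReport": {
      "properties": {
        "sigma2_f": {
          "minimum": 0,
          "title": "Sigma2 F",
          "type": "number"
        },
        "sigma2_terms": {
          "items": {
            "type": "number"
          },
          "title": "Sigma2 Terms",
          "type": "array"
        },
        "sigma2_e": {
          "minimum": 0,
          "title": "Sigma2 E",
          "type": "number"
        },
        "sigma2_d": {
          "minimum": 0,
          "title": "Sigma2 D",
          "type": "number"
        }
      },
      "required": [
        "sigma2_f",
        "sigma2_terms",
        "sigma2_e",
        "sigma2_d"
      ],
      "title": "PartitionReport",
      "type": "object"
    }
  },
  "description": "Full variance-partition report written by the ``r2`` command.",
  "properties": {
    "partition": {
      "$ref": "#/$defs/PartitionReport"
    },
    "r2_marginal": {
      "maximum": 1,
      "minimum": 0,
      "title": "R2 Marginal",
      "type": "number"
    },
    "r2_conditional": {
      "maximum": 1,
      "minimum": 0,
      "title": "R2 Conditional",
      "type": "number"
    },
    "family_link": {
      "title": "Family Link",
      "type": "string"
    },
    "fit": {
      "anyOf": [
        {
          "$ref": "#/$defs/FitReport"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    }
  },
  "required": [
    "partition",
    "r2_marginal",
    "r2_conditional",
    "family_link"
  ],
  "title": "R2Report",
  "type": "object"
}
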