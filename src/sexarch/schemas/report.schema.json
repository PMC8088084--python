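{
 "$defs": {
  "BiasSummaryRow": {
   "properties": {
    "leg": {
     "title": "Leg",
     "type": "integer"
    },
    "n_expressed": {
     "title": "N Expressed",
     "type": "integer"
    },
    "n_male_biased": {
     "title": "N Male Biased",
     "type": "integer"
    },
    "pct_male_biased": {
     "title": "Pct Male Biased",
     "type": "number"
    },
    "n_female_biased": {
     "title": "N Female Biased",
     "type": "integer"
    },
    "pct_female_biased": {
     "title": "Pct Female Biased",
     "type": "number"
    }
   },
   "required": [
    "leg",
    "n_expressed",
    "n_male_biased",
    "pct_male_biased",
    "n_female_biased",
    "pct_female_biased"
   ],
   "title": "BiasSummaryRow",
   "type": "object"
  },
  "ClusterSection": {
   "properties": {
    "leg": {
     "title": "Leg",
     "type": "integer"
    },
    "direction": {
     "title": "Direction",
     "type": "string"
    },
    "observed_proportion": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "title": "Observed Proportion"
    },
    "null_mean": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "title": "Null Mean"
    },
    "interval": {
     "maxItems": 2,
     "minItems": 2,
     "prefixItems": [
      {
       "type": "number"
      },
      {
       "type": "number"
      }
     ],
     "title": "Interval",
     "type": "array"
    },
    "significant": {
     "title": "Significant",
     "type": "boolean"
    }
   },
   "required": [
    "leg",
    "direction",
    "observed_proportion",
    "null_mean",
    "interval",
    "significant"
   ],
   "title": "ClusterSection",
   "type": "object"
  },
  "CrosstalkSection": {
   "properties": {
    "leg": {
     "title": "Leg",
     "type": "integer"
    },
    "sex_direction": {
     "title": "Sex Direction",
     "type": "string"
    },
    "overlap_count": {
     "title": "Overlap Count",
     "type": "integer"
    },
    "n_sex_biased": {
     "title": "N Sex Biased",
     "type": "integer"
    },
    "overlap_pct": {
     "title": "Overlap Pct",
     "type": "number"
    },
    "pvalue": {
     "title": "Pvalue",
     "type": "number"
    }
   },
   "required": [
    "leg",
    "sex_direction",
    "overlap_count",
    "n_sex_biased",
    "overlap_pct",
    "pvalue"
   ],
   "title": "CrosstalkSection",
   "type": "object"
  },
  "DndsSection": {
   "properties": {
    "pair": {
     "title": "Pair",
     "type": "string"
    },
    "pvalue": {
     "title": "Pvalue",
     "type": "number"
    },
    "medians": {
     "additionalProperties": {
      "type": "number"
     },
     "title": "Medians",
     "type": "object"
    },
    "n_excluded": {
     "title": "N Excluded",
     "type": "integer"
    },
    "bootstrap_cutoff": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Bootstrap Cutoff"
    },
    "nonrandom": {
     "anyOf": [
      {
       "type": "boolean"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Nonrandom"
    }
   },
   "required": [
    "pair",
    "pvalue",
    "medians",
    "n_excluded"
   ],
   "title": "DndsSection",
   "type": "object"
  },
  "RegionRow": {
   "properties": {
    "scaffold": {
     "title": "Scaffold",
     "type": "string"
    },
    "start": {
     "title": "Start",
     "type": "integer"
    },
    "end": {
     "title": "End",
     "type": "integer"
    },
    "direction": {
     "title": "Direction",
     "type": "string"
    },
    "n_windows": {
     "title": "N Windows",
     "type": "integer"
    },
    "leg": {
     "title": "Leg",
     "type": "integer"
    }
   },
   "required": [
    "scaffold",
    "start",
    "end",
    "direction",
    "n_windows",
    "leg"
   ],
   "title": "RegionRow",
   "type": "object"
  },
  "XSection": {
   "properties": {
    "x_scaffold": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "title": "X Scaffold"
    },
    "coverage_ratio": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "title": "Coverage Ratio"
    },
    "y_candidates": {
     "items": {
      "type": "string"
     },
     "title": "Y Candidates",
     "type": "array"
    },
    "dosage_p_by_leg": {
     "additionalProperties": {
      "anyOf": [
       {
        "type": "number"
       },
       {
        "type": "null"
       }
      ]
     },
     "title": "Dosage P By Leg",
     "type": "object"
    },
    "fisher_by_leg": {
     "additionalProperties": {
      "additionalProperties": {
       "anyOf": [
        {
         "type": "number"
        },
        {
         "type": "null"
        }
       ]
      },
      "type": "object"
     },
     "title": "Fisher By Leg",
     "type": "object"
    }
   },
   "required": [
    "x_scaffold",
    "coverage_ratio",
    "y_candidates",
    "dosage_p_by_leg",
    "fisher_by_leg"
   ],
   "title": "XSection",
   "type": "object"
  }
 },
 "properties": {
  "seed": {
   "title": "Seed",
   "type": "integer"
  },
  "config_hash": {
   "title": "Config Hash",
   "type": "string"
  },
  "bias_summary": {
   "items": {
    "$ref": "#/$defs/BiasSummaryRow"
   },
   "title": "Bias Summary",
   "type": "array"
  },
  "crosstalk": {
   "items": {
    "$ref": "#/$defs/CrosstalkSection"
   },
   "title": "Crosstalk",
   "type": "array"
  },
  "x_chromosome": {
   "anyOf": [
    {
     "$ref": "#/$defs/XSection"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "regions": {
   "items": {
    "$ref": "#/$defs/RegionRow"
   },
   "title": "Regions",
   "type": "array"
  },
  "clusters": {
   "items": {
    "$ref": "#/$defs/ClusterSection"
   },
   "title": "Clusters",
   "type": "array"
  },
  "dnds": {
   "items": {
    "$ref": "#/$defs/DndsSection"
   },
   "title": "Dnds",
   "type": "array"
  }
 },
 "required": [
  "seed",
  "config_hash",
  "bias_summary"
 ],
 "title": "RunReport",
 "type": "object"
}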