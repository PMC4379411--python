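{
 "$defs": {
  "ConservationReport": {
   "properties": {
    "host_intron_percentiles": {
     "items": {
      "$ref": "#/$defs/HostIntronPercentile"
     },
     "title": "Host Intron Percentiles",
     "type": "array"
    },
    "mean_identity_by_group": {
     "additionalProperties": {
      "type": "number"
     },
     "title": "Mean Identity By Group",
     "type": "object"
    },
    "perfect_runs": {
     "items": {
      "$ref": "#/$defs/PerfectRunReport"
     },
     "title": "Perfect Runs",
     "type": "array"
    }
   },
   "title": "ConservationReport",
   "type": "object"
  },
  "GroupHistory": {
   "properties": {
    "cost": {
     "title": "Cost",
     "type": "integer"
    },
    "fitch_cost": {
     "title": "Fitch Cost",
     "type": "integer"
    },
    "gain_branch": {
     "anyOf": [
      {
       "items": {
        "type": "string"
       },
       "type": "array"
      },
      {
       "type": "null"
      }
     ],
     "title": "Gain Branch"
    },
    "group": {
     "title": "Group",
     "type": "string"
    },
    "loss_branches": {
     "items": {
      "items": {
       "type": "string"
      },
      "type": "array"
     },
     "title": "Loss Branches",
     "type": "array"
    },
    "present_leaves": {
     "items": {
      "type": "string"
     },
     "title": "Present Leaves",
     "type": "array"
    }
   },
   "required": [
    "group",
    "gain_branch",
    "loss_branches",
    "cost",
    "fitch_cost",
    "present_leaves"
   ],
   "title": "GroupHistory",
   "type": "object"
  },
  "HostIntronPercentile": {
   "properties": {
    "gene_id": {
     "title": "Gene Id",
     "type": "string"
    },
    "group": {
     "title": "Group",
     "type": "string"
    },
    "host_intron": {
     "title": "Host Intron",
     "type": "integer"
    },
    "intron_length": {
     "title": "Intron Length",
     "type": "integer"
    },
    "percentile": {
     "title": "Percentile",
     "type": "number"
    },
    "top_fraction": {
     "title": "Top Fraction",
     "type": "number"
    }
   },
   "required": [
    "gene_id",
    "group",
    "host_intron",
    "intron_length",
    "percentile",
    "top_fraction"
   ],
   "title": "HostIntronPercentile",
   "type": "object"
  },
  "OriginReport": {
   "properties": {
    "ambiguous_groups": {
     "items": {
      "type": "string"
     },
     "title": "Ambiguous Groups",
     "type": "array"
    },
    "histories": {
     "items": {
      "$ref": "#/$defs/GroupHistory"
     },
     "title": "Histories",
     "type": "array"
    },
    "linked_pairs": {
     "items": {
      "items": {
       "type": "string"
      },
      "type": "array"
     },
     "title": "Linked Pairs",
     "type": "array"
    },
    "n_groups": {
     "title": "N Groups",
     "type": "integer"
    },
    "verdict": {
     "title": "Verdict",
     "type": "string"
    }
   },
   "required": [
    "verdict",
    "n_groups"
   ],
   "title": "OriginReport",
   "type": "object"
  },
  "PerfectRunReport": {
   "properties": {
    "end": {
     "title": "End",
     "type": "integer"
    },
    "group": {
     "title": "Group",
     "type": "string"
    },
    "length": {
     "title": "Length",
     "type": "integer"
    },
    "n_sequences": {
     "title": "N Sequences",
     "type": "integer"
    },
    "start": {
     "title": "Start",
     "type": "integer"
    }
   },
   "required": [
    "group",
    "start",
    "end",
    "length",
    "n_sequences"
   ],
   "title": "PerfectRunReport",
   "type": "object"
  },
  "StageRecord": {
   "properties": {
    "hash": {
     "title": "Hash",
     "type": "string"
    },
    "inputs": {
     "additionalProperties": {
      "type": "string"
     },
     "title": "Inputs",
     "type": "object"
    },
    "name": {
     "title": "Name",
     "type": "string"
    },
    "outputs": {
     "additionalProperties": {
      "type": "string"
     },
     "title": "Outputs",
     "type": "object"
    }
   },
   "required": [
    "name",
    "hash"
   ],
   "title": "StageRecord",
   "type": "object"
  },
  "SubfamilyCall": {
   "properties": {
    "gene_id": {
     "title": "Gene Id",
     "type": "string"
    },
    "label": {
     "title": "Label",
     "type": "string"
    },
    "score": {
     "title": "Score",
     "type": "number"
    }
   },
   "required": [
    "gene_id",
    "label",
    "score"
   ],
   "title": "SubfamilyCall",
   "type": "object"
  }
 },
 "description": "Everything one pipeline run produced, with recovery metrics when the\ninputs came from the simulator (metrics are absent otherwise).",
 "properties": {
  "conservation": {
   "anyOf": [
    {
     "$ref": "#/$defs/ConservationReport"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "event_counts": {
   "additionalProperties": {
    "type": "integer"
   },
   "title": "Event Counts",
   "type": "object"
  },
  "files": {
   "additionalProperties": {
    "type": "string"
   },
   "title": "Files",
   "type": "object"
  },
  "metrics": {
   "anyOf": [
    {
     "additionalProperties": {
      "type": "number"
     },
     "type": "object"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Metrics"
  },
  "n_characters": {
   "default": 0,
   "title": "N Characters",
   "type": "integer"
  },
  "n_genes": {
   "default": 0,
   "title": "N Genes",
   "type": "integer"
  },
  "n_stabilized": {
   "anyOf": [
    {
     "type": "integer"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "N Stabilized"
  },
  "nmd_verdict_counts": {
   "additionalProperties": {
    "type": "integer"
   },
   "title": "Nmd Verdict Counts",
   "type": "object"
  },
  "origin": {
   "anyOf": [
    {
     "$ref": "#/$defs/OriginReport"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "parameters": {
   "additionalProperties": true,
   "title": "Parameters",
   "type": "object"
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
  "stages": {
   "items": {
    "$ref": "#/$defs/StageRecord"
   },
   "title": "Stages",
   "type": "array"
  },
  "subfamilies": {
   "items": {
    "$ref": "#/$defs/SubfamilyCall"
   },
   "title": "Subfamilies",
   "type": "array"
  }
 },
 "title": "RunReport",
 "type": "object"
}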