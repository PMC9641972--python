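{
  "$defs": {
    "DiversityModel": {
      "properties": {
        "alpha_group_means": {
          "additionalProperties": {
            "additionalProperties": {
              "type": "number"
            },
            "type": "object"
          },
          "title": "Alpha Group Means",
          "type": "object"
        },
        "kruskal_shannon": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Kruskal Shannon",
          "type": "object"
        },
        "permanova": {
          "$ref": "#/$defs/TestResultModel"
        },
        "anosim": {
          "$ref": "#/$defs/TestResultModel"
        },
        "beta_dispersion_mean": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Beta Dispersion Mean",
          "type": "object"
        }
      },
      "required": [
        "alpha_group_means",
        "kruskal_shannon",
        "permanova",
        "anosim",
        "beta_dispersion_mean"
      ],
      "title": "DiversityModel",
      "type": "object"
    },
    "MantelModel": {
      "properties": {
        "r": {
          "title": "R",
          "type": "number"
        },
        "p_value": {
          "title": "P Value",
          "type": "number"
        },
        "n_perm": {
          "title": "N Perm",
          "type": "integer"
        },
        "controlled": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Controlled"
        }
      },
      "required": [
        "r",
        "p_value",
        "n_perm"
      ],
      "title": "MantelModel",
      "type": "object"
    },
    "NcmModel": {
      "properties": {
        "m": {
          "title": "M",
          "type": "number"
        },
        "Nm": {
          "title": "Nm",
          "type": "number"
        },
        "r_squared": {
          "title": "R Squared",
          "type": "number"
        },
        "N": {
          "title": "N",
          "type": "number"
        },
        "detection_limit": {
          "title": "Detection Limit",
          "type": "number"
        },
        "n_taxa": {
          "title": "N Taxa",
          "type": "integer"
        }
      },
      "required": [
        "m",
        "Nm",
        "r_squared",
        "N",
        "detection_limit",
        "n_taxa"
      ],
      "title": "NcmModel",
      "type": "object"
    },
    "NetworkModel": {
      "properties": {
        "topology": {
          "additionalProperties": {
            "anyOf": [
              {
                "type": "number"
              },
              {
                "type": "integer"
              },
              {
                "type": "null"
              }
            ]
          },
          "title": "Topology",
          "type": "object"
        },
        "n_modules": {
          "title": "N Modules",
          "type": "integer"
        },
        "subnetworks": {
          "additionalProperties": {
            "$ref": "#/$defs/SubnetworkModel"
          },
          "title": "Subnetworks",
          "type": "object"
        }
      },
      "required": [
        "topology",
        "n_modules",
        "subnetworks"
      ],
      "title": "NetworkModel",
      "type": "object"
    },
    "NicheModel": {
      "properties": {
        "community_breadth_group_means": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Community Breadth Group Means",
          "type": "object"
        },
        "kruskal": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Kruskal",
          "type": "object"
        }
      },
      "required": [
        "community_breadth_group_means",
        "kruskal"
      ],
      "title": "NicheModel",
      "type": "object"
    },
    "PartitionModel": {
      "properties": {
        "fractions": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Fractions",
          "type": "object"
        },
        "n_pairs": {
          "title": "N Pairs",
          "type": "integer"
        },
        "mean_bnti": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Mean Bnti"
        }
      },
      "required": [
        "fractions",
        "n_pairs"
      ],
      "title": "PartitionModel",
      "type": "object"
    },
    "SubnetworkModel": {
      "properties": {
        "n_nodes": {
          "title": "N Nodes",
          "type": "integer"
        },
        "n_edges": {
          "title": "N Edges",
          "type": "integer"
        },
        "graph_density": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Graph Density"
        },
        "average_degree": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Average Degree"
        }
      },
      "required": [
        "n_nodes",
        "n_edges"
      ],
      "title": "SubnetworkModel",
      "type": "object"
    },
    "TestResultModel": {
      "properties": {
        "statistic": {
          "title": "Statistic",
          "type": "number"
        },
        "p_value": {
          "title": "P Value",
          "type": "number"
        },
        "n_perm": {
          "title": "N Perm",
          "type": "integer"
        }
      },
      "required": [
        "statistic",
        "p_value",
        "n_perm"
      ],
      "title": "TestResultModel",
      "type": "object"
    }
  },
  "properties": {
    "config": {
      "additionalProperties": true,
      "title": "Config",
      "type": "object"
    },
    "seeds": {
      "additionalProperties": {
        "type": "integer"
      },
      "title": "Seeds",
      "type": "object"
    },
    "n_samples": {
      "title": "N Samples",
      "type": "integer"
    },
    "n_taxa": {
      "title": "N Taxa",
      "type": "integer"
    },
    "diversity": {
      "anyOf": [
        {
          "$ref": "#/$defs/DiversityModel"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "niche": {
      "anyOf": [
        {
          "$ref": "#/$defs/NicheModel"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "assembly": {
      "anyOf": [
        {
          "additionalProperties": {
            "$ref": "#/$defs/PartitionModel"
          },
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Assembly"
    },
    "ncm": {
      "anyOf": [
        {
          "additionalProperties": {
            "$ref": "#/$defs/NcmModel"
          },
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Ncm"
    },
    "network": {
      "anyOf": [
        {
          "$ref": "#/$defs/NetworkModel"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "mantel": {
      "anyOf": [
        {
          "additionalProperties": {
            "$ref": "#/$defs/MantelModel"
          },
          "type": "object"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Mantel"
    }
  },
  "required": [
    "config",
    "seeds",
    "n_samples",
    "n_taxa"
  ],
  "title": "PipelineReport",
  "type": "object"
}
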