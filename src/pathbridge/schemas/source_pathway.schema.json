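{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Source pathway fixture document",
  "description": "Reaction-centric pathway document consumed by pathbridge. Mirrors the Reactome data model: entities participate in role-typed reaction branches; complexes and entity sets list their components. Coordinates are diagram units, origin top-left, y downward.",
  "type": "object",
  "required": ["name", "organism"],
  "properties": {
    "name": {"type": "string"},
    "organism": {"type": "string"},
    "sourceVersion": {"type": "string"},
    "authors": {"type": "array", "items": {"type": "string"}},
    "maintainers": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name"],
        "properties": {"name": {"type": "string"}, "email": {"type": "string"}}
      }
    },
    "xref": {"$ref": "#/$defs/xref"},
    "entities": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "displayName", "class", "geometry"],
        "properties": {
          "id": {"type": "string"},
          "displayName": {"type": "string"},
          "class": {
            "enum": ["protein", "small_molecule", "rna", "gene", "process_node", "complex", "entity_set", "other"]
          },
          "compartment": {"type": "string"},
          "geometry": {
            "type": "object",
            "required": ["centerX", "centerY", "width", "height"],
            "properties": {
              "centerX": {"type": "number"},
              "centerY": {"type": "number"},
              "width": {"type": "number", "exclusiveMinimum": 0},
              "height": {"type": "number", "exclusiveMinimum": 0}
            }
          },
          "xrefs": {"type": "array", "items": {"$ref": "#/$defs/xref"}},
          "components": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["member"],
              "properties": {
                "member": {"type": "string"},
                "stoichiometry": {"type": "integer", "minimum": 1, "default": 1}
              }
            }
          },
          "literature": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "reactions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "branches", "backbonePoints"],
        "properties": {
          "id": {"type": "string"},
          "type": {
            "enum": ["transition", "binding", "dissociation", "omitted", "uncertain"],
            "default": "transition"
          },
          "branches": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["role", "entity"],
              "properties": {
                "role": {"enum": ["input", "output", "catalyst", "activator", "inhibitor"]},
                "entity": {"type": "string"},
                "stoichiometry": {"type": "integer", "minimum": 1, "default": 1}
              }
            }
          },
          "backbonePoints": {
            "type": "array",
            "minItems": 2,
            "items": {"type": "array", "prefixItems": [{"type": "number"}, {"type": "number"}]}
          },
          "xrefs": {"type": "array", "items": {"$ref": "#/$defs/xref"}},
          "literature": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "compartments": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name", "geometry"],
        "properties": {
          "id": {"type": "string"},
          "name": {"type": "string"},
          "geometry": {
            "type": "object",
            "required": ["x", "y", "width", "height"],
            "properties": {
              "x": {"type": "number"},
              "y": {"type": "number"},
              "width": {"type": "number", "exclusiveMinimum": 0},
              "height": {"type": "number", "exclusiveMinimum": 0}
            }
          },
          "membrane": {"type": "boolean", "default": false}
        }
      }
    },
    "notes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["text", "position"],
        "properties": {
          "text": {"type": "string", "minLength": 1},
          "position": {"type": "array", "prefixItems": [{"type": "number"}, {"type": "number"}]}
        }
      }
    }
  },
  "$defs": {
    "xref": {
      "type": "object",
      "required": ["dataSource", "identifier"],
      "properties": {
        "dataSource": {"enum": ["UniProt", "ChEBI", "Reactome", "Ensembl", "HMDB", "PubMed", "Other"]},
        "identifier": {"type": "string", "minLength": 1}
      }
    }
  }
}
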