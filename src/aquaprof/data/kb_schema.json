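{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "aquaprof alert knowledge base",
  "description": "Hierarchical structural-alert knowledge base: Tier 1 domains, Tier 2 mechanistic groups, Tier 3 mechanistic subgroups, molecular initiating events (MIEs), and SMARTS-based structural alerts. Serialized as YAML (canonical) or JSON.",
  "type": "object",
  "required": ["metadata", "domains", "groups", "subgroups", "mies", "alerts"],
  "properties": {
    "metadata": {
      "type": "object",
      "properties": {
        "name": {"type": "string"},
        "version": {"type": "string"},
        "source": {"type": "string"}
      }
    },
    "domains": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name"],
        "properties": {
          "id": {"type": "integer", "enum": [1, 2, 3]},
          "name": {"type": "string", "enum": ["narcosis", "reactive", "specific"]}
        }
      }
    },
    "groups": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name", "domain_id"],
        "properties": {
          "id": {"type": "string", "pattern": "^[123]\\.[0-9]+$"},
          "name": {"type": "string"},
          "domain_id": {"type": "integer"}
        }
      }
    },
    "subgroups": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name", "group_id"],
        "properties": {
          "id": {"type": "string", "pattern": "^[123]\\.[0-9]+\\.[0-9]+$"},
          "name": {"type": "string"},
          "group_id": {"type": "string"}
        }
      }
    },
    "mies": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name", "subgroup_id"],
        "properties": {
          "id": {"type": "string"},
          "name": {"type": "string"},
          "subgroup_id": {"type": "string"},
          "description": {"type": "string"}
        }
      }
    },
    "alerts": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name", "smarts_sequence", "mie_id", "taxa"],
        "properties": {
          "id": {"type": "string"},
          "name": {"type": "string"},
          "smarts_sequence": {
            "type": "array",
            "minItems": 1,
            "items": {"type": "string"},
            "description": "Ordered conjunction: every SMARTS must match."
          },
          "exclusions": {
            "type": "array",
            "items": {"type": "string"},
            "description": "Veto patterns: any match suppresses the alert."
          },
          "mie_id": {"type": "string"},
          "taxa": {"type": "array", "minItems": 1, "items": {"type": "string"}},
          "notes": {"type": "string"},
          "positive_examples": {"type": "array", "items": {"type": "string"}},
          "negative_examples": {"type": "array", "items": {"type": "string"}},
          "property_constraints": {
            "type": "object",
            "description": "Reserved for numeric property bounds (e.g. logP ranges); unused by the core KB."
          }
        }
      }
    }
  }
}
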