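{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://kgweave.invalid/schemas/graph_document.schema.json",
  "title": "GraphDocument",
  "description": "Serialized knowledge graph: a JSON object with keys 'nodes' and 'edges' (plus 'build_info' metadata). Node and edge field order in files written by kgweave follows the property order below.",
  "type": "object",
  "required": ["nodes", "edges"],
  "additionalProperties": false,
  "properties": {
    "build_info": {
      "type": "object",
      "description": "Build metadata: semantic-model version, source versions, build timestamp, stage name."
    },
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name", "category", "iri", "description", "provided_by", "publications"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string", "description": "CURIE (PREFIX:LOCAL_ID)"},
          "name": {"type": "string"},
          "category": {"type": "string", "description": "primary category from the semantic model"},
          "iri": {"type": "string"},
          "description": {"type": "string"},
          "provided_by": {"type": "array", "items": {"type": "string"}},
          "publications": {"type": "array", "items": {"type": "string"}},
          "all_categories": {
            "type": "array",
            "items": {"type": "string"},
            "description": "canonicalized graphs only: union of member categories"
          },
          "equivalent_identifiers": {
            "type": "array",
            "items": {"type": "string"},
            "description": "canonicalized graphs only: all pre-graph identifiers of the block, including 'id'"
          },
          "all_names": {
            "type": "array",
            "items": {"type": "string"},
            "description": "canonicalized graphs only: union of non-empty member names"
          }
        }
      }
    },
    "edges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["subject", "predicate", "object", "relation", "provided_by", "publications"],
        "additionalProperties": false,
        "properties": {
          "subject": {"type": "string"},
          "predicate": {"type": "string", "description": "normalized predicate from the semantic model"},
          "object": {"type": "string"},
          "relation": {"type": "array", "items": {"type": "string"}, "description": "original source relation phrasing(s)"},
          "provided_by": {"type": "array", "items": {"type": "string"}},
          "publications": {"type": "array", "items": {"type": "string"}}
        }
      }
    }
  }
}
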