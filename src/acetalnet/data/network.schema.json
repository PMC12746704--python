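{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "$id": "acetalnet-network-1.0",
 "title": "acetalnet reaction network file, schema version 1.0",
 "description": "Species and elementary steps of an acetalization reaction network. Energies are in the declared units (kJ/mol or eV) and are normalised to kJ/mol on load; entropies are always J/(K mol).",
 "type": "object",
 "required": ["units", "references", "species", "steps"],
 "properties": {
  "schema_version": {"type": "string"},
  "units": {"enum": ["kJ/mol", "eV"]},
  "temperature_K": {"type": "number", "exclusiveMinimum": 0, "default": 333.15},
  "references": {
   "type": "array", "minItems": 4, "maxItems": 4, "items": {"type": "string"},
   "description": "ids of the sugar, aldehyde, water and hydronium reference species, in stoich order (a, b, c, d)"
  },
  "species": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "role"],
    "properties": {
     "id": {"type": "string"},
     "role": {"enum": ["reference", "sugar_tautomer", "open_intermediate", "protonated_intermediate", "monoacetal", "diacetal", "transition_state", "small_molecule"]},
     "charge": {"type": "integer", "default": 0},
     "stoich": {"type": "array", "minItems": 4, "maxItems": 4, "items": {"type": "integer"}},
     "energy_terms": {
      "type": "object",
      "required": ["E", "ZPE", "S"],
      "properties": {
       "E": {"type": "number", "description": "electronic energy, file units"},
       "ZPE": {"type": "number", "minimum": 0, "description": "zero-point energy, file units"},
       "S": {"type": "number", "minimum": 0, "description": "entropy, J/(K mol)"}
      }
     },
     "g_formation": {"type": "number", "description": "formation free energy on the four-reference zero, file units"},
     "aliases": {"type": "array", "items": {"type": "string"}}
    }
   }
  },
  "steps": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "reactant", "product", "delta_g"],
    "properties": {
     "id": {"type": "string"},
     "reactant": {"type": "string"},
     "product": {"type": "string"},
     "delta_g": {"type": "number"},
     "g_a": {"type": "number", "minimum": 0, "description": "forward activation free energy; omitted = not computed, 0 = barrierless"},
     "ts_id": {"type": "string"},
     "consumes": {"type": "object", "additionalProperties": {"type": "integer"}},
     "releases": {"type": "object", "additionalProperties": {"type": "integer"}},
     "pathway_tags": {"type": "array", "items": {"type": "string"}},
     "reversible": {"type": "boolean", "default": false, "description": "when true, the file must also contain the reverse step with delta_g negated"}
    }
   }
  }
 }
}
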