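# JSON document formats

All documents are UTF-8 JSON; term names are NFC-normalized tokens.

## Ontology (`data/ontology.json`)

```json
{
 "version": "1",
 "provenance": "reconstructed ...",
 "structures": [{"name": "tooth", "parent": "calyx",
                 "synonyms": ["calyx-tooth"], "note": "..."}],
 "properties": [
  {"name": "length", "kind": "quantitative",
   "canonical_unit": "mm", "units": {"mm": 1.0, "cm": 10.0}},
  {"name": "shape", "kind": "qualitative", "states": ["ovate", "..."],
   "applicable_structures": []}
 ],
 "specifiers": [{"base_structure": "tooth", "discriminator": "class",
                 "allowed_values": ["shorter", "longer"]}]
}
```

Property kinds: `qualitative` (needs ≥1 state), `quantitative` (needs a
canonical unit present in its unit registry), `count`, `relative`.
An empty `applicable_structures` list means the property applies
everywhere. The part-of graph must be a tree; all references must
resolve (loaders raise named errors for dangling or duplicate terms).
Built-in ordinal specifier keywords: `first`, `uppermost`, `next-upper`,
`lower-part`, `upper-part`.

## Template (`data/template.json`)

```json
{"name": "arenosae-section",
 "slots": [{"path": "calyx", "property": "length",
            "label": "Calyx", "precision": 1, "unit": "mm"}]}
```

Slot order is total and drives rendering and canonical serialization.

## Description (`data/descriptions/*.json`)

```json
{
 "taxon": "Silene arenosa", "rank": "species",
 "parent": "Silene sect. Arenosae",
 "elements": [
  {"structure": "anthophore", "property": "length",
   "score": {"type": "range", "main": [4.0, 5.0], "unit": "mm"}},
  {"structure": "calyx", "property": "shape",
   "score": {"type": "states", "states": ["cylindrical"]},
   "modifiers": [{"kind": "temporal", "value": "at-anthesis"}]},
  {"structure": "internode[position=uppermost]",
   "property": "relative-length",
   "score": {"type": "relative", "relation": "obviously-longer-than",
             "reference": "internode[position=next-upper]"}},
  {"structure": "internode", "property": "count",
   "score": {"type": "count", "low": 2, "high": 3}},
  {"structure": "flower", "property": "flowering-time",
   "score": {"type": "states", "states": ["nocturnal"]},
   "supplemented": true}
 ]
}
```

Range scores may add `extreme_low` / `extreme_high` (the parenthetical
extremes of the printed notation). `supplemented: true` marks elements
recorded from notes or the key rather than the formal account.

## Key (`data/key.json`)

```json
{
 "name": "Key to species of Arenosae",
 "preamble": "...",
 "couplets": [
  {"id": 2, "leads": [
   {"predicates": [{"structure": "anthophore", "property": "length",
                    "comparator": ">", "value": 6, "unit": "mm"}],
    "goto": 3},
   {"predicates": [{"structure": "anthophore", "property": "length",
                    "comparator": "<", "value": 6, "unit": "mm"}],
    "goto": 5, "notes": ["..."]}
  ]}
 ]
}
```

Comparators: `<`, `>`, `<=`, `>=` (value+unit), `range-within`
(low/high/unit), `state-in` (states), `relative-is` (relation). A
predicate may set `soft: true` (hedged lead: unsatisfied → unknown) and
carry a free-text `note`. Each couplet has exactly two leads; each lead
has exactly one outcome (`goto` or `taxon`); ids are unique, the graph
is acyclic and reachable from the smallest id.
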