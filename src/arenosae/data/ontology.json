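{
 "properties": [
  {
   "applicable_structures": [],
   "canonical_unit": "mm",
   "kind": "quantitative",
   "name": "length",
   "states": [],
   "units": {
    "cm": 10.0,
    "mm": 1.0
   }
  },
  {
   "applicable_structures": [],
   "canonical_unit": "mm",
   "kind": "quantitative",
   "name": "width",
   "states": [],
   "units": {
    "cm": 10.0,
    "mm": 1.0
   }
  },
  {
   "applicable_structures": [],
   "canonical_unit": "mm",
   "kind": "quantitative",
   "name": "height",
   "states": [],
   "units": {
    "cm": 10.0,
    "mm": 1.0
   }
  },
  {
   "applicable_structures": [
    "internode",
    "style"
   ],
   "canonical_unit": null,
   "kind": "count",
   "name": "count",
   "states": [],
   "units": {}
  },
  {
   "applicable_structures": [],
   "canonical_unit": null,
   "kind": "qualitative",
   "name": "shape",
   "states": [
    "lanceolate",
    "oblanceolate",
    "linear",
    "ovate",
    "obovate",
    "elliptic",
    "oblong",
    "ellipsoid",
    "ovoid",
    "deltoid",
    "reniform",
    "spathulate",
    "cylindrical",
    "campanulate",
    "clavate"
   ],
   "units": {}
  },
  {
   "applicable_structures": [],
   "canonical_unit": null,
   "kind": "qualitative",
   "name": "habit",
   "states": [
    "erect",
    "spreading",
    "ascending"
   ],
   "units": {}
  },
  {
   "applicable_structures": [],
   "canonical_unit": null,
   "kind": "qualitative",
   "name": "pubescence",
   "states": [
    "glabrous",
    "pubescent",
    "sparsely-pubescent",
    "puberulent",
    "densely-puberulent",
    "tomentose",
    "densely-tomentose",
    "villous",
    "scabrous",
    "ciliate",
    "papillate"
   ],
   "units": {}
  },
  {
   "applicable_structures": [
    "calyx"
   ],
   "canonical_unit": null,
   "kind": "qualitative",
   "name": "papillae",
   "states": [
    "present",
    "absent"
   ],
   "units": {}
  },
  {
   "applicable_structures": [],
   "canonical_unit": null,
   "kind": "qualitative",
   "name": "apex",
   "states": [
    "mucronate",
    "acuminate",
    "entire",
    "dentate",
    "erose",
    "laciniate",
    "crenate",
    "emarginate",
    "geniculate",
    "antrorse"
   ],
   "units": {}
  },
  {
   "applicable_structures": [],
   "canonical_unit": null,
   "kind": "qualitative",
   "name": "color",
   "states": [
    "white",
    "pink",
    "carmine",
    "green",
    "purple",
    "reddish"
   ],
   "units": {}
  },
  {
   "applicable_structures": [
    "limb"
   ],
   "canonical_unit": null,
   "kind": "qualitative",
   "name": "incision",
   "states": [
    "less-than-middle",
    "middle-or-more"
   ],
   "units": {}
  },
  {
   "applicable_structures": [
    "flower"
   ],
   "canonical_unit": null,
   "kind": "qualitative",
   "name": "flowering-time",
   "states": [
    "diurnal",
    "nocturnal"
   ],
   "units": {}
  },
  {
   "applicable_structures": [
    "anther",
    "style"
   ],
   "canonical_unit": null,
   "kind": "qualitative",
   "name": "exsertion",
   "states": [
    "exserted",
    "included"
   ],
   "units": {}
  },
  {
   "applicable_structures": [
    "inflorescence"
   ],
   "canonical_unit": null,
   "kind": "qualitative",
   "name": "branching",
   "states": [
    "divaricate",
    "non-divaricate"
   ],
   "units": {}
  },
  {
   "applicable_structures": [
    "tooth"
   ],
   "canonical_unit": null,
   "kind": "qualitative",
   "name": "margin-width",
   "states": [
    "narrow",
    "broad"
   ],
   "units": {}
  },
  {
   "applicable_structures": [
    "tooth"
   ],
   "canonical_unit": null,
   "kind": "qualitative",
   "name": "dimorphism",
   "states": [
    "clear",
    "obscure"
   ],
   "units": {}
  },
  {
   "applicable_structures": [
    "leaf",
    "seed",
    "capsule"
   ],
   "canonical_unit": null,
   "kind": "qualitative",
   "name": "texture",
   "states": [
    "fleshy",
    "not-fleshy",
    "smooth",
    "papillate",
    "fragile",
    "robust"
   ],
   "units": {}
  },
  {
   "applicable_structures": [
    "plant"
   ],
   "canonical_unit": null,
   "kind": "qualitative",
   "name": "life-form",
   "states": [
    "annual",
    "perennial"
   ],
   "units": {}
  },
  {
   "applicable_structures": [],
   "canonical_unit": null,
   "kind": "relative",
   "name": "relative-length",
   "states": [],
   "units": {}
  }
 ],
 "provenance": "reconstructed base vocabulary covering the packaged accounts",
 "specifiers": [
  {
   "allowed_values": [
    "uppermost",
    "next-upper"
   ],
   "base_structure": "internode",
   "discriminator": "position"
  },
  {
   "allowed_values": [
    "first"
   ],
   "base_structure": "flower",
   "discriminator": "order"
  },
  {
   "allowed_values": [
    "shorter",
    "longer"
   ],
   "base_structure": "tooth",
   "discriminator": "class"
  },
  {
   "allowed_values": [
    "basal",
    "cauline"
   ],
   "base_structure": "leaf",
   "discriminator": "type"
  },
  {
   "allowed_values": [
    "upper",
    "lower"
   ],
   "base_structure": "limb",
   "discriminator": "surface"
  }
 ],
 "structures": [
  {
   "name": "plant",
   "note": "",
   "parent": null,
   "synonyms": []
  },
  {
   "name": "stem",
   "note": "",
   "parent": "plant",
   "synonyms": []
  },
  {
   "name": "internode",
   "note": "",
   "parent": "stem",
   "synonyms": []
  },
  {
   "name": "leaf",
   "note": "",
   "parent": "plant",
   "synonyms": []
  },
  {
   "name": "inflorescence",
   "note": "",
   "parent": "plant",
   "synonyms": []
  },
  {
   "name": "flower",
   "note": "",
   "parent": "plant",
   "synonyms": []
  },
  {
   "name": "calyx",
   "note": "",
   "parent": "flower",
   "synonyms": []
  },
  {
   "name": "tooth",
   "note": "",
   "parent": "calyx",
   "synonyms": [
    "calyx-tooth"
   ]
  },
  {
   "name": "petal",
   "note": "",
   "parent": "flower",
   "synonyms": []
  },
  {
   "name": "claw",
   "note": "lower part of the petal",
   "parent": "petal",
   "synonyms": []
  },
  {
   "name": "limb",
   "note": "upper part of the petal",
   "parent": "petal",
   "synonyms": []
  },
  {
   "name": "lobe",
   "note": "",
   "parent": "limb",
   "synonyms": []
  },
  {
   "name": "coronal-scale",
   "note": "small scale at the junction of claw and limb",
   "parent": "petal",
   "synonyms": []
  },
  {
   "name": "anthophore",
   "note": "stalk separating the attachment of calyx and corolla",
   "parent": "flower",
   "synonyms": []
  },
  {
   "name": "stamen",
   "note": "",
   "parent": "flower",
   "synonyms": []
  },
  {
   "name": "anther",
   "note": "",
   "parent": "stamen",
   "synonyms": []
  },
  {
   "name": "filament",
   "note": "",
   "parent": "stamen",
   "synonyms": []
  },
  {
   "name": "style",
   "note": "",
   "parent": "flower",
   "synonyms": []
  },
  {
   "name": "pedicel",
   "note": "",
   "parent": "flower",
   "synonyms": []
  },
  {
   "name": "capsule",
   "note": "",
   "parent": "flower",
   "synonyms": []
  },
  {
   "name": "seed",
   "note": "",
   "parent": "capsule",
   "synonyms": []
  }
 ],
 "version": "1"
}
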