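{
 "elements": [
  {
   "property": "height",
   "score": {
    "main": [
     10.0,
     20.0
    ],
    "type": "range",
    "unit": "cm"
   },
   "structure": "plant"
  },
  {
   "property": "habit",
   "score": {
    "states": [
     "erect"
    ],
    "type": "states"
   },
   "structure": "plant"
  },
  {
   "property": "count",
   "score": {
    "high": 5,
    "low": 3,
    "type": "count"
   },
   "structure": "internode"
  },
  {
   "property": "shape",
   "score": {
    "states": [
     "linear"
    ],
    "type": "states"
   },
   "structure": "leaf[type=cauline]"
  },
  {
   "property": "length",
   "score": {
    "main": [
     20.0,
     20.0
    ],
    "type": "range",
    "unit": "mm"
   },
   "structure": "leaf[type=cauline]"
  },
  {
   "property": "width",
   "score": {
    "main": [
     2.0,
     2.0
    ],
    "type": "range",
    "unit": "mm"
   },
   "structure": "leaf[type=cauline]"
  },
  {
   "property": "texture",
   "score": {
    "states": [
     "not-fleshy"
    ],
    "type": "states"
   },
   "structure": "leaf",
   "supplemented": true
  },
  {
   "property": "length",
   "score": {
    "main": [
     12.0,
     13.0
    ],
    "type": "range",
    "unit": "mm"
   },
   "structure": "calyx"
  },
  {
   "modifiers": [
    {
     "kind": "temporal",
     "value": "at-anthesis"
    }
   ],
   "property": "shape",
   "score": {
    "states": [
     "campanulate"
    ],
    "type": "states"
   },
   "structure": "calyx"
  },
  {
   "modifiers": [
    {
     "kind": "temporal",
     "value": "in-fruit"
    }
   ],
   "property": "shape",
   "score": {
    "states": [
     "clavate"
    ],
    "type": "states"
   },
   "structure": "calyx"
  },
  {
   "property": "pubescence",
   "score": {
    "states": [
     "glabrous",
     "sparsely-pubescent"
    ],
    "type": "states"
   },
   "structure": "calyx"
  },
  {
   "property": "papillae",
   "score": {
    "states": [
     "absent"
    ],
    "type": "states"
   },
   "structure": "calyx",
   "supplemented": true
  },
  {
   "property": "dimorphism",
   "score": {
    "states": [
     "obscure"
    ],
    "type": "states"
   },
   "structure": "tooth",
   "supplemented": true
  },
  {
   "property": "length",
   "score": {
    "main": [
     1.0,
     1.5
    ],
    "type": "range",
    "unit": "mm"
   },
   "structure": "tooth[class=shorter]"
  },
  {
   "property": "shape",
   "score": {
    "states": [
     "lanceolate"
    ],
    "type": "states"
   },
   "structure": "tooth[class=shorter]"
  },
  {
   "property": "apex",
   "score": {
    "states": [
     "acuminate"
    ],
    "type": "states"
   },
   "structure": "tooth[class=shorter]"
  },
  {
   "property": "length",
   "score": {
    "main": [
     2.0,
     3.5
    ],
    "type": "range",
    "unit": "mm"
   },
   "structure": "tooth[class=longer]"
  },
  {
   "property": "apex",
   "score": {
    "states": [
     "acuminate"
    ],
    "type": "states"
   },
   "structure": "tooth[class=longer]"
  },
  {
   "property": "branching",
   "score": {
    "states": [
     "non-divaricate"
    ],
    "type": "states"
   },
   "structure": "inflorescence"
  },
  {
   "property": "flowering-time",
   "score": {
    "states": [
     "nocturnal"
    ],
    "type": "states"
   },
   "structure": "flower",
   "supplemented": true
  },
  {
   "property": "length",
   "score": {
    "main": [
     6.0,
     6.5
    ],
    "type": "range",
    "unit": "mm"
   },
   "structure": "claw"
  },
  {
   "property": "pubescence",
   "score": {
    "states": [
     "ciliate"
    ],
    "type": "states"
   },
   "structure": "claw"
  },
  {
   "property": "length",
   "score": {
    "main": [
     6.0,
     6.0
    ],
    "type": "range",
    "unit": "mm"
   },
   "structure": "limb"
  },
  {
   "property": "incision",
   "score": {
    "states": [
     "middle-or-more"
    ],
    "type": "states"
   },
   "structure": "limb"
  },
  {
   "property": "color",
   "score": {
    "states": [
     "pink"
    ],
    "type": "states"
   },
   "structure": "limb[surface=upper]"
  },
  {
   "property": "shape",
   "score": {
    "states": [
     "oblong"
    ],
    "type": "states"
   },
   "structure": "lobe"
  },
  {
   "property": "length",
   "score": {
    "main": [
     2.0,
     2.0
    ],
    "type": "range",
    "unit": "mm"
   },
   "structure": "coronal-scale"
  },
  {
   "property": "shape",
   "score": {
    "states": [
     "ovate"
    ],
    "type": "states"
   },
   "structure": "coronal-scale"
  },
  {
   "property": "apex",
   "score": {
    "states": [
     "entire"
    ],
    "type": "states"
   },
   "structure": "coronal-scale"
  },
  {
   "property": "length",
   "score": {
    "main": [
     5.5,
     5.5
    ],
    "type": "range",
    "unit": "mm"
   },
   "structure": "anthophore"
  },
  {
   "property": "pubescence",
   "score": {
    "states": [
     "puberulent"
    ],
    "type": "states"
   },
   "structure": "anthophore"
  },
  {
   "property": "exsertion",
   "score": {
    "states": [
     "exserted"
    ],
    "type": "states"
   },
   "structure": "anther"
  },
  {
   "property": "pubescence",
   "score": {
    "states": [
     "glabrous"
    ],
    "type": "states"
   },
   "structure": "filament"
  },
  {
   "property": "exsertion",
   "score": {
    "states": [
     "exserted"
    ],
    "type": "states"
   },
   "structure": "style"
  },
  {
   "modifiers": [
    {
     "kind": "temporal",
     "value": "in-flower"
    }
   ],
   "property": "length",
   "score": {
    "main": [
     1.0,
     2.0
    ],
    "type": "range",
    "unit": "cm"
   },
   "structure": "flower[order=first]/pedicel"
  },
  {
   "modifiers": [
    {
     "kind": "temporal",
     "value": "in-fruit"
    }
   ],
   "property": "length",
   "score": {
    "main": [
     2.0,
     3.0
    ],
    "type": "range",
    "unit": "cm"
   },
   "structure": "flower[order=first]/pedicel"
  },
  {
   "property": "habit",
   "score": {
    "states": [
     "erect",
     "spreading"
    ],
    "type": "states"
   },
   "structure": "flower[order=first]/pedicel"
  },
  {
   "property": "apex",
   "score": {
    "states": [
     "antrorse"
    ],
    "type": "states"
   },
   "structure": "flower[order=first]/pedicel"
  },
  {
   "property": "length",
   "score": {
    "main": [
     6.0,
     8.0
    ],
    "type": "range",
    "unit": "mm"
   },
   "structure": "capsule"
  },
  {
   "property": "shape",
   "score": {
    "states": [
     "oblong"
    ],
    "type": "states"
   },
   "structure": "capsule"
  },
  {
   "property": "texture",
   "score": {
    "states": [
     "fragile"
    ],
    "type": "states"
   },
   "structure": "capsule"
  }
 ],
 "parent": "Silene sect. Arenosae",
 "rank": "species",
 "taxon": "Silene striata"
}
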