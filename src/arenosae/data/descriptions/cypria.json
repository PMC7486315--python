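{
 "elements": [
  {
   "property": "height",
   "score": {
    "main": [
     20.0,
     40.0
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
     "erect",
     "spreading"
    ],
    "type": "states"
   },
   "structure": "plant"
  },
  {
   "modifiers": [
    {
     "kind": "spatial",
     "value": "in-lower-part"
    }
   ],
   "property": "pubescence",
   "score": {
    "states": [
     "pubescent"
    ],
    "type": "states"
   },
   "structure": "stem"
  },
  {
   "modifiers": [
    {
     "kind": "spatial",
     "value": "in-upper-part"
    }
   ],
   "property": "pubescence",
   "score": {
    "states": [
     "glabrous"
    ],
    "type": "states"
   },
   "structure": "stem"
  },
  {
   "property": "count",
   "score": {
    "high": 20,
    "low": 10,
    "type": "count"
   },
   "structure": "internode"
  },
  {
   "property": "length",
   "score": {
    "main": [
     2.0,
     4.0
    ],
    "type": "range",
    "unit": "cm"
   },
   "structure": "internode[position=uppermost]"
  },
  {
   "property": "relative-length",
   "score": {
    "reference": "internode[position=next-upper]",
    "relation": "equal-to",
    "type": "relative"
   },
   "structure": "internode[position=uppermost]"
  },
  {
   "property": "shape",
   "score": {
    "states": [
     "oblanceolate"
    ],
    "type": "states"
   },
   "structure": "leaf[type=cauline]"
  },
  {
   "property": "length",
   "score": {
    "main": [
     10.0,
     30.0
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
     1.0,
     2.0
    ],
    "type": "range",
    "unit": "mm"
   },
   "structure": "leaf[type=cauline]"
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
     "pubescent",
     "scabrous"
    ],
    "type": "states"
   },
   "structure": "calyx"
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
     1.5,
     2.0
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
     2.5
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
     "diurnal"
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
     7.0
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
     4.0,
     5.0
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
     "dentate",
     "erose"
    ],
    "type": "states"
   },
   "structure": "coronal-scale"
  },
  {
   "property": "length",
   "score": {
    "main": [
     5.0,
     6.0
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
     "densely-puberulent"
    ],
    "type": "states"
   },
   "structure": "anthophore"
  },
  {
   "property": "exsertion",
   "score": {
    "states": [
     "included"
    ],
    "type": "states"
   },
   "structure": "anther"
  },
  {
   "property": "length",
   "score": {
    "main": [
     6.0,
     7.0
    ],
    "type": "range",
    "unit": "mm"
   },
   "structure": "filament"
  },
  {
   "property": "pubescence",
   "score": {
    "states": [
     "glabrous",
     "pubescent"
    ],
    "type": "states"
   },
   "structure": "filament"
  },
  {
   "property": "exsertion",
   "score": {
    "states": [
     "included"
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
     0.5,
     1.0
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
     1.0,
     1.0
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
     "erect"
    ],
    "type": "states"
   },
   "structure": "flower[order=first]/pedicel"
  },
  {
   "property": "pubescence",
   "score": {
    "states": [
     "glabrous"
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
     7.0,
     7.0
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
  },
  {
   "property": "width",
   "score": {
    "main": [
     0.7,
     0.9
    ],
    "type": "range",
    "unit": "mm"
   },
   "structure": "seed"
  },
  {
   "property": "height",
   "score": {
    "main": [
     0.7,
     0.7
    ],
    "type": "range",
    "unit": "mm"
   },
   "structure": "seed"
  },
  {
   "property": "texture",
   "score": {
    "states": [
     "smooth"
    ],
    "type": "states"
   },
   "structure": "seed"
  }
 ],
 "parent": "Silene microsperma",
 "rank": "subspecies",
 "taxon": "Silene microsperma subsp. cypria"
}
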