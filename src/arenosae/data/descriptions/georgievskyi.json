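{
 "elements": [
  {
   "property": "height",
   "score": {
    "main": [
     20.0,
     50.0
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
   "modifiers": [
    {
     "kind": "spatial",
     "value": "in-lower-part"
    }
   ],
   "property": "pubescence",
   "score": {
    "states": [
     "pubescent",
     "scabrous"
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
     "pubescent"
    ],
    "type": "states"
   },
   "structure": "stem"
  },
  {
   "property": "count",
   "score": {
    "high": 12,
    "low": 8,
    "type": "count"
   },
   "structure": "internode"
  },
  {
   "property": "relative-length",
   "score": {
    "reference": "internode[position=next-upper]",
    "relation": "obviously-longer-than",
    "type": "relative"
   },
   "structure": "internode[position=uppermost]"
  },
  {
   "property": "shape",
   "score": {
    "states": [
     "linear",
     "oblanceolate"
    ],
    "type": "states"
   },
   "structure": "leaf[type=basal]"
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
     10.0,
     40.0
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
     3.0
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
     25.0,
     30.0
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
     "ovoid"
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
     "pubescent"
    ],
    "type": "states"
   },
   "structure": "calyx"
  },
  {
   "property": "dimorphism",
   "score": {
    "states": [
     "clear"
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
     2.0,
     4.0
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
     "ovate"
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
     4.0,
     6.0
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
     10.0,
     12.0
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
     "glabrous"
    ],
    "type": "states"
   },
   "structure": "claw"
  },
  {
   "property": "length",
   "score": {
    "main": [
     7.0,
     9.0
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
     2.2
    ],
    "type": "range",
    "unit": "mm"
   },
   "structure": "coronal-scale"
  },
  {
   "property": "length",
   "score": {
    "main": [
     13.0,
     16.0
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
     "glabrous",
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
   "property": "length",
   "score": {
    "main": [
     12.0,
     15.0
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
     4.0
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
     6.0
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
     12.0,
     12.0
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
     "ellipsoid",
     "oblong"
    ],
    "type": "states"
   },
   "structure": "capsule"
  },
  {
   "property": "width",
   "score": {
    "main": [
     0.8,
     1.0
    ],
    "type": "range",
    "unit": "mm"
   },
   "structure": "seed"
  }
 ],
 "parent": "Silene sect. Arenosae",
 "rank": "species",
 "taxon": "Silene georgievskyi"
}
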