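{
 "elements": [
  {
   "property": "life-form",
   "score": {
    "states": [
     "annual"
    ],
    "type": "states"
   },
   "structure": "plant"
  },
  {
   "property": "height",
   "score": {
    "main": [
     5.0,
     70.0
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
     "ascending",
     "erect"
    ],
    "type": "states"
   },
   "structure": "plant"
  },
  {
   "modifiers": [
    {
     "kind": "frequency",
     "value": "often"
    },
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
   "property": "shape",
   "score": {
    "states": [
     "lanceolate",
     "oblanceolate"
    ],
    "type": "states"
   },
   "structure": "leaf[type=basal]"
  },
  {
   "property": "pubescence",
   "score": {
    "states": [
     "pubescent"
    ],
    "type": "states"
   },
   "structure": "leaf[type=basal]"
  },
  {
   "property": "shape",
   "score": {
    "states": [
     "lanceolate",
     "linear",
     "oblanceolate"
    ],
    "type": "states"
   },
   "structure": "leaf[type=cauline]"
  },
  {
   "property": "pubescence",
   "score": {
    "states": [
     "pubescent"
    ],
    "type": "states"
   },
   "structure": "leaf[type=cauline]"
  },
  {
   "property": "shape",
   "score": {
    "states": [
     "lanceolate"
    ],
    "type": "states"
   },
   "structure": "tooth[class=longer]"
  },
  {
   "modifiers": [
    {
     "kind": "frequency",
     "value": "often"
    }
   ],
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
   "property": "margin-width",
   "score": {
    "states": [
     "narrow"
    ],
    "type": "states"
   },
   "structure": "tooth[class=longer]"
  },
  {
   "property": "margin-width",
   "score": {
    "states": [
     "broad"
    ],
    "type": "states"
   },
   "structure": "tooth[class=shorter]"
  },
  {
   "modifiers": [
    {
     "kind": "frequency",
     "value": "usually"
    }
   ],
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
   "modifiers": [
    {
     "kind": "frequency",
     "value": "usually"
    }
   ],
   "property": "flowering-time",
   "score": {
    "states": [
     "nocturnal"
    ],
    "type": "states"
   },
   "structure": "flower"
  },
  {
   "property": "color",
   "score": {
    "states": [
     "pink",
     "white"
    ],
    "type": "states"
   },
   "structure": "limb[surface=upper]"
  },
  {
   "property": "count",
   "score": {
    "high": 3,
    "low": 3,
    "type": "count"
   },
   "structure": "style"
  },
  {
   "property": "shape",
   "score": {
    "states": [
     "ellipsoid",
     "oblong",
     "obovate"
    ],
    "type": "states"
   },
   "structure": "capsule"
  },
  {
   "property": "shape",
   "score": {
    "states": [
     "reniform"
    ],
    "type": "states"
   },
   "structure": "seed"
  },
  {
   "property": "texture",
   "score": {
    "states": [
     "papillate",
     "smooth"
    ],
    "type": "states"
   },
   "structure": "seed"
  }
 ],
 "rank": "section",
 "taxon": "Silene sect. Arenosae"
}
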