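{
 "name": "arenosae-section",
 "slots": [
  {
   "path": "plant",
   "property": "life-form",
   "label": "Life form",
   "precision": 1,
   "unit": null
  },
  {
   "path": "plant",
   "property": "height",
   "label": "Plant",
   "precision": 1,
   "unit": "cm"
  },
  {
   "path": "plant",
   "property": "habit",
   "label": "Plant",
   "precision": 1,
   "unit": null
  },
  {
   "path": "stem",
   "property": "pubescence",
   "label": "Stem",
   "precision": 1,
   "unit": null
  },
  {
   "path": "internode",
   "property": "count",
   "label": "Distinct internodes",
   "precision": 1,
   "unit": null
  },
  {
   "path": "internode[position=uppermost]",
   "property": "length",
   "label": "the uppermost internode",
   "precision": 1,
   "unit": "cm"
  },
  {
   "path": "internode[position=uppermost]",
   "property": "relative-length",
   "label": "the uppermost internode",
   "precision": 1,
   "unit": null
  },
  {
   "path": "leaf[type=basal]",
   "property": "shape",
   "label": "Basal leaves",
   "precision": 1,
   "unit": null
  },
  {
   "path": "leaf[type=basal]",
   "property": "length",
   "label": "Basal leaves",
   "precision": 1,
   "unit": null
  },
  {
   "path": "leaf[type=basal]",
   "property": "width",
   "label": "Basal leaves",
   "precision": 1,
   "unit": null
  },
  {
   "path": "leaf[type=basal]",
   "property": "pubescence",
   "label": "Basal leaves",
   "precision": 1,
   "unit": null
  },
  {
   "path": "leaf[type=cauline]",
   "property": "shape",
   "label": "Cauline leaves",
   "precision": 1,
   "unit": null
  },
  {
   "path": "leaf[type=cauline]",
   "property": "length",
   "label": "Cauline leaves",
   "precision": 1,
   "unit": null
  },
  {
   "path": "leaf[type=cauline]",
   "property": "width",
   "label": "Cauline leaves",
   "precision": 1,
   "unit": null
  },
  {
   "path": "leaf[type=cauline]",
   "property": "pubescence",
   "label": "Cauline leaves",
   "precision": 1,
   "unit": null
  },
  {
   "path": "leaf",
   "property": "texture",
   "label": "Leaves",
   "precision": 1,
   "unit": null
  },
  {
   "path": "calyx",
   "property": "length",
   "label": "Calyx",
   "precision": 1,
   "unit": null
  },
  {
   "path": "calyx",
   "property": "shape",
   "label": "Calyx",
   "precision": 1,
   "unit": null
  },
  {
   "path": "calyx",
   "property": "pubescence",
   "label": "Calyx",
   "precision": 1,
   "unit": null
  },
  {
   "path": "calyx",
   "property": "papillae",
   "label": "Calyx papillae",
   "precision": 1,
   "unit": null
  },
  {
   "path": "tooth",
   "property": "dimorphism",
   "label": "Calyx teeth",
   "precision": 1,
   "unit": null
  },
  {
   "path": "tooth[class=shorter]",
   "property": "length",
   "label": "shorter teeth",
   "precision": 1,
   "unit": null
  },
  {
   "path": "tooth[class=shorter]",
   "property": "shape",
   "label": "shorter teeth",
   "precision": 1,
   "unit": null
  },
  {
   "path": "tooth[class=shorter]",
   "property": "apex",
   "label": "shorter teeth",
   "precision": 1,
   "unit": null
  },
  {
   "path": "tooth[class=longer]",
   "property": "length",
   "label": "longer teeth",
   "precision": 1,
   "unit": null
  },
  {
   "path": "tooth[class=longer]",
   "property": "shape",
   "label": "longer teeth",
   "precision": 1,
   "unit": null
  },
  {
   "path": "tooth[class=longer]",
   "property": "apex",
   "label": "longer teeth",
   "precision": 1,
   "unit": null
  },
  {
   "path": "tooth[class=longer]",
   "property": "margin-width",
   "label": "longer teeth",
   "precision": 1,
   "unit": null
  },
  {
   "path": "tooth[class=shorter]",
   "property": "margin-width",
   "label": "shorter teeth margin",
   "precision": 1,
   "unit": null
  },
  {
   "path": "inflorescence",
   "property": "branching",
   "label": "Inflorescence",
   "precision": 1,
   "unit": null
  },
  {
   "path": "flower",
   "property": "flowering-time",
   "label": "Flowers",
   "precision": 1,
   "unit": null
  },
  {
   "path": "claw",
   "property": "length",
   "label": "Petal claws",
   "precision": 1,
   "unit": null
  },
  {
   "path": "claw",
   "property": "pubescence",
   "label": "Petal claws",
   "precision": 1,
   "unit": null
  },
  {
   "path": "limb",
   "property": "length",
   "label": "Petal limbs",
   "precision": 1,
   "unit": null
  },
  {
   "path": "limb",
   "property": "incision",
   "label": "Petal limbs",
   "precision": 1,
   "unit": null
  },
  {
   "path": "limb[surface=upper]",
   "property": "color",
   "label": "upper surface",
   "precision": 1,
   "unit": null
  },
  {
   "path": "lobe",
   "property": "shape",
   "label": "lobes",
   "precision": 1,
   "unit": null
  },
  {
   "path": "coronal-scale",
   "property": "length",
   "label": "Coronal scales",
   "precision": 1,
   "unit": null
  },
  {
   "path": "coronal-scale",
   "property": "shape",
   "label": "Coronal scales",
   "precision": 1,
   "unit": null
  },
  {
   "path": "coronal-scale",
   "property": "apex",
   "label": "Coronal scales",
   "precision": 1,
   "unit": null
  },
  {
   "path": "anthophore",
   "property": "length",
   "label": "Anthophore",
   "precision": 1,
   "unit": null
  },
  {
   "path": "anthophore",
   "property": "pubescence",
   "label": "Anthophore",
   "precision": 1,
   "unit": null
  },
  {
   "path": "anther",
   "property": "exsertion",
   "label": "Anthers",
   "precision": 1,
   "unit": null
  },
  {
   "path": "filament",
   "property": "length",
   "label": "Filaments",
   "precision": 1,
   "unit": null
  },
  {
   "path": "filament",
   "property": "pubescence",
   "label": "Filaments",
   "precision": 1,
   "unit": null
  },
  {
   "path": "style",
   "property": "count",
   "label": "Styles",
   "precision": 1,
   "unit": null
  },
  {
   "path": "style",
   "property": "exsertion",
   "label": "Styles",
   "precision": 1,
   "unit": null
  },
  {
   "path": "flower[order=first]/pedicel",
   "property": "length",
   "label": "First pedicel",
   "precision": 1,
   "unit": "cm"
  },
  {
   "path": "flower[order=first]/pedicel",
   "property": "habit",
   "label": "First pedicel",
   "precision": 1,
   "unit": null
  },
  {
   "path": "flower[order=first]/pedicel",
   "property": "pubescence",
   "label": "First pedicel",
   "precision": 1,
   "unit": null
  },
  {
   "path": "flower[order=first]/pedicel",
   "property": "apex",
   "label": "First pedicel",
   "precision": 1,
   "unit": null
  },
  {
   "path": "capsule",
   "property": "length",
   "label": "Capsule",
   "precision": 1,
   "unit": null
  },
  {
   "path": "capsule",
   "property": "shape",
   "label": "Capsule",
   "precision": 1,
   "unit": null
  },
  {
   "path": "capsule",
   "property": "texture",
   "label": "Capsule",
   "precision": 1,
   "unit": null
  },
  {
   "path": "seed",
   "property": "width",
   "label": "Seeds",
   "precision": 1,
   "unit": null
  },
  {
   "path": "seed",
   "property": "height",
   "label": "Seeds",
   "precision": 1,
   "unit": null
  },
  {
   "path": "seed",
   "property": "shape",
   "label": "Seeds",
   "precision": 1,
   "unit": null
  },
  {
   "path": "seed",
   "property": "texture",
   "label": "Seeds",
   "precision": 1,
   "unit": null
  }
 ]
}
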