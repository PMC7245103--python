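{
  "building_blocks": [
    {"label": "Mo1", "mo_count": 1, "note": "MoO6 octahedron monomer"},
    {"label": "Mo2", "mo_count": 2, "note": "generic Mo2 dimer (sharing mode unspecified)"},
    {"label": "Mo2c", "mo_count": 2, "note": "corner-shared Mo2 dimer (wheel building block)"},
    {"label": "Mo2e", "mo_count": 2, "note": "edge-shared reduced Mo2 dimer (ball building block)"},
    {"label": "Mo3", "mo_count": 3, "note": "postulated Keggin precursor triad"},
    {"label": "Mo6", "mo_count": 6, "note": "hexamer building block"},
    {"label": "Mo8", "mo_count": 8, "note": "pentagonal {Mo8} unit with central MoO7 bipyramid"},
    {"label": "Ce-unit", "mo_count": 0, "note": "{Ce(H2O)5} unit, no Mo"}
  ],
  "clusters": [
    {
      "name": "{PMo12}",
      "nuclearity": 12,
      "mo_vi": 10,
      "mo_v": 2,
      "heteroatoms": {"P": 1},
      "note": "Keggin ion [PMo12O40]3-; 2-electron reduced host in compound 1"
    },
    {
      "name": "{Mo36}",
      "nuclearity": 36,
      "mo_vi": 36,
      "mo_v": 0,
      "note": "fully oxidized [MoVI36O112(H2O)16]8- template"
    },
    {
      "name": "{Mo57M}",
      "nuclearity": 57,
      "heteroatoms": {"M": 6},
      "note": "[H3Mo57M6(NO)6O183(H2O)18]22-; oxidation split not recorded"
    },
    {
      "name": "{Mo132}",
      "nuclearity": 132,
      "mo_vi": 72,
      "mo_v": 60,
      "note": "Keplerate ball [MoVI72MoV60O372(CH3COO)30(H2O)72]42-"
    },
    {
      "name": "{Mo150}",
      "nuclearity": 150,
      "mo_vi": 130,
      "mo_v": 20,
      "note": "[MoVI130MoV20O442(OH)10(H2O)60]14- wheel templated by {Mo36}"
    },
    {
      "name": "{Mo154}",
      "nuclearity": 154,
      "note": "[Mo154O462H14(H2O)70]14- molybdenum-blue wheel; oxidation split not recorded"
    },
    {
      "name": "{Mo248}",
      "nuclearity": 248,
      "note": "capped wheel [H16Mo248O720(H2O)128]16-"
    },
    {
      "name": "{Mo368}",
      "nuclearity": 368,
      "note": "lemon-shaped [H16Mo368O1032(H2O)240(SO4)48]48-"
    },
    {
      "name": "{Mo124Ce4}",
      "composition": {"Mo8": 12, "Mo2": 8, "Mo1": 12, "Ce-unit": 4},
      "nuclearity": 124,
      "mo_vi": 100,
      "mo_v": 24,
      "heteroatoms": {"Ce": 4},
      "note": "compound-1 nanoring (24-electron reduced) hosting a {PMo12} Keggin"
    }
  ]
}
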