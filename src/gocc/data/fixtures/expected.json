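{
 "ex1": {
  "surrogate": false,
  "relations": [
   {
    "rtype": "part_of_complex",
    "protein": "CSC-1",
    "complex": "Aurora B kinase complex"
   }
  ],
  "triplets": [
   [
    "GID:CSC-1",
    "GO:0043234"
   ]
  ]
 },
 "ex9": {
  "surrogate": false,
  "relations": [
   {
    "rtype": "part_of_complex",
    "protein": "CSC-1",
    "complex": "Aurora B kinase complex"
   }
  ],
  "triplets": [
   [
    "GID:CSC-1",
    "GO:0043234"
   ]
  ]
 },
 "ex2": {
  "surrogate": false,
  "relations": [
   {
    "rtype": "component_component",
    "pair": [
     "Mad1",
     "Max"
    ]
   }
  ],
  "triplets": [
   [
    "GID:Mad1",
    "GO:0043234"
   ],
   [
    "GID:Max",
    "GO:0043234"
   ]
  ]
 },
 "ex3": {
  "surrogate": false,
  "relations": [
   {
    "rtype": "part_of_complex",
    "protein": "Rpg1",
    "complex": "eIF3 complex"
   },
   {
    "rtype": "part_of_complex",
    "protein": "Nip1",
    "complex": "eIF3 complex"
   },
   {
    "rtype": "part_of_complex",
    "protein": "Prt1",
    "complex": "eIF3 complex"
   },
   {
    "rtype": "part_of_complex",
    "protein": "Tif34",
    "complex": "eIF3 complex"
   },
   {
    "rtype": "part_of_complex",
    "protein": "Tif35",
    "complex": "eIF3 complex"
   }
  ],
  "triplets": [
   [
    "GID:Rpg1",
    "GO:0005852"
   ],
   [
    "GID:Nip1",
    "GO:0005852"
   ],
   [
    "GID:Prt1",
    "GO:0005852"
   ],
   [
    "GID:Tif34",
    "GO:0005852"
   ],
   [
    "GID:Tif35",
    "GO:0005852"
   ]
  ]
 },
 "ex4": {
  "surrogate": false,
  "relations": [
   {
    "rtype": "found_in",
    "protein": "SIRT2",
    "location": "cytoplasm"
   }
  ],
  "triplets": [
   [
    "GID:SIRT2",
    "GO:0005737"
   ]
  ]
 },
 "ex5": {
  "surrogate": true,
  "relations": [
   {
    "rtype": "found_in",
    "protein": "ZmHK1",
    "location": "endoplasmic reticulum"
   }
  ],
  "triplets": [
   [
    "GID:ZmHK1",
    "GO:0005783"
   ]
  ]
 },
 "ex5n": {
  "surrogate": true,
  "relations": [
   {
    "rtype": "found_in",
    "protein": "ZmHK1",
    "location": "endoplasmic reticulum"
   }
  ],
  "triplets": [
   [
    "GID:ZmHK1",
    "GO:0005783"
   ]
  ]
 },
 "ex6": {
  "surrogate": true,
  "relations": [
   {
    "rtype": "moves",
    "protein": "GLUT4",
    "location": "plasma membrane"
   },
   {
    "rtype": "moves",
    "protein": "GLUT4",
    "location": "cytoplasm"
   }
  ],
  "triplets": [
   [
    "GID:GLUT4",
    "GO:0005737"
   ],
   [
    "GID:GLUT4",
    "GO:0005886"
   ]
  ]
 },
 "ex7": {
  "surrogate": false,
  "relations": [
   {
    "rtype": "event_in",
    "protein": "Fbxo45",
    "location": "cytoplasm"
   },
   {
    "rtype": "event_in",
    "protein": "Par-4",
    "location": "cytoplasm"
   },
   {
    "rtype": "ppi",
    "pair": [
     "Fbxo45",
     "Par-4"
    ]
   }
  ],
  "triplets": [
   [
    "GID:Fbxo45",
    "GO:0005737"
   ],
   [
    "GID:Par-4",
    "GO:0005737"
   ]
  ]
 },
 "ex8": {
  "surrogate": true,
  "relations": [
   {
    "rtype": "event_in",
    "protein": "SGLT1",
    "location": "plasma membrane"
   }
  ],
  "triplets": [
   [
    "GID:SGLT1",
    "GO:0005886"
   ]
  ]
 },
 "ex10": {
  "surrogate": false,
  "relations": [
   {
    "rtype": "part_of_complex",
    "protein": "Sp1",
    "complex": "MRE complex"
   }
  ],
  "triplets": [
   [
    "GID:Sp1",
    "GO:0043234"
   ]
  ]
 },
 "ex11": {
  "surrogate": true,
  "relations": [
   {
    "rtype": "part_of_complex",
    "protein": "Rpn10",
    "complex": "26S proteasome"
   }
  ],
  "triplets": [
   [
    "GID:Rpn10",
    "GO:0000502"
   ]
  ]
 },
 "ex12": {
  "surrogate": true,
  "relations": [
   {
    "rtype": "part_of_complex",
    "protein": "Gcn5",
    "complex": "SAGA complex"
   },
   {
    "rtype": "part_of_complex",
    "protein": "Ada2",
    "complex": "SAGA complex"
   }
  ],
  "triplets": [
   [
    "GID:Gcn5",
    "GO:0043234"
   ],
   [
    "GID:Ada2",
    "GO:0043234"
   ]
  ]
 },
 "ex13": {
  "surrogate": true,
  "relations": [
   {
    "rtype": "part_of_complex",
    "protein": "Cdc31",
    "complex": "Sfi1 complex"
   }
  ],
  "triplets": [
   [
    "GID:Cdc31",
    "GO:0043234"
   ]
  ]
 },
 "ex14": {
  "surrogate": true,
  "relations": [
   {
    "rtype": "part_of_complex",
    "protein": "JAB1",
    "complex": "protein complex"
   }
  ],
  "triplets": [
   [
    "GID:JAB1",
    "GO:0043234"
   ]
  ]
 },
 "ex15": {
  "surrogate": true,
  "relations": [
   {
    "rtype": "component_component",
    "pair": [
     "Ku70",
     "Ku80"
    ]
   },
   {
    "rtype": "part_of_complex",
    "protein": "Ku70",
    "complex": "tight heterodimer"
   },
   {
    "rtype": "part_of_complex",
    "protein": "Ku80",
    "complex": "tight heterodimer"
   }
  ],
  "triplets": [
   [
    "GID:Ku70",
    "GO:0043234"
   ],
   [
    "GID:Ku80",
    "GO:0043234"
   ]
  ]
 },
 "ex16": {
  "surrogate": true,
  "relations": [
   {
    "rtype": "component_component",
    "pair": [
     "Survivin",
     "Borealin"
    ]
   }
  ],
  "triplets": [
   [
    "GID:Survivin",
    "GO:0043234"
   ],
   [
    "GID:Borealin",
    "GO:0043234"
   ]
  ]
 },
 "ex17": {
  "surrogate": true,
  "relations": [
   {
    "rtype": "ppi",
    "pair": [
     "Hsp70",
     "Hsp40"
    ]
   },
   {
    "rtype": "component_component",
    "pair": [
     "Hsp70",
     "Hsp40"
    ]
   }
  ],
  "triplets": [
   [
    "GID:Hsp70",
    "GO:0043234"
   ],
   [
    "GID:Hsp40",
    "GO:0043234"
   ]
  ]
 },
 "ex18": {
  "surrogate": true,
  "relations": [
   {
    "rtype": "ppi",
    "pair": [
     "CD47",
     "TSP-1"
    ]
   },
   {
    "rtype": "component_component",
    "pair": [
     "CD47",
     "TSP-1"
    ]
   }
  ],
  "triplets": [
   [
    "GID:CD47",
    "GO:0043234"
   ],
   [
    "GID:TSP-1",
    "GO:0043234"
   ]
  ]
 },
 "ex19": {
  "surrogate": false,
  "relations": [
   {
    "rtype": "ppi",
    "pair": [
     "Bmh1p",
     "Bmh2p"
    ]
   },
   {
    "rtype": "ppi",
    "pair": [
     "Bmh1p",
     "Ste20p"
    ]
   },
   {
    "rtype": "ppi",
    "pair": [
     "Bmh2p",
     "Ste20p"
    ]
   },
   {
    "rtype": "component_component",
    "pair": [
     "Bmh1p",
     "Bmh2p"
    ]
   },
   {
    "rtype": "component_component",
    "pair": [
     "Bmh1p",
     "Ste20p"
    ]
   },
   {
    "rtype": "component_component",
    "pair": [
     "Bmh2p",
     "Ste20p"
    ]
   }
  ],
  "triplets": [
   [
    "GID:Bmh1p",
    "GO:0043234"
   ],
   [
    "GID:Bmh2p",
    "GO:0043234"
   ],
   [
    "GID:Ste20p",
    "GO:0043234"
   ]
  ]
 },
 "ex20": {
  "surrogate": true,
  "relations": [
   {
    "rtype": "ppi",
    "protein": "CAR-1",
    "complex": "conserved protein complex"
   },
   {
    "rtype": "part_of_complex",
    "protein": "CAR-1",
    "complex": "conserved protein complex"
   }
  ],
  "triplets": [
   [
    "GID:CAR-1",
    "GO:0043234"
   ]
  ]
 },
 "cd3": {
  "surrogate": true,
  "relations": [],
  "triplets": []
 },
 "staining": {
  "surrogate": true,
  "relations": [
   {
    "rtype": "staining_in",
    "protein": "CeCDC-14",
    "location": "midbody",
    "confidence": "low"
   }
  ],
  "triplets": [
   [
    "GID:CeCDC-14",
    "GO:0030496"
   ]
  ]
 }
}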