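{
 "disease": "psoriasis",
 "notes": "Reconstruction of the figure-level IL-17 sub-pathway; rate constants default to 1.0, deviations within [0.25, 4] are calibrated to the reported simulation behavior.",
 "species": [
  {
   "id": "IL17A",
   "role": "deg",
   "members": [
    "IL17A"
   ],
   "initial": 0.5
  },
  {
   "id": "IL17F",
   "role": "deg",
   "members": [
    "IL17F"
   ],
   "initial": 0.5
  },
  {
   "id": "IL17D",
   "role": "deg",
   "members": [
    "IL17D"
   ],
   "initial": 0.5
  },
  {
   "id": "IL17RE",
   "role": "deg",
   "members": [
    "IL17RE"
   ],
   "initial": 0.5
  },
  {
   "id": "C1",
   "role": "complex",
   "members": [
    "HSP90",
    "ACT1"
   ],
   "initial": 0.5
  },
  {
   "id": "TRAF6",
   "role": "gene",
   "members": [
    "TRAF6"
   ],
   "initial": 0.5
  },
  {
   "id": "C2",
   "role": "complex",
   "members": [
    "TAB2",
    "TAB3",
    "TAK1"
   ],
   "initial": 0.5
  },
  {
   "id": "NFKB",
   "role": "gene",
   "members": [
    "NFKB1"
   ],
   "initial": 0.5
  },
  {
   "id": "MAPKs",
   "role": "complex",
   "members": [
    "MAPK13",
    "MAPK14"
   ],
   "initial": 0.5
  },
  {
   "id": "AP1",
   "role": "complex",
   "members": [
    "FOSL1",
    "FOS"
   ],
   "initial": 0.5
  },
  {
   "id": "chemokines",
   "role": "complex",
   "members": [
    "CXCL1",
    "CXCL2",
    "CXCL5",
    "CXCL8",
    "CXCL10",
    "CCL2",
    "CCL7",
    "CCL20"
   ],
   "initial": 0.5
  },
  {
   "id": "antimicrobial",
   "role": "complex",
   "members": [
    "S100A7",
    "S100A8",
    "S100A9",
    "LCN2"
   ],
   "initial": 0.5
  },
  {
   "id": "tissue_remodeling",
   "role": "complex",
   "members": [
    "MMP1",
    "MMP9"
   ],
   "initial": 0.5
  },
  {
   "id": "IL1B",
   "role": "deg",
   "members": [
    "IL1B"
   ],
   "initial": 0.5
  },
  {
   "id": "IFNG",
   "role": "deg",
   "members": [
    "IFNG"
   ],
   "initial": 0.5
  },
  {
   "id": "IKBKE",
   "role": "inhibitor",
   "members": [
    "IKBKE"
   ],
   "initial": 0.5
  },
  {
   "id": "C3",
   "role": "inhibitor",
   "members": [
    "ANAPC5",
    "A20"
   ],
   "initial": 0.5
  },
  {
   "id": "autoimmune_pathology",
   "role": "process",
   "members": [
    "AUTOIMMUNE_PATHOLOGY"
   ],
   "initial": 0.0
  },
  {
   "id": "neutrophil_recruitment",
   "role": "process",
   "members": [
    "NEUTROPHIL_RECRUITMENT"
   ],
   "initial": 0.0
  },
  {
   "id": "immunity_extracellular_pathogens",
   "role": "process",
   "members": [
    "IMMUNITY_EXTRACELLULAR_PATHOGENS"
   ],
   "initial": 0.0
  }
 ],
 "edges": [
  {
   "source": "IL17A",
   "target": "C1",
   "kind": "activation",
   "k": 1.5
  },
  {
   "source": "IL17F",
   "target": "C1",
   "kind": "activation",
   "k": 1.5
  },
  {
   "source": "IL17D",
   "target": "IL17RE",
   "kind": "activation",
   "k": 0.8
  },
  {
   "source": "IL17RE",
   "target": "C1",
   "kind": "activation",
   "k": 1.5
  },
  {
   "source": "C1",
   "target": "TRAF6",
   "kind": "activation",
   "k": 1.5
  },
  {
   "source": "TRAF6",
   "target": "C2",
   "kind": "activation",
   "k": 1.5
  },
  {
   "source": "C2",
   "target": "NFKB",
   "kind": "activation",
   "k": 1.5
  },
  {
   "source": "C2",
   "target": "MAPKs",
   "kind": "activation",
   "k": 1.5
  },
  {
   "source": "MAPKs",
   "target": "AP1",
   "kind": "activation",
   "k": 1.5
  },
  {
   "source": "NFKB",
   "target": "chemokines",
   "kind": "activation",
   "k": 4.0
  },
  {
   "source": "NFKB",
   "target": "antimicrobial",
   "kind": "activation",
   "k": 1.8693188990531924
  },
  {
   "source": "NFKB",
   "target": "IL1B",
   "kind": "activation",
   "k": 1.2595358990043972
  },
  {
   "source": "NFKB",
   "target": "IFNG",
   "kind": "activation",
   "k": 1.2595358990043972
  },
  {
   "source": "AP1",
   "target": "chemokines",
   "kind": "activation",
   "k": 4.0
  },
  {
   "source": "AP1",
   "target": "tissue_remodeling",
   "kind": "activation",
   "k": 1.5114430788052766
  },
  {
   "source": "AP1",
   "target": "antimicrobial",
   "kind": "activation",
   "k": 3.1778421283904277
  },
  {
   "source": "chemokines",
   "target": "neutrophil_recruitment",
   "kind": "activation",
   "k": 0.8
  },
  {
   "source": "antimicrobial",
   "target": "immunity_extracellular_pathogens",
   "kind": "activation",
   "k": 0.8
  },
  {
   "source": "tissue_remodeling",
   "target": "autoimmune_pathology",
   "kind": "activation",
   "k": 0.8
  },
  {
   "source": "IL1B",
   "target": "autoimmune_pathology",
   "kind": "activation",
   "k": 0.8
  },
  {
   "source": "IFNG",
   "target": "autoimmune_pathology",
   "kind": "activation",
   "k": 0.3
  },
  {
   "source": "IKBKE",
   "target": "C1",
   "kind": "inhibition",
   "k": 0.25
  },
  {
   "source": "C3",
   "target": "IKBKE",
   "kind": "inhibition",
   "k": 0.25
  }
 ]
}
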