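{
 "disease": "cSCC",
 "notes": "Reconstruction of the figure-level IL-17 sub-pathway; rate constants default to 1.0, deviations within [0.25, 4] are calibrated to the reported simulation behavior.",
 "species": [
  {
   "id": "IL17A",
   "role": "gene",
   "members": [
    "IL17A"
   ],
   "initial": 0.5
  },
  {
   "id": "IL17F",
   "role": "gene",
   "members": [
    "IL17F"
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
   "role": "deg",
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
   "id": "IKBKG",
   "role": "deg",
   "members": [
    "IKBKG"
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
    "MAPK3",
    "MAPK9",
    "MAPK10",
    "MAPK11",
    "MAPK14"
   ],
   "initial": 0.5
  },
  {
   "id": "AP1",
   "role": "complex",
   "members": [
    "FOSL1",
    "JUN"
   ],
   "initial": 0.5
  },
  {
   "id": "JUND",
   "role": "deg",
   "members": [
    "JUND"
   ],
   "initial": 0.5
  },
  {
   "id": "TNF",
   "role": "deg",
   "members": [
    "TNF"
   ],
   "initial": 0.5
  },
  {
   "id": "TRADD",
   "role": "deg",
   "members": [
    "TRADD"
   ],
   "initial": 0.5
  },
  {
   "id": "SRSF1",
   "role": "deg",
   "members": [
    "SRSF1"
   ],
   "initial": 0.5
  },
  {
   "id": "ELAVL1",
   "role": "deg",
   "members": [
    "ELAVL1"
   ],
   "initial": 0.5
  },
  {
   "id": "chemokines",
   "role": "complex",
   "members": [
    "CXCL1",
    "CXCL2",
    "CXCL8",
    "CCL20"
   ],
   "initial": 0.5
  },
  {
   "id": "CXCL3",
   "role": "deg",
   "members": [
    "CXCL3"
   ],
   "initial": 0.5
  },
  {
   "id": "antimicrobial",
   "role": "complex",
   "members": [
    "DEFB4A",
    "DEFB4B",
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
    "MMP3",
    "MMP9",
    "MMP13"
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
   "id": "TRAF2",
   "role": "inhibitor",
   "members": [
    "TRAF2"
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
   "k": 0.5
  },
  {
   "source": "IL17F",
   "target": "C1",
   "kind": "activation",
   "k": 0.5
  },
  {
   "source": "C1",
   "target": "TRAF6",
   "kind": "activation",
   "k": 0.6
  },
  {
   "source": "TRAF6",
   "target": "C2",
   "kind": "activation",
   "k": 0.6
  },
  {
   "source": "C2",
   "target": "IKBKG",
   "kind": "activation",
   "k": 1.0
  },
  {
   "source": "IKBKG",
   "target": "NFKB",
   "kind": "activation",
   "k": 0.8
  },
  {
   "source": "C2",
   "target": "MAPKs",
   "kind": "activation",
   "k": 1.0
  },
  {
   "source": "MAPKs",
   "target": "AP1",
   "kind": "activation",
   "k": 0.7
  },
  {
   "source": "JUND",
   "target": "AP1",
   "kind": "activation",
   "k": 0.5
  },
  {
   "source": "TNF",
   "target": "TRADD",
   "kind": "activation",
   "k": 0.5
  },
  {
   "source": "TRADD",
   "target": "NFKB",
   "kind": "activation",
   "k": 0.35
  },
  {
   "source": "ELAVL1",
   "target": "chemokines",
   "kind": "activation",
   "k": 0.4
  },
  {
   "source": "SRSF1",
   "target": "tissue_remodeling",
   "kind": "activation",
   "k": 0.25
  },
  {
   "source": "CXCL3",
   "target": "chemokines",
   "kind": "activation",
   "k": 0.5
  },
  {
   "source": "NFKB",
   "target": "chemokines",
   "kind": "activation",
   "k": 0.35609932097280916
  },
  {
   "source": "NFKB",
   "target": "antimicrobial",
   "kind": "activation",
   "k": 0.5872579223620499
  },
  {
   "source": "NFKB",
   "target": "IL1B",
   "kind": "activation",
   "k": 0.25
  },
  {
   "source": "AP1",
   "target": "chemokines",
   "kind": "activation",
   "k": 0.2848794567782474
  },
  {
   "source": "AP1",
   "target": "tissue_remodeling",
   "kind": "activation",
   "k": 0.25
  },
  {
   "source": "AP1",
   "target": "antimicrobial",
   "kind": "activation",
   "k": 0.46980633788964
  },
  {
   "source": "chemokines",
   "target": "neutrophil_recruitment",
   "kind": "activation",
   "k": 0.25
  },
  {
   "source": "antimicrobial",
   "target": "immunity_extracellular_pathogens",
   "kind": "activation",
   "k": 0.2642660650629225
  },
  {
   "source": "tissue_remodeling",
   "target": "autoimmune_pathology",
   "kind": "activation",
   "k": 0.25
  },
  {
   "source": "IL1B",
   "target": "autoimmune_pathology",
   "kind": "activation",
   "k": 0.25
  },
  {
   "source": "TRAF2",
   "target": "C1",
   "kind": "inhibition",
   "k": 0.25
  },
  {
   "source": "IKBKE",
   "target": "IKBKG",
   "kind": "inhibition",
   "k": 0.25
  }
 ]
}
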