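{
 "metabolites": [
  {
   "id": "AcCoA",
   "name": "",
   "is_internal": true
  },
  {
   "id": "CoA",
   "name": "",
   "is_internal": true
  },
  {
   "id": "Cit",
   "name": "",
   "is_internal": true
  },
  {
   "id": "ICit",
   "name": "",
   "is_internal": true
  },
  {
   "id": "AKG",
   "name": "",
   "is_internal": true
  },
  {
   "id": "SUCCoA",
   "name": "",
   "is_internal": true
  },
  {
   "id": "SUCC",
   "name": "",
   "is_internal": true
  },
  {
   "id": "Fum",
   "name": "",
   "is_internal": true
  },
  {
   "id": "L-Mal",
   "name": "",
   "is_internal": true
  },
  {
   "id": "OAA",
   "name": "",
   "is_internal": true
  },
  {
   "id": "Glx",
   "name": "",
   "is_internal": true
  },
  {
   "id": "Pyr",
   "name": "",
   "is_internal": true
  },
  {
   "id": "PEP",
   "name": "",
   "is_internal": true
  },
  {
   "id": "G6P",
   "name": "",
   "is_internal": true
  },
  {
   "id": "D-Glc",
   "name": "",
   "is_internal": true
  },
  {
   "id": "NAD",
   "name": "",
   "is_internal": true
  },
  {
   "id": "NADH",
   "name": "",
   "is_internal": true
  },
  {
   "id": "NADP",
   "name": "",
   "is_internal": true
  },
  {
   "id": "NADPH",
   "name": "",
   "is_internal": true
  },
  {
   "id": "ATP",
   "name": "",
   "is_internal": true
  },
  {
   "id": "ADP",
   "name": "",
   "is_internal": true
  },
  {
   "id": "CoQ",
   "name": "",
   "is_internal": true
  },
  {
   "id": "CoQH2",
   "name": "",
   "is_internal": true
  },
  {
   "id": "FA_ext",
   "name": "",
   "is_internal": false
  },
  {
   "id": "O2_ext",
   "name": "",
   "is_internal": false
  },
  {
   "id": "CO2_ext",
   "name": "",
   "is_internal": false
  },
  {
   "id": "Glc_ext",
   "name": "",
   "is_internal": false
  }
 ],
 "reactions": [
  {
   "id": "FAO",
   "stoichiometry": {
    "FA_ext": -1,
    "CoA": -1,
    "NAD": -1,
    "AcCoA": 1,
    "NADH": 1
   },
   "reversible": false
  },
  {
   "id": "CS",
   "stoichiometry": {
    "AcCoA": -1,
    "OAA": -1,
    "Cit": 1,
    "CoA": 1
   },
   "reversible": false
  },
  {
   "id": "ACONT",
   "stoichiometry": {
    "Cit": -1,
    "ICit": 1
   },
   "reversible": true
  },
  {
   "id": "ICDHyr",
   "stoichiometry": {
    "ICit": -1,
    "NADP": -1,
    "AKG": 1,
    "CO2_ext": 1,
    "NADPH": 1
   },
   "reversible": true
  },
  {
   "id": "AKGDH",
   "stoichiometry": {
    "AKG": -1,
    "NAD": -1,
    "CoA": -1,
    "SUCCoA": 1,
    "CO2_ext": 1,
    "NADH": 1
   },
   "reversible": false
  },
  {
   "id": "SUCOAS",
   "stoichiometry": {
    "SUCCoA": -1,
    "ADP": -1,
    "SUCC": 1,
    "CoA": 1,
    "ATP": 1
   },
   "reversible": true
  },
  {
   "id": "SUCDi",
   "stoichiometry": {
    "SUCC": -1,
    "CoQ": -1,
    "Fum": 1,
    "CoQH2": 1
   },
   "reversible": false
  },
  {
   "id": "FUM",
   "stoichiometry": {
    "Fum": -1,
    "L-Mal": 1
   },
   "reversible": true
  },
  {
   "id": "MDH",
   "stoichiometry": {
    "L-Mal": -1,
    "NAD": -1,
    "OAA": 1,
    "NADH": 1
   },
   "reversible": true
  },
  {
   "id": "PDH",
   "stoichiometry": {
    "Pyr": -1,
    "CoA": -1,
    "NAD": -1,
    "AcCoA": 1,
    "CO2_ext": 1,
    "NADH": 1
   },
   "reversible": false
  },
  {
   "id": "PYK",
   "stoichiometry": {
    "PEP": -1,
    "ADP": -1,
    "Pyr": 1,
    "ATP": 1
   },
   "reversible": false
  },
  {
   "id": "PC",
   "stoichiometry": {
    "Pyr": -1,
    "CO2_ext": -1,
    "ATP": -1,
    "OAA": 1,
    "ADP": 1
   },
   "reversible": false
  },
  {
   "id": "PCK1",
   "stoichiometry": {
    "OAA": -1,
    "ATP": -1,
    "PEP": 1,
    "CO2_ext": 1,
    "ADP": 1
   },
   "reversible": false
  },
  {
   "id": "ME1",
   "stoichiometry": {
    "L-Mal": -1,
    "NAD": -1,
    "Pyr": 1,
    "CO2_ext": 1,
    "NADH": 1
   },
   "reversible": false
  },
  {
   "id": "GNEO",
   "stoichiometry": {
    "PEP": -2,
    "ATP": -2,
    "NADH": -2,
    "G6P": 1,
    "ADP": 2,
    "NAD": 2
   },
   "reversible": false
  },
  {
   "id": "G6PP",
   "stoichiometry": {
    "G6P": -1,
    "D-Glc": 1
   },
   "reversible": false
  },
  {
   "id": "GLCex",
   "stoichiometry": {
    "D-Glc": -1,
    "Glc_ext": 1
   },
   "reversible": false
  },
  {
   "id": "NADHOX",
   "stoichiometry": {
    "NADH": -1,
    "CoQ": -1,
    "NAD": 1,
    "CoQH2": 1
   },
   "reversible": false
  },
  {
   "id": "QOX",
   "stoichiometry": {
    "CoQH2": -1,
    "O2_ext": -0.5,
    "CoQ": 1
   },
   "reversible": false
  },
  {
   "id": "ATPS",
   "stoichiometry": {
    "ADP": -1,
    "ATP": 1
   },
   "reversible": false
  },
  {
   "id": "THD",
   "stoichiometry": {
    "NADPH": -1,
    "NAD": -1,
    "NADP": 1,
    "NADH": 1
   },
   "reversible": false
  }
 ]
}
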