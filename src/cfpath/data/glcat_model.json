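{
 "metabolites": [
  {
   "id": "DGlc",
   "name": "",
   "is_internal": true
  },
  {
   "id": "AcGlcD",
   "name": "",
   "is_internal": true
  },
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
   "id": "Prod",
   "name": "",
   "is_internal": true
  },
  {
   "id": "Glc_ext",
   "name": "",
   "is_internal": false
  },
  {
   "id": "Ac_ext",
   "name": "",
   "is_internal": false
  },
  {
   "id": "P_ext",
   "name": "",
   "is_internal": false
  }
 ],
 "reactions": [
  {
   "id": "GLCIN",
   "stoichiometry": {
    "Glc_ext": -1,
    "DGlc": 1
   },
   "reversible": false
  },
  {
   "id": "GLCATr",
   "stoichiometry": {
    "DGlc": -1,
    "AcCoA": -1,
    "AcGlcD": 1,
    "CoA": 1
   },
   "reversible": true
  },
  {
   "id": "ACS",
   "stoichiometry": {
    "Ac_ext": -1,
    "CoA": -1,
    "AcCoA": 1
   },
   "reversible": false
  },
  {
   "id": "USE",
   "stoichiometry": {
    "AcCoA": -1,
    "Prod": 1,
    "CoA": 1
   },
   "reversible": false
  },
  {
   "id": "EXP",
   "stoichiometry": {
    "Prod": -1,
    "P_ext": 1
   },
   "reversible": false
  }
 ]
}
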