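{
 "metabolites": [
  {
   "id": "A",
   "name": "",
   "is_internal": true,
   "formula": "C2H4O2"
  },
  {
   "id": "B",
   "name": "",
   "is_internal": true,
   "formula": "C2H4O2"
  },
  {
   "id": "C",
   "name": "",
   "is_internal": true,
   "formula": "C2H4O2"
  },
  {
   "id": "D",
   "name": "",
   "is_internal": true,
   "formula": "C2H4O2"
  },
  {
   "id": "E",
   "name": "",
   "is_internal": true,
   "formula": "C2H4O2"
  },
  {
   "id": "F",
   "name": "",
   "is_internal": true,
   "formula": "C2H4O2"
  },
  {
   "id": "A_ext",
   "name": "",
   "is_internal": false,
   "formula": "C2H4O2"
  },
  {
   "id": "D_ext",
   "name": "",
   "is_internal": false,
   "formula": "C2H4O2"
  },
  {
   "id": "F_ext",
   "name": "",
   "is_internal": false,
   "formula": "C2H4O2"
  }
 ],
 "reactions": [
  {
   "id": "r1",
   "stoichiometry": {
    "A_ext": -1,
    "A": 1
   },
   "reversible": false
  },
  {
   "id": "r2",
   "stoichiometry": {
    "A": -1,
    "B": 1
   },
   "reversible": false
  },
  {
   "id": "r3",
   "stoichiometry": {
    "B": -1,
    "C": 1
   },
   "reversible": false
  },
  {
   "id": "r4",
   "stoichiometry": {
    "C": -1,
    "D": -1,
    "E": 1
   },
   "reversible": false
  },
  {
   "id": "r5",
   "stoichiometry": {
    "E": -1,
    "F": 1
   },
   "reversible": false
  },
  {
   "id": "r6",
   "stoichiometry": {
    "D_ext": -1,
    "D": 1
   },
   "reversible": false
  },
  {
   "id": "r7",
   "stoichiometry": {
    "F": -1,
    "F_ext": 1
   },
   "reversible": false
  }
 ]
}
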