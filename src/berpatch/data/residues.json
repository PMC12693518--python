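{
  "_comment": "Elemental formulas of DNA chain residues, given as the free 2'-deoxynucleoside 5'-monophosphate (chain composition = sum of residues minus (n-1) H2O; a 5'-hydroxyl end removes one HPO3). AP = intact abasic 2-deoxyribose (cyclic hemiacetal); rAP = borohydride-reduced, ring-opened abasic alcohol (AP + H2); F = tetrahydrofuran abasic analog (1',2'-dideoxyribose, AP - O). Cross-checked against Biopython's monoisotopic DNA masses in the test suite.",
  "residues": {
    "A":   {"C": 10, "H": 14, "N": 5, "O": 6, "P": 1},
    "C":   {"C": 9,  "H": 14, "N": 3, "O": 7, "P": 1},
    "G":   {"C": 10, "H": 14, "N": 5, "O": 7, "P": 1},
    "T":   {"C": 10, "H": 15, "N": 2, "O": 8, "P": 1},
    "U":   {"C": 9,  "H": 13, "N": 2, "O": 8, "P": 1},
    "AP":  {"C": 5,  "H": 11, "N": 0, "O": 7, "P": 1},
    "rAP": {"C": 5,  "H": 13, "N": 0, "O": 7, "P": 1},
    "F":   {"C": 5,  "H": 11, "N": 0, "O": 6, "P": 1}
  }
}
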