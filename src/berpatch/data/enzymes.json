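{
  "_comment": "Restriction/nicking enzyme table. Cut offsets are counted from the 5' end of the recognition string on the top strand; the bottom offset is given in the same (top-strand) coordinate frame. Nicking enzymes cut only the indicated strand; their offset may fall outside the recognition string (supplier convention, e.g. Nt.BspQI cuts one nucleotide 3' of its site).",
  "enzymes": [
    {"name": "NdeI",     "recognition": "CATATG",  "cut_offset_top": 2, "cut_offset_bottom": 4, "nicking": "none"},
    {"name": "HaeII",    "recognition": "RGCGCY",  "cut_offset_top": 5, "cut_offset_bottom": 1, "nicking": "none"},
    {"name": "PstI",     "recognition": "CTGCAG",  "cut_offset_top": 5, "cut_offset_bottom": 1, "nicking": "none"},
    {"name": "BsoBI",    "recognition": "CYCGRG",  "cut_offset_top": 1, "cut_offset_bottom": 5, "nicking": "none"},
    {"name": "Nt.BspQI", "recognition": "GCTCTTC", "cut_offset_top": 8, "cut_offset_bottom": 0, "nicking": "top"},
    {"name": "Nb.BbvCI", "recognition": "CCTCAGC", "cut_offset_top": 0, "cut_offset_bottom": 2, "nicking": "bottom"}
  ]
}
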