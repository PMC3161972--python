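{
  "_comment": "Synthetic default motif patterns (amino-acid regular expressions) per monolignol gene family. These are editable placeholders standing in for curated conserved motifs; replace them with family motifs from the literature for real analyses.",
  "PAL": ["GTITASGDLVPLSYIA", "NDN"],
  "C4H": ["FGAGRRICAG", "PERF"],
  "C3H": ["GGEK"],
  "COMT": ["GGG"],
  "F5H": ["PFGAGRRSCPG"],
  "4CL": ["SSGTTGLPKGV", "GEICIRG"],
  "HCT": ["HKVKD", "DFGWG"],
  "CCoAOMT": ["VGPGTG"],
  "CAD": ["GLGGVG"],
  "CCR": ["KNWYCYGK"]
}
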