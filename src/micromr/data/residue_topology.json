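{
  "_comment": "Heavy-atom side-chain topology per residue type, in side-chain tree order (main chain N, CA, C, O implicit; CB first where present).",
  "ALA": ["CB"],
  "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
  "ASN": ["CB", "CG", "OD1", "ND2"],
  "ASP": ["CB", "CG", "OD1", "OD2"],
  "CYS": ["CB", "SG"],
  "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
  "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
  "GLY": [],
  "HIS": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
  "ILE": ["CB", "CG1", "CG2", "CD1"],
  "LEU": ["CB", "CG", "CD1", "CD2"],
  "LYS": ["CB", "CG", "CD", "CE", "NZ"],
  "MET": ["CB", "CG", "SD", "CE"],
  "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
  "PRO": ["CB", "CG", "CD"],
  "SER": ["CB", "OG"],
  "THR": ["CB", "OG1", "CG2"],
  "TRP": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
  "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
  "UNK": ["CB"],
  "VAL": ["CB", "CG1", "CG2"]
}
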