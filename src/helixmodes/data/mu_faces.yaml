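# Helical-wheel face definition for the IgM heavy-chain (mu) transmembrane
# helix. The wheel advances 100 degrees per residue; angles are relative to
# the reference residue below. Sectors are half-open [start, end) in degrees
# and may wrap through 360 (start > end).
#
# TM-C is the face conserved across membrane-immunoglobulin classes; TM-S is
# the class-specific face. The residue lists name the interface residues the
# wheel sectors are anchored on (mu-chain numbering 442-473).
reference_residue: 449
sectors:
  TM-C: [330.0, 130.0]
  TM-S: [150.0, 330.0]
tm_c_residues: [449, 453, 456, 457, 460, 461, 464, 467, 468]
tm_s_residues: [447, 451, 452, 455, 459, 462, 463, 465, 466, 470]
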