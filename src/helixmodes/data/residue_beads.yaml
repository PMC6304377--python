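# 1-bead-per-residue coarse-grained classes: C apolar, N aromatic, P polar,
# Q charged. Charges in elementary charge units (only K/R/D/E carry charge).
ALA: {bead_type: C, charge: 0.0}
VAL: {bead_type: C, charge: 0.0}
LEU: {bead_type: C, charge: 0.0}
ILE: {bead_type: C, charge: 0.0}
MET: {bead_type: C, charge: 0.0}
PRO: {bead_type: C, charge: 0.0}
CYS: {bead_type: C, charge: 0.0}
PHE: {bead_type: N, charge: 0.0}
TRP: {bead_type: N, charge: 0.0}
TYR: {bead_type: N, charge: 0.0}
HIS: {bead_type: N, charge: 0.0}
GLY: {bead_type: P, charge: 0.0}
SER: {bead_type: P, charge: 0.0}
THR: {bead_type: P, charge: 0.0}
ASN: {bead_type: P, charge: 0.0}
GLN: {bead_type: P, charge: 0.0}
LYS: {bead_type: Q, charge: 1.0}
ARG: {bead_type: Q, charge: 1.0}
ASP: {bead_type: Q, charge: -1.0}
GLU: {bead_type: Q, charge: -1.0}
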