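# Per-residue scalar features broadcast to all atoms of a residue.
#
# hydrophobicity: Kyte-Doolittle scale (unitless, positive = hydrophobic)
# charge: net formal charge at physiological pH (elementary charges;
#         His carries a small fractional value for its partial protonation)
# binding_probability: relative propensity of the residue to occur in
#         ligand-binding sites, rescaled to [0, 1]. These defaults are a
#         literature-style propensity ordering (aromatic/large residues
#         high, small polar residues low); the table is an editable
#         config and can be replaced wholesale.
#
# The UNK row is the explicit fallback for any residue name not listed.
ALA: {hydrophobicity:  1.8, charge:  0.0, binding_probability: 0.26}
ARG: {hydrophobicity: -4.5, charge:  1.0, binding_probability: 0.38}
ASN: {hydrophobicity: -3.5, charge:  0.0, binding_probability: 0.36}
ASP: {hydrophobicity: -3.5, charge: -1.0, binding_probability: 0.40}
CYS: {hydrophobicity:  2.5, charge:  0.0, binding_probability: 0.45}
GLN: {hydrophobicity: -3.5, charge:  0.0, binding_probability: 0.33}
GLU: {hydrophobicity: -3.5, charge: -1.0, binding_probability: 0.35}
GLY: {hydrophobicity: -0.4, charge:  0.0, binding_probability: 0.35}
HIS: {hydrophobicity: -3.2, charge:  0.1, binding_probability: 0.60}
ILE: {hydrophobicity:  4.5, charge:  0.0, binding_probability: 0.30}
LEU: {hydrophobicity:  3.8, charge:  0.0, binding_probability: 0.32}
LYS: {hydrophobicity: -3.9, charge:  1.0, binding_probability: 0.27}
MET: {hydrophobicity:  1.9, charge:  0.0, binding_probability: 0.48}
PHE: {hydrophobicity:  2.8, charge:  0.0, binding_probability: 0.60}
PRO: {hydrophobicity: -1.6, charge:  0.0, binding_probability: 0.25}
SER: {hydrophobicity: -0.8, charge:  0.0, binding_probability: 0.30}
THR: {hydrophobicity: -0.7, charge:  0.0, binding_probability: 0.31}
TRP: {hydrophobicity: -0.9, charge:  0.0, binding_probability: 0.85}
TYR: {hydrophobicity: -1.3, charge:  0.0, binding_probability: 0.72}
VAL: {hydrophobicity:  4.2, charge:  0.0, binding_probability: 0.29}
UNK: {hydrophobicity:  0.0, charge:  0.0, binding_probability: 0.00}
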