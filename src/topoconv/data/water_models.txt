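# Reference three-site water models used for recognition.
# Columns: name  q_O(e)  q_H(e)  sigma_O(nm)  epsilon_O(kJ/mol)
# TIP3P: Jorgensen et al., J. Chem. Phys. 79 (1983) 926; eps = 0.1521 kcal/mol.
# SPC/E: Berendsen et al., J. Phys. Chem. 91 (1987) 6269; eps = 0.1553 kcal/mol.
# Hydrogen LJ is zero in both models.
TIP3P  -0.834   0.417   0.315061  0.6363864
SPCE   -0.8476  0.4238  0.316557  0.6497752
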