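# Newly fitted torsion parameters for N-aryl amides and phenylpyrroles.
# Format: TT I J K L V1 V2 V3   (atom type 0 = wildcard; energies in kcal/mol)
# Atom types: 0 wildcard, 3 carbonyl carbon, 10 amide nitrogen, 28 amide
# hydrogen, 37 aromatic carbon, 39 pyrrole nitrogen, 44 thiophene sulfur,
# 63 alpha carbon (5-ring heteroaromatic), 64 beta carbon, 65 alpha aromatic
# 5-ring nitrogen, 66 beta aromatic 5-ring nitrogen.
#
# N-aryl amides
0 0 10 37 0     0.0    2.7   0.0
0 3 10 64 66   -0.31  -5.82  0.0
0 28 10 64 66   0.00   1.29  0.00
0 3 10 64 63    0.00   7.97  0.00
0 28 10 64 63   0.00   7.97  0.00
0 3 10 64 64    2.47  -3.26  0.00
0 28 10 64 64   0.00   4.76  0.00
0 3 10 64 65   -0.76   8.14  0.00
0 28 10 64 65   0.00   5.27  0.00
0 44 63 10 3  -11.5    6.60  0.00
0 44 63 10 28   0.00   3.34  0.00
# Phenylpyrroles
1 0 37 39 0     0.0    2.6   0.0
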