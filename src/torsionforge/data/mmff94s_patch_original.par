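# Original MMFF94s torsion record superseded by the refit.
# Format: TT I J K L V1 V2 V3   (atom type 0 = wildcard; energies in kcal/mol)
#
# Only the record whose coefficients are quoted in the source implementation
# notes is shipped here.  The original 0-63-10-0, 0-64-10-0 and 0-37-39-0
# records are referenced but their coefficients are not reproduced.
0 0 10 37 0   0.0 6.0 0.0
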