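# table: atom transfer free energies
# units: kcal/mol, water -> membrane core
# provenance: least-squares distribution of the Fauchere-Pliska side-chain
# provenance: octanol partition scale (sign-flipped to water->apolar) over
# provenance: side-chain heavy-atom category counts of idealized residues;
# provenance: guanidinium N split from ammonium N (delocalized charge);
# provenance: backbone atoms 0 by convention (the scale covers side chains only)
backbone	0.0000
aliphatic_C	-0.3713
aromatic_C	-0.2592
polar_N	0.4991
charged_N	2.4754
guanidinium_N	0.8318
polar_O	0.7078
charged_O	0.8167
sulfur	-0.6423
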