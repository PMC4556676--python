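# table: packing radii and well depths per atom category
# columns: category radius epsilon
# units: Angstrom, kcal/mol
# provenance: Bondi-type van der Waals radii; uniform shallow well depths;
# provenance: backbone uses a compromise radius for its mixed N/C/O content
backbone	1.65	0.10
aliphatic_C	1.70	0.12
aromatic_C	1.75	0.10
polar_N	1.55	0.16
charged_N	1.55	0.16
guanidinium_N	1.55	0.16
polar_O	1.52	0.16
charged_O	1.52	0.16
sulfur	1.80	0.20
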