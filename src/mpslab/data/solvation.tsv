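# table: Gaussian-exclusion solvation parameters per atom category
# columns: category dgfree_water dgfree_memb lambda radius volume
# units: kcal/mol, Angstrom, Angstrom^3
# provenance: EEF1-flavored reference free energies; apolar carbon positive
# provenance: (hydrophobic effect), polar/charged negative; backbone kept
# provenance: small because helical backbone amides are internally hydrogen
# provenance: bonded and largely pre-desolvated; the membrane-phase value is
# provenance: the water value shifted by the category's transfer energy from
# provenance: atom_transfer.tsv; lambda is the standard 3.5 A correlation
# provenance: length; radii Bondi-type; volumes approximate group volumes
backbone	-1.00	-1.0000	3.5	1.65	14.7
aliphatic_C	0.52	0.1487	3.5	1.70	23.7
aromatic_C	0.20	-0.0592	3.5	1.75	18.4
polar_N	-5.00	-4.5009	3.5	1.55	11.2
charged_N	-10.00	-7.5246	3.5	1.55	11.2
guanidinium_N	-5.00	-4.1682	3.5	1.55	11.2
polar_O	-5.00	-4.2922	3.5	1.52	10.8
charged_O	-10.00	-9.1833	3.5	1.52	10.8
sulfur	-0.50	-1.1423	3.5	1.80	14.7
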