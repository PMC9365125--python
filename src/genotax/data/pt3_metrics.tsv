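# Published pairwise relatedness metrics of strain PT3 (Al. hakodatensis)
# against the seven reference type strains, as printed in the describing
# study.  AAI against the five Amphritea references was printed only as a
# range (64.6-67.1%); the two endpoints are assigned to atlantica/balenae
# and interior values to the remaining three -- every choice within the
# printed range yields the same delineation verdict.  16S similarity was
# printed as 98.3% for spongicola/ceti and 95.4-98.3% overall; interior
# values are likewise representative only.
genome_a	genome_b	metric	value
PT3	Al_spongicola	ANI	89.0
PT3	Al_ceti	ANI	80.1
PT3	A_atlantica	ANI	72.2
PT3	A_pacifica	ANI	72.2
PT3	A_opalescens	ANI	71.3
PT3	A_japonica	ANI	71.7
PT3	A_balenae	ANI	72.3
PT3	Al_spongicola	dDDH	36.4
PT3	Al_ceti	dDDH	22.7
PT3	A_atlantica	dDDH	21.9
PT3	A_pacifica	dDDH	21.5
PT3	A_opalescens	dDDH	21.2
PT3	A_japonica	dDDH	22.5
PT3	A_balenae	dDDH	22.3
PT3	Al_spongicola	AAI	93.7
PT3	Al_ceti	AAI	86.9
PT3	A_atlantica	AAI	67.1
PT3	A_balenae	AAI	64.6
PT3	A_japonica	AAI	65.8
PT3	A_opalescens	AAI	65.2
PT3	A_pacifica	AAI	66.4
PT3	Al_spongicola	16S	98.3
PT3	Al_ceti	16S	98.3
PT3	A_atlantica	16S	95.4
PT3	A_japonica	16S	95.8
PT3	A_balenae	16S	95.6
PT3	A_opalescens	16S	95.5
PT3	A_pacifica	16S	95.7
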