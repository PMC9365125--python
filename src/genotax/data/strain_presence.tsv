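# Bundled reference presence/absence matrix for the eight type-strain genomes
# of Aliamphritea (hakodatensis, ceti, spongicola) and Amphritea (atlantica,
# japonica, balenae, opalescens, pacifica), transcribed from the published
# gene-composition tables and clade-level gene distributions.
# +: gene present; -: absent.
symbol	Al_hakodatensis	Al_ceti	Al_spongicola	A_atlantica	A_japonica	A_balenae	A_opalescens	A_pacifica
accA	+	+	+	+	+	+	+	+
accB	+	+	+	+	+	+	+	+
accC	+	+	+	+	+	+	+	+
accD	+	+	+	+	+	+	+	+
fabD	+	+	+	+	+	+	+	+
fabH	+	+	+	-	-	-	-	-
fabY	+	+	+	+	+	+	+	+
fabB	+	+	+	+	+	+	+	+
fabF	+	+	+	+	+	+	+	+
fabG	+	+	+	+	+	+	+	+
fabA	+	+	+	+	+	+	+	+
fabZ	+	+	+	+	+	+	+	+
fabI	-	-	+	+	+	+	-	+
fabV	+	+	+	+	+	+	+	+
Des1	+	+	+	-	-	-	-	-
Des2	+	+	+	-	-	-	-	-
Des3	+	+	+	-	-	-	-	-
Des4	-	-	-	+	-	-	-	+
lpxA	+	+	+	+	+	+	+	+
pfaA	-	-	-	-	-	-	-	-
pfaB	-	-	-	-	-	-	-	-
pfaC	-	-	-	-	-	-	-	-
pfaD	-	-	-	-	-	-	-	-
oleA	-	-	-	-	-	-	-	-
oleB	-	-	-	-	-	-	-	-
oleC	-	-	-	-	-	-	-	-
oleD	-	-	-	-	-	-	-	-
plsX	+	+	+	+	+	+	+	+
plsY	+	+	+	+	+	+	+	+
plsC	+	+	+	+	+	+	+	+
cdsA	+	+	+	+	+	+	+	+
pssA	+	+	+	+	+	+	+	+
psd	+	+	+	+	+	+	+	+
pgsA	+	+	+	+	+	+	+	+
pgpA	+	+	+	+	+	+	+	+
cls	-	-	-	+	-	+	+	+
ubiC	+	+	+	+	+	+	+	+
ubiA	+	+	+	+	+	+	+	+
ubiD	+	+	+	+	+	+	+	+
ubiX	+	+	+	+	+	+	+	+
ubiI	+	+	+	+	+	+	+	+
ubiG	+	+	+	+	+	+	+	+
ubiH	+	+	+	+	+	+	+	+
ubiE	+	+	+	+	+	+	+	+
ispA	+	+	+	+	+	+	+	+
ispB	+	+	+	+	+	+	+	+
ubiB	+	+	+	+	+	+	+	+
ubiJ	+	+	+	+	+	+	+	+
ubiK	+	+	+	+	+	+	+	+
ubiF	+	+	+	+	+	+	+	+
speA	+	+	+	+	+	+	+	+
speB	+	+	+	+	+	+	+	+
speC	-	-	-	+	+	+	+	+
speD	-	-	-	+	+	+	+	+
speE	+	+	+	+	+	+	+	+
spuC	+	+	+	+	+	+	+	+
kauB	+	+	+	+	+	+	+	+
phaA	+	+	+	+	+	+	+	+
phaB	+	+	+	+	+	+	+	+
phaC	+	+	+	+	+	+	+	+
phaE	+	+	+	+	+	+	+	+
dctM	+	+	+	+	+	+	+	+
dctP	+	+	+	+	+	+	+	+
dctQ	+	+	+	+	+	+	+	+
tctA	+	+	+	+	-	+	+	+
tctB	+	+	+	+	-	+	+	+
tctC	+	+	+	+	-	+	+	+
yejA	-	-	-	+	+	+	+	+
yejB	-	-	-	+	+	+	+	+
yejE	-	-	-	+	+	+	+	+
yejF	-	-	-	+	+	+	+	+
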