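# Common type-II restriction endonucleases with 4-6 bp recognition sites.
# Columns: name, recognition site (IUPAC), cut offset = number of site bases
# 5' of the top-strand cut (G^GATCC -> offset 1).  User-extensible.
name	site	cut_offset
AflII	CTTAAG	1
AluI	AGCT	2
ApoI	RAATTY	1
AvaI	CYCGRG	1
BamHI	GGATCC	1
BglII	AGATCT	1
BsrGI	TGTACA	1
ClaI	ATCGAT	2
DdeI	CTNAG	1
DraI	TTTAAA	3
EcoRI	GAATTC	1
EcoRV	GATATC	3
HaeIII	GGCC	2
HhaI	GCGC	3
HindIII	AAGCTT	1
HinfI	GANTC	1
HpaII	CCGG	1
KpnI	GGTACC	5
MboI	GATC	0
MseI	TTAA	1
NcoI	CCATGG	1
NdeI	CATATG	2
NheI	GCTAGC	1
NlaIII	CATG	4
PstI	CTGCAG	5
PvuII	CAGCTG	3
RsaI	GTAC	2
SacI	GAGCTC	5
SalI	GTCGAC	1
ScaI	AGTACT	3
SpeI	ACTAGT	1
SphI	GCATGC	5
SspI	AATATT	3
TaqI	TCGA	1
XbaI	TCTAGA	1
XhoI	CTCGAG	1
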