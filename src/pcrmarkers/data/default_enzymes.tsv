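# Default restriction-enzyme panel: enzymes that digest reliably in PCR buffer.
# Columns: name, IUPAC recognition site, cut offset (0-based, top strand).
TaqI	TCGA	1
AluI	AGCT	2
RsaI	GTAC	2
DpnII	GATC	0
HinfI	GANTC	1
HaeIII	GGCC	2
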