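# Division of the 20 natural amino acids into three groups per
# physicochemical property (Dubchak-style CTD groupings).
# columns: property <TAB> group1 <TAB> group2 <TAB> group3
hydrophobicity	DEKNQR	AGHPSTY	CFILMVW
vdw_volume	ACDGPST	EILNQV	FHKMRWY
polarity	CFILMVWY	AGPST	DEHKNQR
polarizability	ADGST	CEILNPQV	FHKMRWY
charge	KR	DE	ACFGHILMNPQSTVWY
secondary_structure	AEHKLMQR	CFITVWY	DGNPS
solvent_accessibility	ACFGILVW	DEKNQR	HMPSTY
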