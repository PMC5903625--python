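# Default function-category KO sets. The three SCFA production pathways are the
# exact published enzyme sets (acetate kinase / acetyl-CoA synthase / phosphate
# acetyltransferase; propionate CoA-transferase / acetyl-CoA synthase; butyrate
# kinase / acetoacetate CoA-transferase / phosphate butyryltransferase) —
# K01895 genuinely appears in both the acetate and propionate sets. The
# peptidase / amino-acid metabolism / amino-acid transporter sets are synthetic
# editable defaults: replace them with project-specific KEGG BRITE selections.
category	kos
peptidases	K77001,K77002,K77003,K77004,K77005,K77006,K77007,K77008
amino_acid_metabolism	K77011,K77012,K77013,K77014,K77015,K77016,K77017,K77018
amino_acid_transport	K77021,K77022,K77023,K77024,K77025,K77026
scfa_acetate	K00925,K00625,K01895,K13788
scfa_propionate	K01895,K01026
scfa_butyrate	K01034,K01035,K01896,K00929,K00634
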