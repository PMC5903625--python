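# Synthetic default module catalog. Module ids, descriptions and set sizes follow
# the six-module sugar/protein contrast analysed by the pipeline; KO memberships
# are synthetic placeholders (KEGG's own module definitions are licensed data and
# should be supplied as a user TSV for real analyses).
module_id	description	kos
M00377	Reductive acetyl-CoA pathway (Wood-Ljungdahl pathway)	K76001,K76002,K76003,K76004,K76005,K76006,K76007,K76008,K76009,K76010
M00422	Acetyl-CoA pathway, CO2 => acetyl-CoA	K76011,K76012,K76013,K76014,K76015
M00196	Multiple sugar transport system	K76016,K76017,K76018,K76019
M00018	Threonine biosynthesis, aspartate => homoserine => threonine	K76020,K76021,K76022,K76023,K76024,K76025,K76026,K76027,K76028,K76029
M00299	Spermidine/putrescine transport system	K76030,K76031,K76032,K76033
M00236	Putative polar amino acid transport system	K76034,K76035,K76036
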