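drug	target
Celecoxib	PDPK1
Dasatinib	EPHA2
Erlotinib	EGFR
Everolimus	MTOR
Gefitinib	EGFR
Imatinib	PDGFRA
Lapatinib	EGFR
Lapatinib	ERBB2
Sirolimus	MTOR
Tamoxifen	PRKCI
Tamoxifen	PRKCZ
Thalidomide	TNF
Vandetanib	EGFR
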