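drug_code	name	status	gene
D09GYT	Methoxamine	Approved	SGT15
D0T6SU	Phendimetrazine	Approved	SGT16
D0AZ3C	Imatinib	Approved	INT15
D03LJR	Sirolimus	Approved	INT16
D0K3QS	Everolimus	Approved	INT17
D0ES1Q	Temsirolimus	Approved	INT18
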