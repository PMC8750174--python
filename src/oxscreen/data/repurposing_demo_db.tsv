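drug_id	name	group	gene
DB00114	Pyridoxal phosphate	approved	SGT01
DB00114	Pyridoxal phosphate	approved	INT01
DB00321	Amitriptyline	approved	SGT02
DB00321	Amitriptyline	approved	INT02
DB00668	Epinephrine	approved	SGT03
DB00668	Epinephrine	approved	INT03
DB01427	Amrinone	approved	SGT04
DB01427	Amrinone	approved	INT04
DB06637	Dalfampridine	approved	SGT05
DB06637	Dalfampridine	approved	INT05
DB15035	Zanubrutinib	approved	SGT06
DB15035	Zanubrutinib	approved	INT06
DB01133	Tiludronic acid	approved	SGT07
DB01133	Tiludronic acid	approved	INT07
DB01593	Zinc	approved	SGT08
DB01593	Zinc	approved	INT08
DB14487	Zinc acetate	approved	SGT09
DB14487	Zinc acetate	approved	INT09
DB14533	Zinc chloride	approved	SGT10
DB14533	Zinc chloride	approved	INT10
DB14548	Zinc sulfate	approved	SGT11
DB14548	Zinc sulfate	approved	INT11
DB12010	Fostamatinib	approved	SGT12
DB12010	Fostamatinib	approved	INT12
DB04272	Citric acid	approved	SGT13
DB04272	Citric acid	approved	INT13
DB09130	Copper	approved	SGT14
DB09130	Copper	approved	INT14
DB00723	Methoxamine	approved	SGT15
DB01579	Phendimetrazine	approved	SGT16
DB00619	Imatinib	approved	INT15
DB00877	Sirolimus	approved	INT16
DB01590	Everolimus	approved	INT17
DB06287	Temsirolimus	approved	INT18
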