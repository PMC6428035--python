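rsid	gene	level	drugs	association_type
rs1057910	CYP2C9	1A	warfarin;phenytoin	dosage
rs1799853	CYP2C9	1A	warfarin;phenytoin	dosage
rs3892097	CYP2D6	1A	amitriptyline;clomipramine;desipramine;doxepin;imipramine;nortriptyline;trimipramine	dosage
rs5030655	CYP2D6	1A	paroxetine;fluvoxamine;amitriptyline;nortriptyline;codeine	dosage
rs1065852	CYP2D6	1A	paroxetine;nortriptyline;codeine;amitriptyline	dosage
rs1065852	CYP2D6	1B	tramadol	efficacy
rs4149056	SLCO1B1	1A	simvastatin	toxicity
rs35742686	CYP2D6	1A	amitriptyline;nortriptyline;trimipramine;clomipramine;tamoxifen;codeine;paroxetine;doxepin;fluvoxamine	dosage
rs35742686	CYP2D6	1B	tramadol	efficacy
rs7294	VKORC1	1B	warfarin	dosage
rs2108622	CYP4F2	1A	warfarin	dosage
rs3745274	CYP2B6	1B	efavirenz	dosage
rs4244285	CYP2C19	1A	amitriptyline;clopidogrel	efficacy
rs28399504	CYP2C19	1A	clopidogrel	efficacy
rs41291556	CYP2C19	1A	clopidogrel	efficacy
rs113993960	CFTR	1A	ivacaftor	efficacy
rs115545701	CFTR	1A	ivacaftor	efficacy
rs113993958	CFTR	1A	ivacaftor	efficacy
rs150212784	CFTR	1A	ivacaftor	efficacy
rs78769542	CFTR	1A	ivacaftor	efficacy
rs75541969	CFTR	1A	ivacaftor	efficacy
rs67376798	DPYD	1A	capecitabine;fluorouracil;pyrimidine analogs;tegafur	toxicity
rs3918290	DPYD	1A	capecitabine;fluorouracil;pyrimidine analogs;tegafur	toxicity
rs1800462	TPMT	1A	azathioprine;mercaptopurine;purine analogs;thioguanine	toxicity
rs1800460	TPMT	1A	azathioprine;mercaptopurine;purine analogs;thioguanine	toxicity
rs1142345	TPMT	1A	azathioprine;mercaptopurine;purine analogs;thioguanine	toxicity
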