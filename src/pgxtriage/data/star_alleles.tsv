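gene	allele_name	defining_rsids	function_class
CYP2C9	*2	rs1799853	decreased
CYP2C9	*3	rs1057910	decreased
CYP2D6	*3	rs35742686	none
CYP2D6	*4	rs3892097	none
CYP2D6	*6	rs5030655	none
CYP2C19	*2	rs4244285	none
CYP2C19	*4	rs28399504	none
CYP2C19	*8	rs41291556	none
SLCO1B1	*5	rs4149056	decreased
DPYD	*2A	rs3918290	none
TPMT	*2	rs1800462	decreased
TPMT	*3A	rs1800460;rs1142345	none
TPMT	*3B	rs1800460	decreased
TPMT	*3C	rs1142345	decreased
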