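gene	domain	start	end
ASXL1	HARE	11	83
ASXL1	ASXH	241	369
ASXL1	PHD	1506	1541
EZH2	SANT1	159	250
EZH2	SANT2	433	481
EZH2	SET	617	738
DNMT3A	PWWP	290	348
DNMT3A	PHD	536	589
DNMT3A	MTase	638	908
TET2	BOX1	1104	1478
TET2	BOX2	1845	2002
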