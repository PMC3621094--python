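motif_id	gene	ref_start	pattern	key_positions
MHR	gag	260	KEPFQSYVDRFL	0,4,8,9
zinc_knuckle_1	gag	380	CAYCKEKGHWAKDC	0,3,8,13
zinc_knuckle_2	gag	401	CAYCKEKGHWAKDC	0,3,8,13
dUTPase_1	pro	20	AGLDL	0,1,3
dUTPase_2	pro	50	SGLAAK	0,1
dUTPase_3	pro	80	GVIDSDYRGEIK	0,3,5
dUTPase_4	pro	110	VAQLIV	0,1
dUTPase_5	pro	140	RGSGGFGSTG	0,5,9
protease_DxG	pro	180	LLDTGADDTV	2,4
RT_DDD	pol	200	KVDDDLLI	2,3,4
IN_DDE	pol	650	SADGSDPQSREL	2,5,10
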