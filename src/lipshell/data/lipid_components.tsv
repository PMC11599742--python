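code	lipid_class	display_name	source
22B	linear_acyl	long-chain alkane fragment	paper_list
97N	linear_acyl	alkyl chain fragment	paper_list
ARC	archaeal_diphytanyl	diphytanyl glycerophosphoglycerol (archaeal PG)	paper_list
C14	linear_acyl	tetradecane	paper_list
CPS	detergent	CHAPS	paper_list
D10	linear_acyl	decane	paper_list
D12	linear_acyl	dodecane	paper_list
DAO	linear_acyl	lauryl (dodecyl) chain	paper_list
DD9	linear_acyl	nonyl chain fragment	paper_list
DPG	linear_acyl	diacyl glycerophosphoglycerol fragment	paper_list
GLC	sugar_headgroup_fragment	alpha-D-glucopyranose	paper_list
GOL	small_amphiphile_or_cryo	glycerol	paper_list
HEX	linear_acyl	hexane	paper_list
HP6	linear_acyl	heptane	paper_list
L2P	archaeal_diphytanyl	diphytanyl glycolipid core (S-TGA-1)	paper_list
L3P	archaeal_diphytanyl	diphytanyl glycerol fragment	paper_list
L4P	archaeal_diphytanyl	diphytanyl ether lipid fragment	paper_list
LFA	linear_acyl	eicosane (long fatty alkane)	paper_list
LI1	linear_acyl	linear alkyl lipid fragment	paper_list
MAN	sugar_headgroup_fragment	alpha-D-mannopyranose	paper_list
MPG	linear_acyl	monoacylglycerol (host lipid)	paper_list
MYS	linear_acyl	myristyl chain	paper_list
NAG	sugar_headgroup_fragment	N-acetyl-D-glucosamine	paper_list
OCT	linear_acyl	n-octane	paper_list
OLA	linear_acyl	oleic acid	paper_list
OLB	linear_acyl	2,3-dihydroxypropyl oleate (monoolein isomer)	paper_list
OLC	linear_acyl	monoolein (1-oleoyl-R-glycerol)	paper_list
PCA	small_amphiphile_or_cryo	pyroglutamic acid	paper_list
PCW	linear_acyl	phosphatidylcholine (diacyl)	paper_list
PH1	archaeal_diphytanyl	phytanyl chain	paper_list
PLM	linear_acyl	palmitic acid	paper_list
PX4	linear_acyl	dimyristoyl phosphatidylcholine	paper_list
R16	linear_acyl	hexadecane	paper_list
SGA	sugar_headgroup_fragment	sulfoglycoside sugar fragment	paper_list
SQL	isoprenoid_squalene	squalene (alternate code)	paper_list
SQU	isoprenoid_squalene	squalene	paper_list
SXN	carotenoid	salinixanthin	paper_list
TRD	linear_acyl	tridecane	paper_list
UND	linear_acyl	undecane	paper_list
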