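# Polymorphic sites in the 535 bp partial 16S rRNA alignment: 14 haplotypes
# observed in 20 pronghorn spiny lobster individuals from eight Pacific
# localities. Dot = identical to the reference (Type 1), dash = gap, blank
# count = 0. The source prints site coordinates as vertical digit columns
# ("x2222222222223334" / "20344445578882694" / "83901573651692830"); the
# first digit is illegible in the source, so positions are not transcribed
# and play no role in any computation.
#length: 535
type	pattern	EP	GA	MT	TPP	HC	IN	NC	FPP
1	TGTGGTATGGATG-TTT			1
2	............A-...				1			1
3	............A-..C					1
4	............A-C..					1	1
5	..........T.A-...				1
6	..........T.A-C..						1
7	.........A..A-...								1
8	..C.........A-...								1
9	.AA.........A-C..				1
10	...A....T...A-...							1
11	C....C......A-..C						1
12	....A....A.CAT.C.	1	4
13	....A..C.A.CAT.C.	1
14	....A.G..A.CAT.C.		1
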