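# Synthetic stand-in genomic codon-usage table for E. coli.
# Counts are published whole-genome usage frequencies (per-mille) scaled by
# 10 and rounded; they approximate, but were not counted from, the study
# strain's annotation. Codons in coding-strand orientation; stops excluded.
codon	count
TTT	223
TTC	166
TTA	139
TTG	137
CTT	110
CTC	110
CTA	39
CTG	526
ATT	303
ATC	251
ATA	44
ATG	279
GTT	183
GTC	153
GTA	109
GTG	264
TCT	85
TCC	86
TCA	72
TCG	89
CCT	70
CCC	55
CCA	84
CCG	232
ACT	90
ACC	234
ACA	71
ACG	144
GCT	153
GCC	255
GCA	201
GCG	336
TAT	162
TAC	122
CAT	129
CAC	97
CAA	153
CAG	288
AAT	177
AAC	217
AAA	336
AAG	103
GAT	321
GAC	191
GAA	394
GAG	178
TGT	52
TGC	64
TGG	152
CGT	209
CGC	220
CGA	36
CGG	54
AGT	88
AGC	161
AGA	21
AGG	12
GGT	247
GGC	296
GGA	80
GGG	111
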