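codon	weight
AAA	1.0
AAC	2.0
AAG	2.0
AAT	1.0
ACA	1.0
ACC	2.0
ACG	2.0
ACT	1.0
AGA	1.0
AGC	2.0
AGG	2.0
AGT	1.0
ATA	1.0
ATC	2.0
ATG	1.5
ATT	1.0
CAA	1.0
CAC	2.0
CAG	2.0
CAT	1.0
CCA	1.0
CCC	2.0
CCG	2.0
CCT	1.0
CGA	1.0
CGC	2.0
CGG	2.0
CGT	1.0
CTA	1.0
CTC	2.0
CTG	2.0
CTT	1.0
GAA	1.0
GAC	2.0
GAG	2.0
GAT	1.0
GCA	1.0
GCC	2.0
GCG	2.0
GCT	1.0
GGA	1.0
GGC	2.0
GGG	2.0
GGT	1.0
GTA	1.0
GTC	2.0
GTG	2.0
GTT	1.0
TAC	2.0
TAT	1.0
TCA	1.0
TCC	2.0
TCG	2.0
TCT	1.0
TGC	2.0
TGG	2.0
TGT	1.0
TTA	1.0
TTC	2.0
TTG	2.0
TTT	1.0
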