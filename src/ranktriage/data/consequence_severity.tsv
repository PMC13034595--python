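# VEP-style consequence severity table: rank 0 is most severe.
rank	consequence	impact
0	transcript_ablation	HIGH
1	splice_acceptor_variant	HIGH
2	splice_donor_variant	HIGH
3	stop_gained	HIGH
4	frameshift_variant	HIGH
5	stop_lost	HIGH
6	start_lost	HIGH
7	transcript_amplification	HIGH
8	inframe_insertion	MODERATE
9	inframe_deletion	MODERATE
10	missense_variant	MODERATE
11	protein_altering_variant	MODERATE
12	splice_region_variant	LOW
13	incomplete_terminal_codon_variant	LOW
14	start_retained_variant	LOW
15	stop_retained_variant	LOW
16	synonymous_variant	LOW
17	coding_sequence_variant	MODIFIER
18	mature_miRNA_variant	MODIFIER
19	5_prime_UTR_variant	MODIFIER
20	3_prime_UTR_variant	MODIFIER
21	non_coding_transcript_exon_variant	MODIFIER
22	intron_variant	MODIFIER
23	upstream_gene_variant	MODIFIER
24	downstream_gene_variant	MODIFIER
25	regulatory_region_variant	MODIFIER
26	intergenic_variant	MODIFIER
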