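# Editable STR locus threshold configuration.
#
# Thresholds are ILLUSTRATIVE DEFAULTS for common disease loci, intended
# as a starting point only: clinical repeat-class boundaries are site
# policy and must be reviewed and versioned locally before diagnostic use.
# Boundaries are inclusive at each *_max (count == normal_max is normal).

[[locus]]
locus_id = "HTT_CAG"
gene = "HTT"
repeat_unit = "CAG"
normal_max = 26
intermediate_max = 35
premutation_max = 39    # reduced-penetrance range; >39 = full

[[locus]]
locus_id = "FMR1_CGG"
gene = "FMR1"
repeat_unit = "CGG"
normal_max = 44
intermediate_max = 54
premutation_max = 200

[[locus]]
locus_id = "DMPK_CTG"
gene = "DMPK"
repeat_unit = "CTG"
normal_max = 34
intermediate_max = 34   # no intermediate zone defined at this locus
premutation_max = 49

[[locus]]
locus_id = "ATXN2_CAG"
gene = "ATXN2"
repeat_unit = "CAG"
normal_max = 31
intermediate_max = 31
premutation_max = 32
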