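# Default rank model, version "default-1".
#
# An ordered list of scoring categories; within a category the first
# matching rule wins and the mandatory `fallback` applies when none match.
# Scores are additive across categories.  `when` conditions must all hold;
# absent annotation values satisfy only the `absent` operator, so no rule
# ever fires on imputed data.
#
# Category intent:
#   frequency       rarer is better; common variants score heavily negative.
#                   `clinvar_rescue` lifts negative scores to 0 for ClinVar
#                   P/LP variants with >=1 review star, so a known
#                   pathogenic but locally common variant is never buried.
#   consequence     predicted functional impact class (VEP-style).
#   deleteriousness CADD (PHRED-scaled) bins.
#   clinvar         assertion strength; benign assertions score negative.
#   inheritance     compatibility with a monogenic model; confirmed de novo
#                   scores highest.  Dominant models deliberately score
#                   above zero so heterozygous hits in dominant genes are
#                   not structurally under-ranked.
#   splicing        SpliceAI delta-score bins.
#   compound        filled by compound-pair scoring, fallback elsewhere.

version = "default-1"

[[category]]
name = "frequency"
fallback = 4        # absent frequency = never observed = novel
min = -12
max = 4
clinvar_rescue = true

[[category.rule]]
id = "af_common"
score = -12
when = [{ field = "gnomad_af", op = "ge", value = 0.05 }]

[[category.rule]]
id = "af_above_1pct"
score = -10
when = [{ field = "gnomad_af", op = "ge", value = 0.01 }]

[[category.rule]]
id = "af_sub_1pct"
score = 1
when = [{ field = "gnomad_af", op = "ge", value = 0.005 }]

[[category.rule]]
id = "af_sub_half_pct"
score = 2
when = [{ field = "gnomad_af", op = "ge", value = 0.001 }]

[[category.rule]]
id = "af_rare"
score = 3
when = [{ field = "gnomad_af", op = "ge", value = 0.0001 }]

[[category.rule]]
id = "af_ultra_rare"
score = 4
when = [{ field = "gnomad_af", op = "lt", value = 0.0001 }]

[[category]]
name = "consequence"
fallback = 0
min = 0
max = 8

[[category.rule]]
id = "impact_high"
score = 8
when = [{ field = "impact", op = "eq", value = "HIGH" }]

[[category.rule]]
id = "impact_moderate"
score = 5
when = [{ field = "impact", op = "eq", value = "MODERATE" }]

[[category.rule]]
id = "impact_low"
score = 1
when = [{ field = "impact", op = "eq", value = "LOW" }]

[[category]]
name = "deleteriousness"
fallback = 0
min = 0
max = 3

[[category.rule]]
id = "cadd_ge_30"
score = 3
when = [{ field = "cadd_phred", op = "ge", value = 30.0 }]

[[category.rule]]
id = "cadd_ge_20"
score = 2
when = [{ field = "cadd_phred", op = "ge", value = 20.0 }]

[[category.rule]]
id = "cadd_ge_10"
score = 1
when = [{ field = "cadd_phred", op = "ge", value = 10.0 }]

[[category]]
name = "clinvar"
fallback = 0
min = -4
max = 8

[[category.rule]]
id = "clinvar_p_starred"
score = 8
when = [
    { field = "clinvar_sig", op = "eq", value = "P" },
    { field = "clinvar_stars", op = "ge", value = 1 },
]

[[category.rule]]
id = "clinvar_lp_starred"
score = 6
when = [
    { field = "clinvar_sig", op = "eq", value = "LP" },
    { field = "clinvar_stars", op = "ge", value = 1 },
]

[[category.rule]]
id = "clinvar_plp_unstarred"
score = 5
when = [{ field = "clinvar_sig", op = "in", value = ["P", "LP"] }]

[[category.rule]]
id = "clinvar_lb"
score = -2
when = [{ field = "clinvar_sig", op = "eq", value = "LB" }]

[[category.rule]]
id = "clinvar_b"
score = -4
when = [{ field = "clinvar_sig", op = "eq", value = "B" }]

[[category]]
name = "inheritance"
fallback = -2       # genotypes contradict every monogenic hypothesis
min = -2
max = 5

[[category.rule]]
id = "model_denovo"
score = 5
when = [{ field = "models", op = "contains_any", value = ["AD_dn", "AR_hom_dn", "XD_dn", "XR_dn"] }]

[[category.rule]]
id = "model_recessive"
score = 3
when = [{ field = "models", op = "contains_any", value = ["AR_hom", "AR_comp", "XR"] }]

[[category.rule]]
id = "model_dominant"
score = 2
when = [{ field = "models", op = "contains_any", value = ["AD", "XD"] }]

[[category]]
name = "splicing"
fallback = 0
min = 0
max = 4

[[category.rule]]
id = "spliceai_high"
score = 4
when = [{ field = "spliceai_max", op = "ge", value = 0.8 }]

[[category.rule]]
id = "spliceai_mid"
score = 3
when = [{ field = "spliceai_max", op = "ge", value = 0.5 }]

[[category.rule]]
id = "spliceai_low"
score = 1
when = [{ field = "spliceai_max", op = "ge", value = 0.2 }]

[[category]]
name = "compound"
fallback = 0
min = 0
max = 8

[compound]
category = "compound"
partner_threshold = 10
full_bonus = 8
partial_bonus = 2
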