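# Methods

This note documents the models and rules implemented in `ranktriage`,
the parameters that matter, the numerical conventions, and what the
synthetic test conditions do and do not establish.

## Scope and assumptions

The package operates strictly downstream of variant calling and
annotation: it consumes a multi-sample VCF whose INFO fields already
carry population frequencies (gnomAD-style AF / allele count /
homozygote count, local SV frequency), a most-severe consequence term,
ClinVar significance and review stars, CADD, REVEL and SpliceAI scores,
and a signed distance to the nearest exon boundary. It never computes
annotations, never imputes an absent one, and treats each decomposed
(site, alt) pair as an independent variant. Multi-allelic sites are
split before any rule runs; in the per-allele view, other alternate
alleles read as reference — each candidate allele is judged on its own.
Coordinates are 1-based VCF conventions; SV END is taken from the
record, never recomputed.

Absent annotations are handled rule by rule, always in the direction of
clinical sensitivity: an absent population frequency means "never
observed" and therefore rare (it can pass the frequency filter and takes
the top frequency score); absent counts never trigger a discard; an
absent CADD or SpliceAI score simply contributes the category fallback.

## Rank model

The rank score is a sum of per-category integer scores. Categories,
their rules, score bounds and mandatory fallbacks live in a versioned
TOML file; the engine hard-codes nothing, mirroring how a clinical lab
versions its production scoring over time. Within a category the first
matching rule wins; a rule's conditions must all hold; absent values
satisfy only the `absent` operator, so no comparison ever fires on
imputed data.

The shipped `default-1` model scores:

| category        | range     | highest rule                          |
|-----------------|-----------|---------------------------------------|
| frequency       | −12 … 4   | AF < 1e-4 or absent → 4; AF ≥ 5% → −12 |
| consequence     | 0 … 8     | HIGH impact → 8, MODERATE → 5, LOW → 1 |
| deleteriousness | 0 … 3     | CADD ≥ 30 → 3, ≥ 20 → 2, ≥ 10 → 1      |
| clinvar         | −4 … 8    | P ≥ 1★ → 8, LP ≥ 1★ → 6, P/LP 0★ → 5, LB → −2, B → −4 |
| inheritance     | −2 … 5    | confirmed de novo → 5, recessive (hom/compound/XR) → 3, dominant → 2, no compatible model → −2 |
| splicing        | 0 … 4     | SpliceAI ≥ 0.8 → 4, ≥ 0.5 → 3, ≥ 0.2 → 1 |
| compound        | 0 … 8     | filled by compound-pair scoring        |

Design choices worth naming:

- **Dominant models score above zero.** Rank models tuned for recessive
  disease historically under-rank heterozygous hits in dominant genes
  when no second allele exists; `default-1` deliberately gives AD/XD a
  positive inheritance score so a lone dominant candidate is not
  structurally buried.
- **Known-pathogenic retention at scoring level.** A category can be
  flagged `clinvar_rescue`: its negative scores are lifted to 0 for
  ClinVar P/LP variants with ≥ 1 review star. `default-1` flags the
  frequency category, so a known pathogenic but locally common variant
  (e.g. a founder allele) is neither filtered out nor buried by a
  frequency penalty — the scoring-level counterpart of the filter-level
  unconditional retention.
- **Monotonicity.** Under `default-1`, replacing one annotation by a
  strictly more damaging value (lower AF bin, severer impact, higher
  CADD bin, stronger ClinVar assertion) never decreases the total; this
  is property-tested over the full annotation lattice.

### Compound-pair scoring

Compound-heterozygote candidates are found per gene (see below); each
paired variant's compound category is set to a step function of the
*minimum* of its partners' pre-compound totals: the full bonus (8) when
the weakest partner reaches the partner threshold (10), otherwise a
partial bonus (2). The min-based form — rather than mean or a
penalty-below-threshold — was chosen because a compound-het hypothesis
is only as credible as its weaker allele; the rule is isolated behind
`CompoundBonusRule` so sites can swap it. Paired variants also gain the
AR_comp genetic model and have their inheritance category re-evaluated
(pre-compound totals are taken before this, so the bonus input is
unambiguous). One consequence of the min rule: for a variant with three
or more partners, removing its weakest partner can *raise* its bonus;
for ordinary two-member pairs, removing the partner always drops the
variant back to the category fallback.

### Ranking

Variants are ordered by descending total; ties break on (contig order,
position, ref, alt), giving byte-identical output across runs. Rank
positions are dense and unique (1..n) even among tied totals, matching
how a reviewer walks an ordered list.

## Inheritance-model annotation

Models are *exclusion-based*: a variant is annotated with every model
the observed genotypes do not contradict. Missing genotypes are
permissive — an ungenotyped relative can never remove a model —
with one deliberate exception: the de novo refinements positively
require both parents of an affected carrier to be present and genotyped
homozygous-reference (an unproven de novo is not reported as one). On
the X chromosome males are hemizygous and a son's X comes from his
mother, so only the mother's genotype is required to confirm a male de
novo; pseudoautosomal intervals (GRCh38 defaults, configurable) are
treated as autosomal. Penetrance is not modeled; a `relaxed` flag
permits unaffected carriers for the dominant models as a
reduced-penetrance escape hatch. Unaffected siblings exclude dominant
candidates by default (same escape hatch applies). Multigenerational
dominant inheritance is plain AD over an arbitrary pedigree — the
predicate is identical, so no separate model name exists.

Compound-het pairing considers all variant pairs sharing a gene: every
affected member must be heterozygous for both; where parental genotypes
phase both variants, the pair must be in trans (one maternal/one
paternal, or one inherited/one de novo — two de novo variants cannot be
shown trans and are excluded); a pair an unaffected member demonstrably
carries in trans is excluded. Without usable parental data any het/het
pair stands, flagged unphased.

## Filters

All four filter stages emit per-variant decisions with rule ids, so any
stage ordering can be audited; the pipeline runs panel → splice
assessment → clinical → frequency discard, and the clinical and panel
filters commute (they inspect disjoint fields). Numerical conventions:

- The 1% frequency cutoff is strict (`< 0.01`): a variant at exactly 1%
  is removed. Configurable via `af_cutoff`.
- "More than five" is strict the other way: gnomAD allele count 5 is
  retained, 6 discarded (dominant pediatric mode); likewise homozygote
  counts (recessive mode). Mixed-mode panels use the laxer recessive
  rule.
- The splice window is ±20 bp; `distance_to_exon` 0 means exonic, and an
  unannotated distance never causes removal.
- The small-panel rescue applies to panels of ≤ 2 genes and intronic
  variants with gnomAD AF **< 0.001** (absent counts as rare). The
  source description of this rule prints the inequality in the opposite
  direction while calling the variants "rare"; the direction is
  internally contradictory as printed, and this package implements the
  rare (<) reading rather than guessing silently.
- The SV threshold is applied to the *frequency* in the local SV
  database (the count-vs-frequency reading is ambiguous at the source;
  frequency chosen).

## STR classification

Repeat-count estimates are binned per locus: normal iff count ≤
`normal_max`, intermediate iff ≤ `intermediate_max`, premutation iff ≤
`premutation_max`, full otherwise — inclusive at every boundary, a
documented convention since per-locus boundary semantics are site
policy. Equal consecutive thresholds collapse a zone (e.g. loci with no
defined intermediate range). Premutation and full calls set
`requires_confirmation`; short-read WGS sizing is always marked
estimate-only because clinically reportable expansions must be sized by
PCR fragment analysis or Southern blot. The shipped locus file contains
illustrative thresholds for HTT, FMR1, DMPK and ATXN2 and must be
reviewed locally before any diagnostic use.

## Benchmark harness

For each solved case the harness applies panel filter → clinical filter
→ scoring → ranking and reports the causative variant's rank among the
survivors (ranking within the clinical-filter survivor list, since that
is the list a reviewer actually walks). A truth variant missing from the
VCF or removed by a filter is reported as `not_found` with the removing
rule id — never silently dropped, never imputed as a worst rank. The
frequency-discard stage is not part of the benchmark path.

`summarize_ranks` reports: fraction at rank 1; median; mean; SD (n−1
denominator); a 95% CI half-width of 1.96·SD/√n (the convention is
self-consistent with reporting "±0.3" for SD 8.3 at n ≈ 3,000); the
fraction of ranks strictly greater than the cutoff (default 50, the
approximate limit of routine manual review); and the maximum. The
"below cutoff" direction reads rank position numerically greater than
the cutoff, i.e. listed further down the page.

## Synthetic cohorts

The generator produces what the pipeline consumes — annotated VCF + PED
+ panel + truth table — with no sequence content, no linkage structure
and no real gene models. Background annotations are drawn independently
per variant from categorical/binned distributions chosen to look like a
panel-region callset: 10% of variants carry no population frequency,
the rest follow log-uniform bins from 1e-5 to 0.5 (60% of the mass
below the 1% clinical cutoff); 2% HIGH / 30% MODERATE impact with
consequence terms drawn consistently with the impact class; CADD bins
with 3% above 30; ClinVar assertions on 2.5% of variants (0.2% P/LP);
SpliceAI present on 40%. gnomAD counts are derived from AF at a
gnomAD-v2-like allele number of 250,000 (AC = AF·AN, homozygotes from
Hardy-Weinberg), so the count-based discard rules engage realistically.

Genotypes follow a Mendelian transmission model: parents are
Hardy-Weinberg draws at a within-family carrier frequency of 0.25
(family VCFs only contain sites called in the family, so the generator
conditions on at least one carrier), children inherit one random allele
per parent, and a per-variant de novo probability of 0.001 injects
parents-reference/child-het sites (~0.5 per 500-variant case). Each
case spikes exactly one causative variant (two, in trans, for the
compound-recessive model) with genotypes satisfying the configured
model and a pathogenic-like annotation profile: AF absent or < 1e-4,
HIGH impact with probability 0.8 (else MODERATE missense), CADD 25–40,
ClinVar P with two stars with probability 0.7. By construction the
spike always survives the clinical filter, so a benchmark miss
isolates a ranking defect.

Seeding: `numpy.random.default_rng([root_seed, case_index])` per case
(plus fixed extra words for the causative-gene and panel streams), so
any single case is reproducible without generating its predecessors and
cohort output is bit-identical across reruns.

**What passing the synthetic benchmark shows — and does not.** Recovery
of ≥ 95% rank-1 spikes over 200 seeded trios (500 background variants
each; sizes chosen to exercise the full pipeline at desk scale)
demonstrates that the scoring and filtering machinery orders an
unambiguous pathogenic variant above realistic background and that the
pipeline is deterministic. It does not estimate clinical sensitivity:
real cohorts contain annotation errors, missing ClinVar assertions,
dominant variants without a compound partner, coverage-compromised
regions, and phenotype-panel mismatches, all of which the generator
deliberately omits. Published rank-distribution figures from clinical
cohorts (e.g. 35% rank 1, median 2, SD 8.3 over ~3,000 variants) are
schema examples for the benchmark output, not reproduction targets.

## Known limitations

- No statistical or read-backed phasing; trans configurations are
  demonstrable only through parental genotypes.
- No imprinting, uniparental-disomy or mitochondrial inheritance
  models.
- Per-gene frequency thresholds beyond the two printed modes, and
  historical rank-model reconstruction, are out of scope.
- The rule engine evaluates conjunctions only; a category needing
  disjunction must spell out one rule per branch.
- STR records flow through the SV frequency rule in the clinical
  filter; locus-specific repeat interpretation happens only in the STR
  classifier.
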