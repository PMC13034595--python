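"""Seeded synthetic annotated cohorts: trio genotypes, spiked causatives.

The generator emulates what the triage pipeline actually consumes — an
annotated family VCF plus PED — without any sequence content.  Background
variants draw annotations from configurable categorical/binned
distributions (population frequency with a point mass at "absent",
impact-stratified consequence terms, CADD bins, ClinVar status, SpliceAI)
and genotypes from a Mendelian transmission model: parental genotypes are
Hardy-Weinberg draws at a family carrier frequency, child alleles are
random parental transmissions, and a configured per-variant de novo rate
injects parents-reference / child-het sites.  Each case spikes exactly
one causative variant (a trans pair for the compound-recessive model)
whose genotypes satisfy the configured inheritance model and whose
annotation profile is pathogenic-like: rare or absent frequency,
MODERATE/HIGH impact, high CADD, optionally ClinVar Pathogenic — by
construction such a spike always survives the clinical filter, so a
benchmark miss indicates ranking, not filtering.

A single root seed derives per-case generators through
``numpy.random.default_rng([seed, case_index])``, so any case is
reproducible in isolation and output is byte-identical across reruns.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .benchmark import TruthEntry
from .core import (
    AffectedStatus,
    AnnotationBundle,
    ClinvarSig,
    GenePanel,
    Genotype,
    Impact,
    Individual,
    PanelMode,
    Pedigree,
    VariantRecord,
    VarType,
    chrom_sort_key,
    variant_key,
)
from .inheritance import GeneticModel
from .io import write_pedigree, write_vcf

__all__ = ["SimConfig", "simulate_case", "simulate_cohort", "panel_for_case"]


def _categorical(rng: np.random.Generator, probs: dict) -> object:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


_HIGH_TERMS = ["stop_gained", "frameshift_variant", "splice_donor_variant", "splice_acceptor_variant"]
_MODERATE_TERMS = ["missense_variant", "inframe_deletion", "inframe_insertion"]
_LOW_TERMS = ["synonymous_variant", "splice_region_variant"]
_MODIFIER_TERMS = ["intron_variant", "5_prime_UTR_variant", "3_prime_UTR_variant"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic cohort.

    Defaults describe a realistic annotated rare-disease trio: several
    hundred panel-region variants per case, overwhelmingly benign-looking
    background, and one pathogenic-like spike consistent with the
    configured inheritance model.
    """

    seed: int = 0
    n_cases: int = 1
    variants_per_case: int = 600
    n_genes: int = 40
    panel_size: int = 20
    trio: bool = True
    causative_model: GeneticModel = GeneticModel.AD_DENOVO
    panel_mode: PanelMode = PanelMode.MIXED

    # annotation distributions (probabilities sum to 1 per categorical)
    af_absent_prob: float = 0.10
    af_bins: tuple = (
        ((1e-5, 1e-4), 0.10),
        ((1e-4, 1e-3), 0.15),
        ((1e-3, 0.01), 0.25),
        ((0.01, 0.05), 0.20),
        ((0.05, 0.5), 0.20),
    )
    impact_probs: tuple = (("HIGH", 0.02), ("MODERATE", 0.30), ("LOW", 0.28), ("MODIFIER", 0.40))
    cadd_probs: tuple = ((None, 0.25), ((0, 10), 0.35), ((10, 20), 0.25), ((20, 30), 0.12), ((30, 40), 0.03))
    clinvar_probs: tuple = (
        ("none", 0.9750),
        ("B", 0.0100),
        ("LB", 0.0060),
        ("VUS", 0.0060),
        ("conflicting", 0.0010),
        ("LP", 0.0012),
        ("P", 0.0008),
    )
    clinvar_star_probs: tuple = ((0, 0.30), (1, 0.50), (2, 0.15), (3, 0.04), (4, 0.01))
    spliceai_probs: tuple = ((None, 0.60), ((0.0, 0.2), 0.30), ((0.2, 0.5), 0.06), ((0.5, 1.0), 0.04))

    # genotype model
    family_alt_freq: float = 0.25
    denovo_rate: float = 0.001

    # causative annotation profile
    causative_impact_high_prob: float = 0.8
    causative_clinvar_p_prob: float = 0.7

    def validate(self) -> None:
        for name in ("impact_probs", "cadd_probs", "clinvar_probs", "clinvar_star_probs", "spliceai_probs"):
            total = sum(p for _, p in getattr(self, name))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
        bin_total = self.af_absent_prob + sum(p for _, p in self.af_bins)
        if abs(bin_total - 1.0) > 1e-9:
            raise ValueError(f"AF distribution sums to {bin_total}, not 1")
        denovo_models = {
            GeneticModel.AD_DENOVO,
            GeneticModel.AR_HOM_DENOVO,
            GeneticModel.XD_DENOVO,
            GeneticModel.XR_DENOVO,
        }
        parental = denovo_models | {
            GeneticModel.AR_COMP,
            GeneticModel.XR,
            GeneticModel.AD,
        }
        if not self.trio and self.causative_model in parental:
            raise ValueError(
                f"causative model {self.causative_model.value} requires trio genotypes"
            )


def _gene_locus(gene_index: int, x_linked: bool = False) -> tuple[str, int]:
    if x_linked:
        return "X", 10_000_000 + gene_index * 1_000_000
    return str((gene_index % 22) + 1), 5_000_000 + (gene_index // 22 + 1) * 3_000_000 + gene_index * 100_000

def _gene_name(i: int) -> str:
    return f"GENE{i + 1:04d}"


def _sample_af(rng: np.random.Generator, cfg: SimConfig):
    if rng.random() < cfg.af_absent_prob:
        return None
    weights = np.array([p for _, p in cfg.af_bins])
    idx = rng.choice(len(cfg.af_bins), p=weights / weights.sum())
    lo, hi = cfg.af_bins[idx][0]
    af = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return float(f"{af:.6g}")


def _sample_range(rng: np.random.Generator, choices: tuple):
    weights = np.array([p for _, p in choices])
    idx = rng.choice(len(choices), p=weights / weights.sum())
    val = choices[idx][0]
    if val is None or not isinstance(val, tuple):
        return val
    lo, hi = val
    return float(f"{rng.uniform(lo, hi):.6g}")


def _background_annotations(rng: np.random.Generator, cfg: SimConfig) -> AnnotationBundle:
    af = _sample_af(rng, cfg)
    impact = Impact(_categorical(rng, dict(cfg.impact_probs)))
    terms = {
        Impact.HIGH: _HIGH_TERMS,
        Impact.MODERATE: _MODERATE_TERMS,
        Impact.LOW: _LOW_TERMS,
        Impact.MODIFIER: _MODIFIER_TERMS,
    }[impact]
    consequence = terms[rng.integers(len(terms))]
    if consequence == "intron_variant":
        dist = int(rng.integers(1, 5000))
    elif consequence in ("splice_region_variant", "splice_donor_variant", "splice_acceptor_variant"):
        dist = int(rng.integers(1, 9))
    else:
        dist = 0
    sig = ClinvarSig(_categorical(rng, dict(cfg.clinvar_probs)))
    stars = (
        int(_categorical(rng, dict(cfg.clinvar_star_probs)))
        if sig is not ClinvarSig.NONE
        else 0
    )
    cadd = _sample_range(rng, cfg.cadd_probs)
    spliceai = _sample_range(rng, cfg.spliceai_probs)
    an = 250_000  # gnomAD-v2-like allele number for derived counts
    return AnnotationBundle(
        consequence=consequence,
        impact=impact,
        gnomad_af=af,
        gnomad_ac=None if af is None else max(1, round(af * an)),
        gnomad_nhomalt=None if af is None else round(af * af * an / 2),
        clinvar_sig=sig,
        clinvar_stars=stars,
        cadd_phred=cadd,
        spliceai_max=spliceai,
        distance_to_exon=dist,
    )


_BASES = ["A", "C", "G", "T"]


def _alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


def _hwe_genotype(rng: np.random.Generator, f: float) -> Genotype:
    n_alt = int(rng.binomial(2, f))
    alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[n_alt]
    return Genotype(alleles=alleles)


def _transmit(rng: np.random.Generator, parent: Genotype) -> int:
    return int(parent.alleles[rng.integers(2)])


def _background_genotypes(
    rng: np.random.Generator, cfg: SimConfig, sample_ids: list[str]
) -> dict[str, Genotype]:
    """Mendelian-consistent trio (or singleton) genotypes; resampled until
    at least one family member carries the alt (a called variant must be
    present in somebody)."""
    if len(sample_ids) == 1:
        for _ in range(50):
            gt = _hwe_genotype(rng, cfg.family_alt_freq)
            if gt.carries_alt:
                return {sample_ids[0]: gt}
        return {sample_ids[0]: Genotype(alleles=(0, 1))}
    child, father, mother = sample_ids
    if rng.random() < cfg.denovo_rate:
        return {
            child: Genotype(alleles=(0, 1)),
            father: Genotype(alleles=(0, 0)),
            mother: Genotype(alleles=(0, 0)),
        }
    for _ in range(50):
        fg = _hwe_genotype(rng, cfg.family_alt_freq)
        mg = _hwe_genotype(rng, cfg.family_alt_freq)
        cg = Genotype(alleles=(_transmit(rng, fg), _transmit(rng, mg)))
        if fg.carries_alt or mg.carries_alt or cg.carries_alt:
            return {child: cg, father: fg, mother: mg}
    return {
        child: Genotype(alleles=(0, 1)),
        father: Genotype(alleles=(0, 1)),
        mother: Genotype(alleles=(0, 0)),
    }


def _causative_annotations(rng: np.random.Generator, cfg: SimConfig) -> AnnotationBundle:
    high = rng.random() < cfg.causative_impact_high_prob
    consequence = "stop_gained" if high else "missense_variant"
    clinvar_p = rng.random() < cfg.causative_clinvar_p_prob
    af = None if rng.random() < 0.5 else float(f"{np.exp(rng.uniform(np.log(1e-6), np.log(1e-4))):.6g}")
    return AnnotationBundle(
        consequence=consequence,
        impact=Impact.HIGH if high else Impact.MODERATE,
        gnomad_af=af,
        gnomad_ac=None if af is None else max(1, round(af * 250_000)),
        gnomad_nhomalt=None if af is None else 0,
        clinvar_sig=ClinvarSig.P if clinvar_p else ClinvarSig.NONE,
        clinvar_stars=2 if clinvar_p else 0,
        cadd_phred=float(f"{rng.uniform(25, 40):.6g}"),
        distance_to_exon=0,
    )


def _causative_genotype_sets(
    model: GeneticModel, sample_ids: list[str]
) -> list[dict[str, Genotype]]:
    """Genotype maps (one per spiked variant) satisfying the model."""
    het = Genotype(alleles=(0, 1))
    hom = Genotype(alleles=(1, 1))
    ref = Genotype(alleles=(0, 0))
    hemi_alt = Genotype(alleles=(1, None), hemizygous=True)
    hemi_ref = Genotype(alleles=(0, None), hemizygous=True)
    if len(sample_ids) == 1:
        (child,) = sample_ids
        if model in (GeneticModel.AR_HOM,):
            return [{child: hom}]
        return [{child: het}]
    child, father, mother = sample_ids
    if model is GeneticModel.AR_HOM:
        return [{child: hom, father: het, mother: het}]
    if model is GeneticModel.AD_DENOVO:
        return [{child: het, father: ref, mother: ref}]
    if model is GeneticModel.AD:
        # inherited dominant: transmitting parent is affected too
        return [{child: het, father: het, mother: ref}]
    if model is GeneticModel.AR_COMP:
        return [
            {child: het, father: het, mother: ref},
            {child: het, father: ref, mother: het},
        ]
    if model is GeneticModel.XR:
        return [{child: hemi_alt, father: hemi_ref, mother: het}]
    if model is GeneticModel.XD_DENOVO:
        return [{child: het, father: hemi_ref, mother: ref}]
    raise ValueError(f"unsupported causative model: {model.value}")


def _make_pedigree(cfg: SimConfig, case_id: str, model: GeneticModel, rng) -> Pedigree:
    from .core import Sex

    if model in (GeneticModel.XR,):
        child_sex = Sex.MALE
    elif model in (GeneticModel.XD_DENOVO,):
        child_sex = Sex.FEMALE
    else:
        child_sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
    child = Individual(
        id=f"{case_id}-proband",
        father_id=f"{case_id}-father" if cfg.trio else None,
        mother_id=f"{case_id}-mother" if cfg.trio else None,
        sex=child_sex,
        status=AffectedStatus.AFFECTED,
    )
    if not cfg.trio:
        return Pedigree(family_id=case_id, members=[child])
    father_status = (
        AffectedStatus.AFFECTED if model is GeneticModel.AD else AffectedStatus.UNAFFECTED
    )
    father = Individual(id=f"{case_id}-father", sex=Sex.MALE, status=father_status)
    mother = Individual(id=f"{case_id}-mother", sex=Sex.FEMALE, status=AffectedStatus.UNAFFECTED)
    return Pedigree(family_id=case_id, members=[child, father, mother])


def simulate_case(
    config: SimConfig, case_index: int
) -> tuple[list[VariantRecord], Pedigree, TruthEntry]:
    """Generate one annotated case: background + spiked causative variant(s)."""
    config.validate()
    rng = np.random.default_rng([config.seed, case_index])
    case_id = f"CASE{case_index:04d}"
    pedigree = _make_pedigree(config, case_id, config.causative_model, rng)
    sample_ids = [m.id for m in pedigree.members]

    x_model = config.causative_model in (GeneticModel.XR, GeneticModel.XD_DENOVO)
    causative_gene_idx = _causative_gene_index(config, case_index)
    variants: list[VariantRecord] = []
    for i in range(config.variants_per_case):
        gene_idx = int(rng.integers(config.n_genes))
        chrom, base = _gene_locus(gene_idx)
        ref, alt = _alleles(rng)
        ann = _background_annotations(rng, cfg=config)
        variants.append(
            VariantRecord(
                chrom=chrom,
                pos=base + int(rng.integers(1, 90_000)),
                ref=ref,
                alt=alt,
                var_type=VarType.SNV,
                gene_ids={_gene_name(gene_idx)},
                annotations=ann,
                genotypes=_background_genotypes(rng, config, sample_ids),
            )
        )

    chrom, base = _gene_locus(causative_gene_idx, x_linked=x_model)
    truth_keys = []
    for j, genotypes in enumerate(
        _causative_genotype_sets(config.causative_model, sample_ids)
    ):
        ref, alt = _alleles(rng)
        spike = VariantRecord(
            chrom=chrom,
            pos=base + 95_000 + j * 13,
            ref=ref,
            alt=alt,
            var_type=VarType.SNV,
            gene_ids={_gene_name(causative_gene_idx)},
            annotations=_causative_annotations(rng, config),
            genotypes=genotypes,
        )
        truth_keys.append(variant_key(spike))
        variants.append(spike)

    variants.sort(key=lambda v: (chrom_sort_key(v.chrom), v.pos, v.ref, v.alt))
    truth = TruthEntry(
        case_id=case_id,
        variant_keys=tuple(truth_keys),
        panel_name=f"{case_id}-panel",
        mode=config.panel_mode.value,
    )
    return variants, pedigree, truth


def _causative_gene_index(config: SimConfig, case_index: int) -> int:
    # dedicated stream so the causative gene is recoverable without
    # replaying the case's background draws
    return int(np.random.default_rng([config.seed, case_index, 3]).integers(config.n_genes))


def panel_for_case(config: SimConfig, case_index: int) -> GenePanel:
    """The per-case in-silico panel: the causative gene plus a random draw
    of background genes (same derived seed as the case itself)."""
    case_id = f"CASE{case_index:04d}"
    causative_gene_idx = _causative_gene_index(config, case_index)
    others = [i for i in range(config.n_genes) if i != causative_gene_idx]
    rng2 = np.random.default_rng([config.seed, case_index, 7])
    extra = rng2.choice(len(others), size=min(config.panel_size - 1, len(others)), replace=False)
    genes = {_gene_name(causative_gene_idx)} | {_gene_name(others[i]) for i in extra}
    return GenePanel(
        name=f"{case_id}-panel",
        version="sim-1",
        genes=genes,
        mode=config.panel_mode,
    )


def simulate_cohort(
    config: SimConfig, outdir: str | Path, force: bool = False
) -> dict:
    """Write n_cases cases (VCF + PED + panel TSV), a truth table and a
    manifest with per-file checksums.  Refuses a non-empty output
    directory unless ``force``."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"output directory {outdir} is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)
    truth_lines = ["case_id\tvariant_keys\tpanel\tmode"]
    files: dict[str, str] = {}
    for i in range(config.n_cases):
        variants, pedigree, truth = simulate_case(config, i)
        panel = panel_for_case(config, i)
        vcf_path = outdir / f"{truth.case_id}.vcf"
        ped_path = outdir / f"{truth.case_id}.ped"
        panel_path = outdir / f"{truth.case_id}.panel.tsv"
        write_vcf(variants, [m.id for m in pedigree.members], vcf_path)
        write_pedigree(pedigree, ped_path)
        panel_path.write_text(
            f"#name={panel.name}\n#version={panel.version}\n#mode={panel.mode.value}\n"
            + "\n".join(sorted(panel.genes))
            + "\n"
        )
        truth_lines.append(
            f"{truth.case_id}\t{','.join(truth.variant_keys)}\t{truth.panel_name}\t{truth.mode}"
        )
        for p in (vcf_path, ped_path, panel_path):
            files[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    truth_path = outdir / "truth.tsv"
    truth_path.write_text("\n".join(truth_lines) + "\n")
    files[truth_path.name] = hashlib.sha256(truth_path.read_bytes()).hexdigest()
    manifest = {
        "seed": config.seed,
        "n_cases": config.n_cases,
        "variants_per_case": config.variants_per_case,
        "causative_model": config.causative_model.value,
        "files": dict(sorted(files.items())),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
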