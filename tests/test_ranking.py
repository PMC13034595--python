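"""Rank-model parsing, category scoring, compound adjustment, ranking."""

from __future__ import annotations

import itertools
import random

import pytest

from ranktriage.inheritance import GeneticModel as GM
from ranktriage.rankmodel import (
    CategoryConfig,
    CompoundBonusRule,
    RankModelConfig,
    RankModelError,
    RuleCondition,
    ScoreRule,
    parse_rank_model,
)
from ranktriage.ranking import rank_case, score_compound_pairs, score_variant

from conftest import mkvar


def minimal_model(rules, fallback=0, min_score=-20, max_score=20,
                  threshold=10, full=8, partial=2):
    return RankModelConfig(
        version="test",
        categories=(
            CategoryConfig(name="only", rules=tuple(rules), fallback=fallback,
                           min_score=min_score, max_score=max_score),
            CategoryConfig(name="compound", rules=(), fallback=0,
                           min_score=0, max_score=8),
        ),
        compound_category="compound",
        compound_bonus=CompoundBonusRule(partner_threshold=threshold,
                                         full_bonus=full, partial_bonus=partial),
    )


class TestRankModelConfig:
    def test_shipped_default_parses_with_expected_categories(self, model):
        assert model.version == "default-1"
        assert model.category_names == [
            "frequency", "consequence", "deleteriousness", "clinvar",
            "inheritance", "splicing", "compound",
        ]

    def test_missing_version_rejected(self):
        with pytest.raises(RankModelError, match="version"):
            parse_rank_model({"category": [], "compound": {}})

    def test_rule_score_above_category_max_rejected(self):
        with pytest.raises(RankModelError, match="outside"):
            CategoryConfig(
                name="frequency",
                rules=(ScoreRule(id="r", score=99, conditions=(
                    RuleCondition("gnomad_af", "lt", 0.0001),)),),
                fallback=0, min_score=0, max_score=4,
            )

    def test_fallback_is_mandatory(self):
        from ranktriage.rankmodel import _parse_category
        with pytest.raises(RankModelError, match="fallback"):
            _parse_category({"name": "x", "min": 0, "max": 1})

    def test_category_order_matches_file_order(self, tmp_path, model):
        from ranktriage.rankmodel import load_rank_model
        p = tmp_path / "m.toml"
        p.write_text(
            'version = "v"\n'
            '[[category]]\nname = "b"\nfallback = 0\nmin = 0\nmax = 1\n'
            '[[category]]\nname = "a"\nfallback = 0\nmin = 0\nmax = 1\n'
            '[[category]]\nname = "compound"\nfallback = 0\nmin = 0\nmax = 2\n'
            '[compound]\npartner_threshold = 1\nfull_bonus = 2\npartial_bonus = 0\n'
        )
        assert load_rank_model(p).category_names == ["b", "a", "compound"]

    def test_absent_values_never_match_comparisons(self):
        cond = RuleCondition("cadd_phred", "ge", 10)
        assert not cond.evaluate(mkvar().annotations, set())


class TestScoreVariant:
    def test_single_rule_config(self):
        m = minimal_model([ScoreRule(id="high", score=5, conditions=(
            RuleCondition("impact", "eq", "HIGH"),))])
        rv = score_variant(mkvar(impact="HIGH", consequence="stop_gained"), set(), m)
        assert rv.total_score == 5 and rv.category_scores["only"] == 5

    def test_all_fallback_zero_totals_zero(self):
        m = minimal_model([], fallback=0)
        assert score_variant(mkvar(), set(), m).total_score == 0

    def test_hand_summed_total_against_shipped_config(self, model):
        """De novo HIGH-impact ClinVar-P gold-star variant, AF absent,
        CADD 35: frequency 4 + consequence 8 + deleteriousness 3 +
        clinvar 8 + inheritance 5 + splicing 0 + compound 0 = 28."""
        v = mkvar(impact="HIGH", consequence="stop_gained", clinvar_sig="P",
                  clinvar_stars=2, cadd_phred=35.0)
        rv = score_variant(v, {GM.AD, GM.AD_DENOVO}, model)
        assert rv.category_scores == {
            "frequency": 4, "consequence": 8, "deleteriousness": 3,
            "clinvar": 8, "inheritance": 5, "splicing": 0, "compound": 0,
        }
        assert rv.total_score == 28

    def test_additivity_holds_on_random_annotations(self, model):
        rng = random.Random(0)
        sigs = ["P", "LP", "VUS", "LB", "B", "none"]
        for _ in range(200):
            v = mkvar(
                gnomad_af=rng.choice([None, rng.random() * 0.2]),
                impact=rng.choice(["HIGH", "MODERATE", "LOW", "MODIFIER"]),
                cadd_phred=rng.choice([None, rng.random() * 40]),
                clinvar_sig=rng.choice(sigs),
                clinvar_stars=rng.randint(0, 4),
                spliceai_max=rng.choice([None, rng.random()]),
            )
            rv = score_variant(v, {GM.AD}, model)
            assert rv.total_score == sum(rv.category_scores.values())

    def test_starred_pathogenic_never_scores_negative_frequency(self, model):
        v = mkvar(gnomad_af=0.2, clinvar_sig="P", clinvar_stars=1)
        rv = score_variant(v, set(), model)
        assert rv.category_scores["frequency"] == 0
        assert rv.rule_ids["frequency"] == "clinvar_rescue"
        # without the star the penalty stands
        v2 = mkvar(gnomad_af=0.2, clinvar_sig="P", clinvar_stars=0)
        assert score_variant(v2, set(), model).category_scores["frequency"] == -12

    def test_category_monotonicity_over_annotation_lattice(self, model):
        """Replacing one annotation by a strictly more damaging value never
        decreases the total under the shipped config."""
        af_axis = [0.2, 0.03, 0.008, 0.003, 0.0005, 5e-5, None]
        impact_axis = ["MODIFIER", "LOW", "MODERATE", "HIGH"]
        cadd_axis = [None, 15.0, 25.0, 35.0]
        clinvar_axis = [("B", 1), ("LB", 1), ("none", 0), ("LP", 1), ("P", 1)]

        def total(af_i, im_i, ca_i, cl_i):
            sig, stars = clinvar_axis[cl_i]
            v = mkvar(gnomad_af=af_axis[af_i], impact=impact_axis[im_i],
                      cadd_phred=cadd_axis[ca_i], clinvar_sig=sig,
                      clinvar_stars=stars)
            return score_variant(v, {GM.AD}, model).total_score

        dims = (len(af_axis), len(impact_axis), len(cadd_axis), len(clinvar_axis))
        for idx in itertools.product(*(range(d) for d in dims)):
            base = total(*idx)
            for axis in range(4):
                if idx[axis] + 1 < dims[axis]:
                    step = list(idx)
                    step[axis] += 1
                    assert total(*step) >= base, (idx, axis)


class TestCompoundScoring:
    def _scored(self, model, positions_scores):
        out = []
        for pos, ann in positions_scores:
            v = mkvar(pos=pos, **ann)
            out.append(score_variant(v, {GM.AD}, model))
        return out

    def test_strong_pair_gets_full_bonus(self, model):
        strong = dict(impact="HIGH", consequence="stop_gained", cadd_phred=35.0)
        ranked = self._scored(model, [(100, strong), (200, strong)])
        pair = {frozenset({ranked[0].key, ranked[1].key})}
        updated = score_compound_pairs(ranked, pair, model)
        for rv in updated:
            assert rv.category_scores["compound"] == model.compound_bonus.full_bonus
            assert GM.AR_COMP in rv.genetic_models
            assert rv.total_score == sum(rv.category_scores.values())

    def test_unpaired_variant_unchanged(self, model):
        ranked = self._scored(model, [(100, dict(impact="HIGH", consequence="stop_gained"))])
        (updated,) = score_compound_pairs(ranked, set(), model)
        assert updated.category_scores["compound"] == 0
        assert updated.total_score == ranked[0].total_score

    def test_unknown_pair_key_rejected(self, model):
        ranked = self._scored(model, [(100, {})])
        with pytest.raises(KeyError):
            score_compound_pairs(ranked, {frozenset({ranked[0].key, "9:9:A:T"})}, model)

    def test_triangle_scored_against_min_partner_matches_bruteforce(self, model):
        anns = [dict(impact="HIGH", consequence="stop_gained", cadd_phred=35.0),
                dict(impact="MODERATE", consequence="missense_variant"),
                dict(impact="LOW", consequence="synonymous_variant", gnomad_af=0.03)]
        ranked = self._scored(model, [(100 + i, a) for i, a in enumerate(anns)])
        keys = [rv.key for rv in ranked]
        pairs = {frozenset({keys[i], keys[j]})
                 for i, j in itertools.combinations(range(3), 2)}
        updated = score_compound_pairs(ranked, pairs, model)

        # brute force: recompute each variant's compound score independently
        pre = {rv.key: rv.total_score - rv.category_scores["compound"]
               for rv in ranked}
        for rv in updated:
            partners = [k for k in keys if k != rv.key]
            expected = model.compound_bonus(min(pre[p] for p in partners))
            assert rv.category_scores["compound"] == expected
            assert rv.compound_partners == set(partners)

    def test_deleting_sole_partner_never_raises_survivor_total(self, model):
        rng = random.Random(5)
        for _ in range(50):
            anns = [dict(impact=rng.choice(["HIGH", "MODERATE", "LOW"]),
                         gnomad_af=rng.choice([None, 0.004, 0.03]))
                    for _ in range(2)]
            ranked = self._scored(model, [(100 + i, a) for i, a in enumerate(anns)])
            pair = {frozenset({ranked[0].key, ranked[1].key})}
            paired = score_compound_pairs(ranked, pair, model)
            alone = score_compound_pairs([ranked[0]], set(), model)
            assert alone[0].total_score <= paired[0].total_score


class TestRankCase:
    def test_tie_break_by_coordinate(self, model):
        anns = [(29, "1", 500), (12, "2", 100), (12, "1", 900), (3, "3", 1)]
        ranked = []
        for score, chrom, pos in anns:
            rv = score_variant(mkvar(chrom=chrom, pos=pos), set(), model)
            rv.total_score = score
            ranked.append(rv)
        out = rank_case(ranked)
        assert [rv.rank_position for rv in out] == [1, 2, 3, 4]
        assert [(rv.variant.chrom, rv.variant.pos) for rv in out] == [
            ("1", 500), ("1", 900), ("2", 100), ("3", 1)]

    def test_single_variant_is_rank_one(self, model):
        (out,) = rank_case([score_variant(mkvar(), set(), model)])
        assert out.rank_position == 1

    def test_matches_reference_stable_sort(self, model):
        rng = random.Random(11)
        ranked = []
        for i in range(100):
            rv = score_variant(
                mkvar(chrom=str(rng.randint(1, 22)), pos=rng.randint(1, 10**6)),
                set(), model)
            rv.total_score = rng.randint(-5, 30)
            ranked.append(rv)
        out = rank_case(ranked)
        from ranktriage.core import chrom_sort_key
        ref = sorted(ranked, key=lambda r: (
            -r.total_score, chrom_sort_key(r.variant.chrom), r.variant.pos,
            r.variant.ref, r.variant.alt))
        assert [r.key for r in out] == [r.key for r in ref]
        assert [r.rank_position for r in out] == list(range(1, 101))
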