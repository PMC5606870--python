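"""Precedence classification of Tier 2 variants and the REVEL layer."""

import pytest
from hypothesis import given, settings, strategies as st

from paneltriage.classify import (
    CLINVAR_2STAR,
    FREQ_BENIGN,
    INSIGHT,
    INTERNAL_RECENT,
    LIKELY_PATHOGENIC,
    NO_ANNOTATION,
    NOT_PATHOGENIC,
    PATHOGENIC,
    REVIEW_REQUIRED,
    VUS,
    AnnotationEvidence,
    apply_revel,
    classify_missense,
)
from paneltriage.config import PipelineConfig
from tests.test_tiering import make_variant

CFG = PipelineConfig()
V = make_variant()
KEY = V.variant_key


class TestPrecedence:
    def test_insight_wins_and_revel_never_consulted(self):
        # a frequent benign scenario: InSiGHT class 1 with a high REVEL score
        ev = AnnotationEvidence(KEY, insight_class=1, revel=0.536)
        c = classify_missense(V, ev, CFG)
        assert (c.cls, c.rule_fired) == (NOT_PATHOGENIC, INSIGHT)
        assert not c.predicted_damaging  # REVEL applies to VUS only

    def test_no_annotation_is_vus(self):
        ev = AnnotationEvidence(KEY, max_maf=0.001)
        c = classify_missense(V, ev, CFG)
        assert (c.cls, c.rule_fired) == (VUS, NO_ANNOTATION)

    def test_frequency_band_fires_before_databases(self):
        ev = AnnotationEvidence(KEY, insight_class=5, max_maf=0.03)
        c = classify_missense(V, ev, CFG)
        assert (c.cls, c.rule_fired) == (NOT_PATHOGENIC, FREQ_BENIGN)

    def test_frequency_band_is_half_open(self):
        at_five = AnnotationEvidence(KEY, max_maf=0.05)
        # 5% belongs to the exclusion filter upstream, not the benign band
        assert classify_missense(V, at_five, CFG).rule_fired == NO_ANNOTATION
        at_two = AnnotationEvidence(KEY, max_maf=0.02)
        assert classify_missense(V, at_two, CFG).rule_fired == FREQ_BENIGN

    def test_recent_internal_beats_clinvar(self):
        ev = AnnotationEvidence(
            KEY, internal_class=LIKELY_PATHOGENIC, internal_review_year=2016,
            clinvar_class=NOT_PATHOGENIC, clinvar_stars=3,
        )
        c = classify_missense(V, ev, CFG)
        assert (c.cls, c.rule_fired) == (LIKELY_PATHOGENIC, INTERNAL_RECENT)

    def test_stale_internal_defers_to_two_star_clinvar(self):
        ev = AnnotationEvidence(
            KEY, internal_class=LIKELY_PATHOGENIC, internal_review_year=2012,
            clinvar_class=PATHOGENIC, clinvar_stars=2,
        )
        c = classify_missense(V, ev, CFG)
        assert (c.cls, c.rule_fired) == (PATHOGENIC, CLINVAR_2STAR)

    @pytest.mark.parametrize(
        "ev",
        [
            AnnotationEvidence(KEY, internal_class=VUS, internal_review_year=2010),
            AnnotationEvidence(KEY, clinvar_class=PATHOGENIC, clinvar_stars=1),
            AnnotationEvidence(KEY, hgmd=True),
        ],
    )
    def test_weak_evidence_flags_for_human_review(self, ev):
        c = classify_missense(V, ev, CFG)
        assert (c.cls, c.rule_fired) == (VUS, REVIEW_REQUIRED)
        assert c.review_flag

    def test_missing_evidence_row_behaves_as_unannotated(self):
        from paneltriage.decisions import DecisionLog

        log = DecisionLog()
        c = classify_missense(V, None, CFG, log=log)
        assert (c.cls, c.rule_fired) == (VUS, NO_ANNOTATION)
        assert any(r.rule == "missing_evidence_row" for r in log.records)

    @given(
        maf=st.floats(0.0, 0.049),
        insight=st.one_of(st.none(), st.integers(1, 5)),
        internal_year=st.one_of(st.none(), st.integers(2005, 2020)),
        stars=st.one_of(st.none(), st.integers(0, 4)),
        hgmd=st.booleans(),
    )
    @settings(max_examples=200, deadline=None)
    def test_exactly_one_rule_fires(self, maf, insight, internal_year, stars, hgmd):
        ev = AnnotationEvidence(
            KEY,
            insight_class=insight,
            internal_class=VUS if internal_year is not None else None,
            internal_review_year=internal_year,
            clinvar_class=VUS if stars is not None else None,
            clinvar_stars=stars,
            hgmd=hgmd,
            max_maf=maf,
        )
        c = classify_missense(V, ev, CFG)
        # the fired rule uniquely identifies the branch, and the expected
        # branch is recomputed here independently by first-match semantics
        if 0.02 <= maf < 0.05:
            expected = FREQ_BENIGN
        elif insight is not None:
            expected = INSIGHT
        elif internal_year is not None and internal_year >= 2015:
            expected = INTERNAL_RECENT
        elif stars is not None and stars >= 2:
            expected = CLINVAR_2STAR
        elif internal_year is not None or stars is not None or hgmd:
            expected = REVIEW_REQUIRED
        else:
            expected = NO_ANNOTATION
        assert c.rule_fired == expected


class TestRevel:
    def test_at_cutoff_is_damaging(self):
        c = classify_missense(V, AnnotationEvidence(KEY, revel=0.536), CFG)
        c = apply_revel(c, AnnotationEvidence(KEY, revel=0.536), CFG)
        assert c.cls == VUS and c.predicted_damaging

    def test_below_cutoff_not_damaging(self):
        ev = AnnotationEvidence(KEY, revel=0.49)
        c = apply_revel(classify_missense(V, ev, CFG), ev, CFG)
        assert not c.predicted_damaging

    def test_non_vus_classes_unchanged(self):
        ev = AnnotationEvidence(KEY, insight_class=1, revel=0.9)
        c = classify_missense(V, ev, CFG)
        assert apply_revel(c, ev, CFG) == c

    def test_absent_score_never_damaging(self):
        ev = AnnotationEvidence(KEY)
        c = apply_revel(classify_missense(V, ev, CFG), ev, CFG)
        assert not c.predicted_damaging

    @given(revel=st.one_of(st.none(), st.floats(0.0, 1.0)), maf=st.floats(0.0, 0.049))
    @settings(max_examples=100, deadline=None)
    def test_revel_only_sets_flags_never_classes(self, revel, maf):
        with_score = AnnotationEvidence(KEY, revel=revel, max_maf=maf)
        without = AnnotationEvidence(KEY, revel=None, max_maf=maf)
        c_with = apply_revel(classify_missense(V, with_score, CFG), with_score, CFG)
        c_without = apply_revel(classify_missense(V, without, CFG), without, CFG)
        assert c_with.cls == c_without.cls
        assert c_with.rule_fired == c_without.rule_fired


def test_cohort_tallies_partition_unique_missense(small_bundle, small_result):
    """Every unique retained missense is classified exactly once and the
    class tally matches the planted evidence design."""
    from paneltriage.classify import class_tally, missense_keys

    keys = missense_keys(small_result.assignments)
    tally = class_tally(small_result.classifications, keys=keys)
    spec_design = small_bundle.truth.variants
    t2 = spec_design[(spec_design.intended_tier == "TIER2")
                     & (spec_design.consequence == "missense")]
    assert tally["total"] == len(keys) == len(t2)
    assert tally["pathogenic_or_likely"] == (
        t2.intended_class.isin(["PATHOGENIC", "LIKELY_PATHOGENIC"]).sum()
    )
    assert tally["vus_predicted_damaging"] == int(t2.intended_damaging.sum())
    assert tally["pathogenic_or_likely"] + tally["benign_side"] + tally["vus"] == tally["total"]
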