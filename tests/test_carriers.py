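"""Group assignment, multi-variant carrier detection and summary rates."""

import pytest
from hypothesis import given, settings, strategies as st

from paneltriage.carriers import (
    COMPOUND_HET,
    FCCTX,
    HOMOZYGOUS,
    MULTI_GENE,
    PMMR,
    UNSELECTED,
    YOUNG_ONSET,
    assign_group,
    find_multi_variant_carriers,
    headline_rate,
    two_variant_carriers,
)
from tests.test_tiering import make_variant


class TestAssignGroup:
    def test_fcctx_beats_young_onset(self):
        assert assign_group({FCCTX: True, YOUNG_ONSET: True}) == FCCTX

    def test_young_onset_beats_pmmr(self):
        assert assign_group({YOUNG_ONSET: True, PMMR: True}) == YOUNG_ONSET

    def test_unselected_alone(self):
        assert assign_group({UNSELECTED: True}) == UNSELECTED

    def test_control_flag_wins(self):
        assert assign_group({"control": True, FCCTX: True}) == "control"

    def test_no_flags_is_error(self):
        with pytest.raises(ValueError, match="eligibility"):
            assign_group({})

    @given(flags=st.sets(st.sampled_from([FCCTX, YOUNG_ONSET, PMMR, "dMMR", UNSELECTED]),
                         min_size=1))
    @settings(max_examples=50, deadline=None)
    def test_total_deterministic_function(self, flags):
        eligibility = {g: True for g in flags}
        g1 = assign_group(eligibility)
        g2 = assign_group(dict(reversed(list(eligibility.items()))))
        assert g1 == g2 and g1 in flags


def _variant(sample, gene, pos, zygosity="het"):
    return make_variant(sample_id=sample, gene=gene, pos=pos, zygosity=zygosity)


class TestMultiVariant:
    def test_homozygote_detected(self):
        vs = [_variant("s1", "MUTYH", 100, "hom_alt")]
        recs, hist = find_multi_variant_carriers(vs, {vs[0].variant_key})
        assert [r.pattern for r in recs] == [HOMOZYGOUS]
        assert hist == {}  # one distinct variant

    def test_compound_het_needs_two_distinct_in_one_gene(self):
        vs = [_variant("s1", "MUTYH", 100), _variant("s1", "MUTYH", 200)]
        recs, hist = find_multi_variant_carriers(vs, {v.variant_key for v in vs})
        assert [r.pattern for r in recs] == [COMPOUND_HET]
        assert hist == {2: 1}

    def test_multi_gene_record(self):
        vs = [_variant("s1", "MUTYH", 100), _variant("s1", "PMS1", 200)]
        recs, _ = find_multi_variant_carriers(vs, {v.variant_key for v in vs})
        assert [r.pattern for r in recs] == [MULTI_GENE]

    def test_single_qualifying_variant_no_record(self):
        vs = [_variant("s1", "MUTYH", 100)]
        recs, hist = find_multi_variant_carriers(vs, {vs[0].variant_key})
        assert recs == [] and hist == {}

    def test_non_qualifying_variants_ignored(self):
        vs = [_variant("s1", "MUTYH", 100), _variant("s1", "MUTYH", 200)]
        recs, _ = find_multi_variant_carriers(vs, {vs[0].variant_key})
        assert recs == []

    def test_order_symmetric_and_idempotent(self):
        vs = [_variant("s1", "MUTYH", 100), _variant("s1", "MUTYH", 200)]
        keys = {v.variant_key for v in vs}
        fwd, _ = find_multi_variant_carriers(vs, keys)
        rev, _ = find_multi_variant_carriers(list(reversed(vs)), keys)
        dup, _ = find_multi_variant_carriers(vs + vs, keys)
        assert {(r.sample_id, r.gene, tuple(sorted(r.variant_keys))) for r in fwd} \
            == {(r.sample_id, r.gene, tuple(sorted(r.variant_keys))) for r in rev} \
            == {(r.sample_id, r.gene, tuple(sorted(r.variant_keys))) for r in dup}

    def test_two_variant_carriers_counts_hom_and_compound(self):
        vs = [
            _variant("s1", "MUTYH", 100, "hom_alt"),
            _variant("s2", "MUTYH", 100), _variant("s2", "MUTYH", 200),
            _variant("s3", "MUTYH", 100),  # single het: not biallelic
        ]
        recs, _ = find_multi_variant_carriers(vs, {v.variant_key for v in vs})
        assert two_variant_carriers(recs, "MUTYH") == {"s1", "s2"}


class TestHeadlineRates:
    def test_published_arithmetic(self):
        assert headline_rate(92, 1231) == 7.5
        assert headline_rate(72, 1231) == 5.8
        assert headline_rate(0, 500) == 0.0

    def test_zero_denominator_is_error(self):
        with pytest.raises(ValueError):
            headline_rate(1, 0)


def test_planted_multi_variant_carriers_recovered(default_bundle, default_result):
    """Every planted homozygote / compound het / multi-gene case is found."""
    truth = default_bundle.truth.multi
    got = {
        (r.sample_id, r.gene, r.pattern) for r in default_result.multi_carriers
    }
    for row in truth.itertuples(index=False):
        assert (row.sample_id, row.gene, row.pattern) in got
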