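"""Variant filtering (DP/GQ/MAF), tier assignment and splice distances."""

import pytest
from hypothesis import given, settings, strategies as st

from paneltriage.config import PipelineConfig
from paneltriage.targets import build_panel
from paneltriage.tiering import (
    EXCLUDED,
    EXCLUDED_DP,
    EXCLUDED_GQ,
    EXCLUDED_MAF,
    RETAINED,
    TIER1,
    TIER2,
    PopulationFrequencyTable,
    VariantRecord,
    assign_tier,
    filter_variant,
    is_splice_region,
    percent_carriers,
    splice_distance,
    tier1_overview,
    tier_variants,
)

CFG = PipelineConfig()


def make_variant(consequence="missense", dp=100, gq=99, pos=15000030, **kw):
    defaults = dict(
        sample_id="s1", chrom="chr3", pos=pos, ref="A", alt="G", gene="MLH1",
        transcript="NM_MLH1", consequence=consequence, protein_change="p.X",
        dp=dp, gq=gq, zygosity="het",
    )
    defaults.update(kw)
    return VariantRecord(**defaults)


def freq_table(af_by_pop):
    t = PopulationFrequencyTable()
    for (src, pop), af in af_by_pop.items():
        t.add("chr3:15000030:A:G", src, pop, af)
    return t


class TestFilter:
    def test_low_depth_fails_first(self):
        v = make_variant(dp=19, gq=99)
        assert filter_variant(v, PopulationFrequencyTable(), CFG) == EXCLUDED_DP

    def test_low_gq(self):
        v = make_variant(dp=50, gq=29)
        assert filter_variant(v, PopulationFrequencyTable(), CFG) == EXCLUDED_GQ

    def test_maf_at_or_above_5pct_in_any_population(self):
        v = make_variant(dp=100, gq=60)
        t = freq_table({("KG", "EUR"): 0.001, ("EXAC", "AFR"): 0.051})
        assert filter_variant(v, t, CFG) == EXCLUDED_MAF

    def test_boundaries_retained(self):
        # DP exactly 20 and GQ exactly 30 are kept; AF 0.049 is below the bound
        v = make_variant(dp=20, gq=30)
        t = freq_table({("KG", "EUR"): 0.049})
        assert filter_variant(v, t, CFG) == RETAINED

    def test_absent_frequency_means_novel(self):
        v = make_variant()
        assert filter_variant(v, PopulationFrequencyTable(), CFG) == RETAINED

    @given(
        dp=st.integers(0, 60), gq=st.integers(0, 60),
        af=st.floats(0.0, 0.2),
    )
    @settings(max_examples=150, deadline=None)
    def test_rules_are_conjunctive(self, dp, gq, af):
        """Retention never depends on rule order: it equals the conjunction."""
        v = make_variant(dp=dp, gq=gq)
        t = freq_table({("KG", "EUR"): af})
        status = filter_variant(v, t, CFG)
        should_retain = dp >= 20 and gq >= 30 and af < 0.05
        assert (status == RETAINED) == should_retain


class TestTier:
    @pytest.mark.parametrize(
        "consequence,tier",
        [
            ("nonsense", TIER1), ("frameshift", TIER1), ("splice_site", TIER1),
            ("initiator_codon", TIER1), ("stop_loss", TIER1),
            ("missense", TIER2), ("inframe_indel", TIER2),
        ],
    )
    def test_consequence_to_tier(self, consequence, tier):
        assert assign_tier(make_variant(consequence=consequence))[0] == tier

    @pytest.mark.parametrize("consequence", ["synonymous", "intronic", "UTR", "intergenic"])
    def test_non_coding_and_silent_excluded(self, consequence):
        tier, status = assign_tier(make_variant(consequence=consequence))
        assert (tier, status) == (EXCLUDED, "excluded_consequence")

    def test_unknown_consequence_is_an_error(self):
        with pytest.raises(ValueError, match="consequence"):
            make_variant(consequence="regulatory")

    def test_tier_variants_logs_every_decision(self, cfg):
        from paneltriage.decisions import DecisionLog

        log = DecisionLog()
        vs = [make_variant(), make_variant(consequence="synonymous", pos=15000040),
              make_variant(dp=5, pos=15000050)]
        assignments = tier_variants(vs, PopulationFrequencyTable(), cfg, log=log)
        assert len(log.filter("tier")) == len(vs)
        assert [a.filter_status for a in assignments] == [
            RETAINED, "excluded_consequence", EXCLUDED_DP,
        ]


class TestSpliceDistance:
    PANEL = build_panel(["MLH1"])

    def exon_end(self):
        return self.PANEL[0].exon_end  # exclusive

    def test_two_bases_into_intron_is_splice(self):
        pos = self.exon_end() + 1  # second intronic base
        d = splice_distance("chr3", pos, "MLH1", self.PANEL)
        assert d == 2 and is_splice_region(d)

    def test_three_bases_is_intronic(self):
        pos = self.exon_end() + 2
        d = splice_distance("chr3", pos, "MLH1", self.PANEL)
        assert d == 3 and not is_splice_region(d)

    def test_exonic_position_not_splice(self):
        t = self.PANEL[0]
        d = splice_distance("chr3", (t.exon_start + t.exon_end) // 2, "MLH1", self.PANEL)
        assert d <= 0 and not is_splice_region(d)

    def test_upstream_boundary_symmetric(self):
        t = self.PANEL[3]
        assert splice_distance("chr3", t.exon_start - 2, "MLH1", self.PANEL) == 2

    def test_outside_capture_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            splice_distance("chr3", 1, "MLH1", self.PANEL)


class TestOverview:
    def test_percent_carriers_rounding(self):
        assert percent_carriers(59, 548) == 10.8
        assert percent_carriers(11, 153) == 7.2
        assert percent_carriers(5, 93) == 5.4

    def test_overview_counts_unique_variants_and_carriers(self):
        vs = []
        # two carriers of one nonsense variant + one carrier of another, same gene
        for sid in ("a", "b"):
            vs.append(make_variant(consequence="nonsense", sample_id=sid))
        vs.append(make_variant(consequence="nonsense", sample_id="c", pos=15000040))
        assignments = tier_variants(vs, PopulationFrequencyTable(), CFG)
        table = tier1_overview(
            assignments, groups={"a": "g1", "b": "g1", "c": "g2"},
            group_sizes={"g1": 100, "g2": 50}, group_order=["g1", "g2"],
        )
        total = table[table.gene == "Total"].iloc[0]
        assert (total["g1_variants"], total["g1_individuals"]) == (1, 2)
        assert (total["g2_variants"], total["g2_individuals"]) == (1, 1)
        assert total["g1_pct_carriers"] == 2.0
        # empty cells stay blank
        empty = tier1_overview(assignments, groups={}, group_sizes={"g1": 10},
                               group_order=["g1"])
        assert empty[empty.gene == "Total"].iloc[0]["g1_pct_carriers"] == ""
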