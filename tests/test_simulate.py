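"""Synthetic cohort generator: determinism, planted structure, round-trips."""

import numpy as np
import pandas as pd
import pytest

from paneltriage import CohortSpec, PipelineConfig, generate_cohort
from paneltriage.carriers import CONTROL


def test_default_group_totals_match_study_sizes(default_bundle):
    meta = default_bundle.metadata_frame()
    qc_fail = set(default_bundle.truth.qc_fail["sample_id"])
    retained = meta[~meta.sample_id.isin(qc_fail)]
    counts = retained.groupby("group").size().to_dict()
    assert counts == {
        "FCCTX": 153, "unselected": 548, "young_onset": 333,
        "pMMR": 68, "dMMR": 129, "control": 93,
    }


def test_controls_have_no_age_at_diagnosis(default_bundle):
    for s in default_bundle.samples:
        if s.group == CONTROL:
            assert s.age_at_dx is None
        else:
            assert 16 <= s.age_at_dx <= 90


def test_all_sizes_zero_yields_empty_bundle(cfg):
    spec = CohortSpec()
    spec.group_sizes = {g: 0 for g in spec.group_sizes}
    spec.n_qc_fail = 0
    spec.tier1_spectrum = {k: 0 for k in spec.tier1_spectrum}
    spec.n_missense = spec.n_pathogenic_side = spec.n_benign_side = 0
    spec.n_freq_benign = spec.n_vus_damaging = spec.n_inframe_indel = 0
    spec.n_synonymous = spec.n_intronic = spec.n_maf_excluded = 0
    spec.n_low_dp = spec.n_low_gq = 0
    spec.plant_cnvs = spec.plant_multivariant = False
    bundle = generate_cohort(cfg, spec, seed=3)
    assert bundle.samples == [] and bundle.variants == []
    assert len(bundle.truth.variants) == 0 and len(bundle.truth.carriers) == 0


def test_negative_sizes_rejected(cfg):
    spec = CohortSpec()
    spec.group_sizes["FCCTX"] = -1
    with pytest.raises(ValueError, match="sizes"):
        generate_cohort(cfg, spec, seed=3)


def test_same_seed_is_byte_identical(cfg, tmp_path):
    spec = CohortSpec()
    spec.group_sizes = {"FCCTX": 5, "unselected": 10, "young_onset": 5,
                        "pMMR": 2, "dMMR": 2, "control": 3}
    spec.n_qc_fail = 1
    a, b = tmp_path / "a", tmp_path / "b"
    generate_cohort(cfg, spec, seed=42).write(a)
    generate_cohort(cfg, spec, seed=42).write(b)
    files = sorted(p.name for p in a.iterdir())
    assert files == sorted(p.name for p in b.iterdir())
    for name in files:
        assert (a / name).read_bytes() == (b / name).read_bytes(), name


def test_different_seed_differs(cfg, small_bundle):
    other = generate_cohort(cfg, None, seed=999)
    assert {v.variant_key for v in other.variants} != {
        v.variant_key for v in small_bundle.variants
    }


def test_vcf_round_trip_preserves_instances(small_bundle, tmp_path):
    """Writing then reading the VCF reproduces every per-sample record."""
    from paneltriage.io import read_vcf_variants
    from paneltriage.simulate import write_vcf

    path = tmp_path / "cohort.vcf"
    write_vcf(small_bundle, path)
    back = read_vcf_variants(path)
    assert sorted(back, key=lambda v: (v.variant_key, v.sample_id)) == sorted(
        small_bundle.variants, key=lambda v: (v.variant_key, v.sample_id)
    )


def test_evidence_max_maf_consistent_with_frequency_table(small_bundle):
    for key, ev in small_bundle.evidence.items():
        assert ev.max_maf == pytest.approx(small_bundle.frequencies.max_af(key))


def test_planted_maf_bands_are_realized(default_bundle):
    """Realized max frequencies fall in the planted band for every variant."""
    tv = default_bundle.truth.variants
    freqs = default_bundle.frequencies
    for row in tv.itertuples(index=False):
        af = freqs.max_af(row.variant_key)
        if row.maf_band == "novel":
            assert af == 0.0
        elif row.maf_band == "rare":
            assert 0.0 < af < 0.02
        elif row.maf_band == "benign":
            assert 0.02 <= af < 0.05
        else:
            assert af >= 0.05


def test_unique_variant_spectrum_matches_spec(default_bundle):
    tv = default_bundle.truth.variants
    tier1 = tv[tv.intended_tier == "TIER1"]
    assert tier1.consequence.value_counts().to_dict() == {
        "frameshift": 43, "nonsense": 29, "splice_site": 13,
        "initiator_codon": 6, "stop_loss": 1,
    }
    t2 = tv[tv.intended_tier == "TIER2"]
    assert (t2.consequence == "missense").sum() == 658
    assert (t2.consequence == "inframe_indel").sum() == 17


def test_splice_variants_sit_in_the_splice_window(default_bundle):
    from paneltriage.tiering import is_splice_region, splice_distance

    for v in default_bundle.variants:
        if v.consequence == "splice_site":
            d = splice_distance(v.chrom, v.pos, v.gene, default_bundle.targets)
            assert is_splice_region(d)
        elif v.consequence == "intronic":
            d = splice_distance(v.chrom, v.pos, v.gene, default_bundle.targets)
            assert d > 2
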