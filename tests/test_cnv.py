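"""Coverage-pattern learning, weighted CBS and CNV calling."""

import numpy as np
import pandas as pd
import pytest

from paneltriage.cnv import (
    CNVError,
    CNVSegment,
    CoverageMatrix,
    build_reference_pattern,
    call_cnvs,
    compute_log2_ratios,
    segment,
    segment_gene_profiles,
    smooth_outliers,
)
from paneltriage.config import PipelineConfig
from paneltriage.simulate import CohortSpec, _base_coverage, inject_cnv
from paneltriage.targets import build_panel, targets_by_gene

CFG = PipelineConfig(seed=0)
PANEL3 = build_panel(["MLH1", "MSH2", "MSH6"])
GENE_SIZES = {g: len(ts) for g, ts in targets_by_gene(PANEL3).items()}


def matrix_from_array(depths: np.ndarray, targets=PANEL3) -> CoverageMatrix:
    ids = [f"s{i:03d}" for i in range(depths.shape[0])]
    return CoverageMatrix(
        pd.DataFrame(depths, index=ids, columns=[t.target_id for t in targets]), targets
    )


class TestReferencePattern:
    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(50, 200, size=len(PANEL3))
        scales = rng.uniform(0.5, 2.0, size=(20, 1))
        m = matrix_from_array(scales * base[None, :])
        ref = build_reference_pattern(m, CFG)
        # pattern equals the shared profile up to each sample's median scale
        expected = base / np.median(base)
        assert np.allclose(ref.pattern, expected, rtol=1e-9)

    def test_one_outlier_sample_does_not_move_the_median(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(50, 200, size=len(PANEL3))
        depths = np.tile(base, (50, 1)) * rng.lognormal(0, 0.05, size=(50, len(PANEL3)))
        clean_ref = build_reference_pattern(matrix_from_array(depths), CFG)
        corrupted = depths.copy()
        corrupted[0] = base * 40.0  # wildly over-sequenced sample
        ref = build_reference_pattern(matrix_from_array(corrupted), CFG)
        assert np.allclose(ref.pattern, clean_ref.pattern, rtol=0.05)

    def test_constant_matrix_dispersion_capped_by_epsilon(self):
        m = matrix_from_array(np.full((10, len(PANEL3)), 80.0))
        ref = build_reference_pattern(m, CFG)
        assert np.all(ref.dispersion == 0.0)
        assert np.allclose(ref.weights, 1.0 / CFG.pattern_epsilon)

    def test_too_few_samples_rejected(self):
        m = matrix_from_array(np.full((4, len(PANEL3)), 80.0))
        with pytest.raises(CNVError, match="samples"):
            build_reference_pattern(m, CFG)


class TestLog2Ratios:
    def test_identity_deletion_and_gain(self):
        base = np.full(len(PANEL3), 100.0)
        depths = np.tile(base, (20, 1))
        # sample 0: heterozygous deletion over MLH1 targets 0..4; sample 1: 3 copies
        depths[0, :5] *= 0.5
        depths[1, 5:10] *= 1.5
        m = matrix_from_array(depths)
        ref = build_reference_pattern(m, CFG)
        ratios = compute_log2_ratios(m, ref, CFG)
        assert abs(ratios.iloc[2, 0]) < 0.01  # untouched sample ~ 0
        assert ratios.iloc[0, 0] == pytest.approx(-1.0, abs=0.05)
        assert ratios.iloc[1, 5] == pytest.approx(np.log2(1.5), abs=0.05)


def exhaustive_best_arc(x, w, min_width):
    """Independent oracle: minimize weighted RSS over all 3-piece fits."""
    n = len(x)
    best, best_rss = None, np.inf
    for i in range(0, n):
        for j in range(i + min_width, n + 1):
            if i == 0 and j == n:
                continue
            inside = np.zeros(n, dtype=bool)
            inside[i:j] = True
            m_in = np.average(x[inside], weights=w[inside])
            m_out = np.average(x[~inside], weights=w[~inside])
            rss = float(
                np.sum(w[inside] * (x[inside] - m_in) ** 2)
                + np.sum(w[~inside] * (x[~inside] - m_out) ** 2)
            )
            if rss < best_rss - 1e-12:
                best_rss, best = rss, (i, j)
    return best


class TestSegmentation:
    def test_flat_profile_is_one_segment(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.05, size=20)
        segs = segment(x, np.ones(20), CFG)
        assert len(segs) == 1
        assert segs[0][2] == pytest.approx(0.0, abs=0.05)

    def test_step_recovers_exact_breakpoints(self):
        rng = np.random.default_rng(3)
        w = rng.uniform(5, 50, size=20)
        # weights are inverse-variability: noise scales as 1/sqrt(w)
        x = rng.normal(0, 0.3 / np.sqrt(w))
        x[5:10] -= 1.0
        segs = segment(x, w, CFG)
        assert [(s[0], s[1]) for s in segs] == [(0, 5), (5, 10), (10, 20)]
        assert segs[1][2] == pytest.approx(-1.0, abs=0.15)

    @pytest.mark.parametrize("seed", range(8))
    def test_first_split_matches_exhaustive_oracle(self, seed):
        """On <=20-target profiles with one true change, CBS's split equals
        the brute-force weighted least-squares search."""
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(8, 21))
        width = int(rng.integers(2, max(3, n // 3)))
        lo = int(rng.integers(0, n - width + 1))
        w = rng.uniform(5, 50, size=n)
        x = rng.normal(0, 0.3 / np.sqrt(w))  # noise consistent with weights
        x[lo : lo + width] -= 1.0
        oracle = exhaustive_best_arc(x, w, CFG.cbs_min_width)
        from paneltriage.cnv import _max_arc

        res = _max_arc(x, w, CFG.cbs_min_width)
        got = (res[0], res[1])
        # maximal |t| and minimal weighted RSS pick the same arc (or its
        # complement, which induces the same breakpoints)
        complement = {got, (0, got[0]) if got[1] == n else None,
                      (got[1], n) if got[0] == 0 else None}
        assert oracle in complement
        # and the planted arc is found
        segs = segment(x, w, CFG)
        assert (lo, lo + width) in {(s[0], s[1]) for s in segs}

    def test_single_target_gene_yields_one_segment(self):
        segs = segment(np.array([-1.0]), np.array([10.0]), CFG)
        assert segs == [(0, 1, -1.0)]

    def test_samples_segment_independently(self):
        rng = np.random.default_rng(4)
        base = np.full(len(PANEL3), 100.0)
        depths = np.tile(base, (20, 1)) * rng.lognormal(0, 0.05, (20, len(PANEL3)))
        depths[0, :6] *= 0.5
        m = matrix_from_array(depths)
        ref = build_reference_pattern(m, CFG)
        ratios = compute_log2_ratios(m, ref, CFG)
        segs = segment_gene_profiles(ratios, ref, PANEL3, CFG, genes=["MLH1"])
        with_event = [s for s in segs if s.sample_id == "s000"]
        others = [s for s in segs if s.sample_id != "s000"]
        assert len(with_event) >= 2
        assert all(len([s for s in others if s.sample_id == sid]) == 1
                   for sid in {s.sample_id for s in others})

    def test_permutation_mode_agrees_on_clear_events(self):
        cfg = CFG.replace(cbs_p_method="permutation", cbs_permutations=500, cbs_alpha=0.05)
        rng = np.random.default_rng(5)
        x = rng.normal(0, 0.05, size=18)
        x[4:12] -= 1.0  # wide event: well above the permutation floor
        segs = segment(x, np.ones(18), cfg, rng=np.random.default_rng(0))
        assert (4, 12) in {(s[0], s[1]) for s in segs}


class TestSmoothing:
    def test_singleton_spike_flattened(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 0.1, size=19)
        x[7] = -1.0
        sm = smooth_outliers(x)
        assert sm[7] > -0.5
        assert np.allclose(np.delete(sm, 7), np.delete(x, 7))

    def test_adjacent_pair_protected(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 0.1, size=19)
        x[7:9] -= 1.0
        sm = smooth_outliers(x)
        assert np.allclose(sm[7:9], x[7:9])


class TestCalls:
    def _segments(self, means_and_ranges, gene="MSH2"):
        return [
            CNVSegment("s1", gene, "chr2", lo, hi, mean)
            for lo, hi, mean in means_and_ranges
        ]

    def test_cutoff_semantics(self):
        segs = self._segments([(0, 5, -1.0), (5, 10, -0.3), (10, 16, 0.6)])
        calls = call_cnvs(segs, PANEL3, CFG)
        assert [(c.call, c.n_targets) for c in calls] == [
            ("deletion", 5), ("amplification", 6),
        ]

    def test_boundaries_one_based_with_feature_span(self):
        segs = self._segments([(10, 15, -1.0)])
        (call,) = call_cnvs(segs, PANEL3, CFG)
        gts = targets_by_gene(PANEL3)["MSH2"]
        assert call.start == gts[10].start + 1 and call.end == gts[14].end
        assert call.feature_span == "exon 11 - exon 15"
        assert not call.at_panel_edge

    def test_edge_flag_set_when_touching_gene_end(self):
        segs = self._segments([(0, 4, -1.0)])
        (call,) = call_cnvs(segs, PANEL3, CFG)
        assert call.at_panel_edge

    def test_non_eligible_gene_dropped(self):
        panel = build_panel(["MLH1", "APC"])
        segs = [CNVSegment("s1", "APC", "chr5", 0, 5, -1.0)]
        assert call_cnvs(segs, panel, CFG) == []

    def test_width_one_segments_never_called(self):
        segs = self._segments([(3, 4, -2.0)])
        assert call_cnvs(segs, PANEL3, CFG) == []


class TestInjectCnv:
    def _matrix(self):
        rng = np.random.default_rng(8)
        return _base_coverage([f"s{i:03d}" for i in range(12)], PANEL3, CohortSpec(), rng)

    def test_het_deletion_halves_depth(self):
        m = self._matrix()
        before = m.depths.iloc[0, :5].to_numpy().copy()
        m2, truth = inject_cnv(m, "s000", "MLH1", (0, 5), 1, rng=np.random.default_rng(0))
        after = m2.depths.iloc[0, :5].to_numpy()
        assert np.allclose(after / before, 0.5, rtol=0.2)
        assert truth["expected_call"] == "deletion"

    def test_diploid_injection_is_identity(self):
        m = self._matrix()
        m2, truth = inject_cnv(m, "s000", "MLH1", (0, 5), 2)
        assert m2.depths.equals(m.depths)
        assert truth["expected_call"] == "none"

    def test_homozygous_deletion_floors_at_noise(self):
        m = self._matrix()
        before = m.depths.iloc[0, 2:4].to_numpy().copy()
        m2, _ = inject_cnv(m, "s000", "MLH1", (2, 4), 0, rng=np.random.default_rng(0))
        after = m2.depths.iloc[0, 2:4].to_numpy()
        assert np.all(after < 0.05 * before)
        assert np.all(after > 0)

    def test_range_and_sample_validation(self):
        m = self._matrix()
        with pytest.raises(ValueError, match="range"):
            inject_cnv(m, "s000", "MSH6", (0, 99), 1)
        with pytest.raises(ValueError, match="sample"):
            inject_cnv(m, "nope", "MSH6", (0, 2), 1)
        with pytest.raises(ValueError, match="copy_number"):
            inject_cnv(m, "s000", "MSH6", (0, 2), 7)
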