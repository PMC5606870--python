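"""Truth-recovery metrics for synthetic cohorts.

Compares pipeline output against a bundle's embedded :class:`TruthSet`:
Tier 1 recall/precision at the (sample, variant) instance level,
classification agreement against the planted evidence design, CNV
detection of planted deletions, and a multi-seed CNV property suite on
small matrices.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .cnv import (
    build_reference_pattern,
    call_cnvs,
    compute_log2_ratios,
    segment_gene_profiles,
)
from .config import PipelineConfig
from .pipeline import PipelineResult
from .simulate import CohortBundle, CohortSpec, _base_coverage, inject_cnv
from .targets import build_panel, targets_by_gene
from .tiering import TIER1


def tier1_recovery(bundle: CohortBundle, result: PipelineResult) -> dict[str, float]:
    """Instance-level recall/precision of planted Tier 1 variants.

    Expected set: planted carriers whose instance passes the planted DP/GQ,
    frequency and sample-QC constraints. Decoys (low DP/GQ, frequent,
    synonymous/intronic, QC-failed samples) must not appear.
    """
    tc = bundle.truth.carriers.merge(bundle.truth.variants, on="variant_key")
    expected = {
        (r.sample_id, r.variant_key)
        for r in tc.itertuples(index=False)
        if r.expected_fate == "retained" and r.intended_tier == "TIER1"
    }
    got = {
        (a.sample_id, a.variant_key)
        for a in result.assignments
        if a.retained and a.tier == TIER1
    }
    tp = len(expected & got)
    return {
        "n_expected": len(expected),
        "n_called": len(got),
        "recall": tp / len(expected) if expected else 1.0,
        "precision": tp / len(got) if got else 1.0,
    }


def classification_agreement(bundle: CohortBundle, result: PipelineResult) -> dict[str, int]:
    """Exact agreement between planted classes/rules/flags and the verdicts."""
    tv = bundle.truth.variants
    t2 = tv[tv.intended_tier == "TIER2"]
    mismatches = 0
    for row in t2.itertuples(index=False):
        c = result.classifications.get(row.variant_key)
        if c is None:
            mismatches += 1
            continue
        ok = (
            c.cls == row.intended_class
            and c.rule_fired == row.intended_rule
            and (row.consequence != "missense" or c.predicted_damaging == row.intended_damaging)
        )
        mismatches += 0 if ok else 1
    return {"n_tier2_planted": len(t2), "mismatches": mismatches}


def cnv_recovery(bundle: CohortBundle, result: PipelineResult) -> dict[str, int]:
    truth = bundle.truth.cnvs
    planted_all = {(r.sample_id, r.gene) for r in truth.itertuples(index=False)}
    planted_multi = {
        (r.sample_id, r.gene) for r in truth.itertuples(index=False) if r.expected_detected
    }
    called = {
        (c.sample_id, c.gene) for c in result.cnv_calls if c.call == "deletion"
    }
    return {
        "planted_total": len(planted_all),
        "planted_multi_exon": len(planted_multi),
        "detected_multi_exon": len(planted_multi & called),
        "detected_total": len(planted_all & called),
        "false_calls": len(called - planted_all),
    }


def multi_variant_recovery(bundle: CohortBundle, result: PipelineResult) -> dict[str, int]:
    truth = bundle.truth.multi
    got = {(r.sample_id, r.gene, r.pattern) for r in result.multi_carriers}
    recovered = sum(
        1
        for r in truth.itertuples(index=False)
        if (r.sample_id, r.gene, r.pattern) in got
    )
    return {"planted": len(truth), "recovered": recovered}


def cnv_seed_suite(
    n_seeds: int = 50,
    base_seed: int = 1000,
    n_samples: int = 40,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Plant deletions in small coverage matrices across many seeds.

    Per seed: three heterozygous multi-exon deletions (4-, 2- and 3-target
    in MLH1/MSH2/MSH6) plus one single-target deletion. Columns report
    whether all multi-exon events were recovered with no false calls, the
    single-target event's fate at defaults, and its fate with smoothing off
    and single-target segments allowed.
    """
    cfg = cfg or PipelineConfig(seed=0)
    relaxed = cfg.replace(cbs_min_width=1, cnv_smooth_outliers=False)
    targets = build_panel(["MLH1", "MSH2", "MSH6"])
    gene_sizes = {g: len(ts) for g, ts in targets_by_gene(targets).items()}
    spec = CohortSpec()
    rows = []
    for k in range(n_seeds):
        rng = np.random.default_rng(base_seed + k)
        ids = [f"s{i:03d}" for i in range(n_samples)]
        m = _base_coverage(ids, targets, spec, rng)
        planted = []
        for j, (gene, width) in enumerate([("MLH1", 4), ("MSH2", 2), ("MSH6", 3)]):
            lo = int(rng.integers(0, gene_sizes[gene] - width + 1))
            m, _ = inject_cnv(m, ids[j], gene, (lo, lo + width), 1, rng=rng)
            planted.append((ids[j], gene))
        single_lo = int(rng.integers(0, gene_sizes["MLH1"]))
        m, _ = inject_cnv(m, ids[10], "MLH1", (single_lo, single_lo + 1), 1, rng=rng)
        single = (ids[10], "MLH1")

        def deletions(config):
            ref = build_reference_pattern(m, config)
            ratios = compute_log2_ratios(m, ref, config)
            calls = call_cnvs(
                segment_gene_profiles(ratios, ref, targets, config), targets, config
            )
            return {(c.sample_id, c.gene) for c in calls if c.call == "deletion"}

        got = deletions(cfg)
        got_relaxed = deletions(relaxed)
        rows.append(
            {
                "seed": base_seed + k,
                "multi_exon_sensitivity": float(len(set(planted) & got) / len(planted)),
                "false_calls": len(got - set(planted) - {single}),
                "single_missed_default": single not in got,
                "single_recovered_relaxed": single in got_relaxed,
            }
        )
    return pd.DataFrame(rows)
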