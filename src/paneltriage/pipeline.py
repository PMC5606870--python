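"""End-to-end orchestration: QC -> filter/tier -> classify -> CNV -> carriers.

:func:`run_bundle` drives the whole pipeline on an in-memory cohort bundle
and returns every intermediate product; :func:`run_pipeline` is the on-disk
variant that reads a bundle directory, delegates, and writes all report
tables plus the decision log and a run manifest. Outputs are byte-stable
for a fixed seed (no timestamps, sorted iteration everywhere).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as ptio
from .carriers import (
    CONTROL,
    MultiVariantCarrier,
    assign_group,
    carrier_table,
    find_multi_variant_carriers,
    headline_rate,
    qualifying_variant_keys,
    two_variant_carriers,
)
from .classify import (
    Classification,
    class_tally,
    classify_cohort,
    missense_keys,
    tier2_overview,
    vus_damaging_percent,
)
from .cnv import (
    CNVCall,
    CoverageMatrix,
    build_reference_pattern,
    call_cnvs,
    calls_to_frame,
    compute_log2_ratios,
    segment_gene_profiles,
)
from .config import PipelineConfig, config_fingerprint
from .decisions import DecisionLog
from .qc import apply_sample_qc
from .simulate import GROUP_DISPLAY_ORDER, CohortBundle, SampleMeta
from .targets import read_targets
from .tiering import (
    TIER1,
    TIER2,
    TierAssignment,
    VariantRecord,
    tier1_overview,
    tier_variants,
)


@dataclass
class PipelineResult:
    retained: list[str]
    qc_report: pd.DataFrame
    groups: dict[str, str]
    group_sizes: dict[str, int]
    assignments: list[TierAssignment]
    classifications: dict[str, Classification]
    tally: dict[str, int]
    cnv_calls: list[CNVCall]
    multi_carriers: list[MultiVariantCarrier]
    multi_histogram: dict[int, int]
    log: DecisionLog
    summary: dict[str, object] = field(default_factory=dict)


def _assign_groups(samples: Sequence[SampleMeta]) -> dict[str, str]:
    groups = {}
    for s in samples:
        groups[s.sample_id] = assign_group({g: True for g in s.eligibility})
    return groups


def run_bundle(bundle: CohortBundle, cfg: PipelineConfig | None = None) -> PipelineResult:
    cfg = cfg or PipelineConfig()
    log = DecisionLog()

    # stage 1: sample QC
    retained, qc_report = apply_sample_qc(bundle.samples, cfg, log=log)
    retained_set = set(retained)
    groups = _assign_groups([s for s in bundle.samples if s.sample_id in retained_set])
    group_sizes: dict[str, int] = {g: 0 for g in GROUP_DISPLAY_ORDER}
    for g in groups.values():
        group_sizes[g] = group_sizes.get(g, 0) + 1

    # stage 2: variant filtering + tiering (QC-excluded samples drop out first)
    variants = [v for v in bundle.variants if v.sample_id in retained_set]
    for v in bundle.variants:
        if v.sample_id not in retained_set:
            log.record(v.sample_id, v.variant_key, "tier", "sample_excluded", "excluded_sample")
    assignments = tier_variants(variants, bundle.frequencies, cfg, log=log)

    # stage 3: Tier 2 classification with REVEL layer
    classifications = classify_cohort(variants, assignments, bundle.evidence, cfg, log=log)
    # the headline tally is over unique retained missense variants; in-frame
    # indels are classified too but tallied separately
    tally = class_tally(classifications, keys=missense_keys(assignments))

    # stage 4: CNV calling (skipped when no coverage matrix is supplied)
    cnv_calls: list[CNVCall] = []
    if bundle.coverage is not None:
        ref = build_reference_pattern(bundle.coverage, cfg)
        for k, tid in enumerate(ref.target_ids):
            if ref.masked[k]:
                log.record("", "", "cnv", "target_masked", f"masked:{tid}")
        ratios = compute_log2_ratios(bundle.coverage, ref, cfg)
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
        segments = segment_gene_profiles(
            ratios, ref, bundle.targets, cfg, genes=cfg.cnv_genes, rng=rng
        )
        segments = [s for s in segments if s.sample_id in retained_set]
        cnv_calls = call_cnvs(segments, bundle.targets, cfg, log=log)

    # stage 5: carrier analysis
    qualifying = qualifying_variant_keys(assignments, classifications)
    multi, histogram = find_multi_variant_carriers(variants, qualifying)

    summary = _summarize(
        groups, group_sizes, assignments, classifications, tally, cnv_calls, multi, histogram, cfg
    )
    return PipelineResult(
        retained=retained,
        qc_report=qc_report,
        groups=groups,
        group_sizes=group_sizes,
        assignments=assignments,
        classifications=classifications,
        tally=tally,
        cnv_calls=cnv_calls,
        multi_carriers=multi,
        multi_histogram=histogram,
        log=log,
        summary=summary,
    )


_HEADLINE_GENES = ("APC", "MLH1", "MSH2", "MSH6")
_MMR_GENES = ("MLH1", "MSH2", "MSH6", "PMS2")


def pathogenic_case_ids(
    assignments: Sequence[TierAssignment],
    classifications: Mapping[str, Classification],
    cnv_calls: Sequence[CNVCall],
    multi: Sequence[MultiVariantCarrier],
    groups: Mapping[str, str],
    genes: Sequence[str] = _HEADLINE_GENES,
) -> set[str]:
    """Cases with a pathogenic finding in the headline genes.

    Counted: Tier 1 variants or pathogenic/likely-pathogenic Tier 2
    variants in ``genes``, deletions called in ``genes``, and biallelic
    (two-allele) qualifying MUTYH carriers. Controls never count.
    """
    from .classify import LIKELY_PATHOGENIC, PATHOGENIC

    cases: set[str] = set()
    for a in assignments:
        if not a.retained or groups.get(a.sample_id) == CONTROL or a.gene not in genes:
            continue
        if a.tier == TIER1:
            cases.add(a.sample_id)
        elif a.tier == TIER2:
            c = classifications.get(a.variant_key)
            if c is not None and c.cls in (PATHOGENIC, LIKELY_PATHOGENIC):
                cases.add(a.sample_id)
    for call in cnv_calls:
        if call.call == "deletion" and call.gene in genes and groups.get(call.sample_id) != CONTROL:
            cases.add(call.sample_id)
    for sid in two_variant_carriers(multi, "MUTYH"):
        if groups.get(sid) != CONTROL:
            cases.add(sid)
    return cases


def _summarize(groups, group_sizes, assignments, classifications, tally,
               cnv_calls, multi, histogram, cfg) -> dict[str, object]:
    n_cases = sum(n for g, n in group_sizes.items() if g != CONTROL)
    n_controls = group_sizes.get(CONTROL, 0)
    tier1 = [a for a in assignments if a.retained and a.tier == TIER1]
    tier1_unique = len({a.variant_key for a in tier1})
    tier1_carriers = len({a.sample_id for a in tier1})
    path_cases = pathogenic_case_ids(assignments, classifications, cnv_calls, multi, groups)
    mmr_path = pathogenic_case_ids(
        assignments, classifications, cnv_calls, [], groups, genes=_MMR_GENES
    )
    multi_samples = sum(histogram.values())
    return {
        "n_retained": len(groups),
        "n_cases": n_cases,
        "n_controls": n_controls,
        "tier1_unique_variants": tier1_unique,
        "tier1_carriers": tier1_carriers,
        "missense_tally": dict(tally),
        "vus_damaging_pct": vus_damaging_percent(tally, ndigits=0) if tally["vus"] else 0.0,
        "cnv_deletions": sum(1 for c in cnv_calls if c.call == "deletion"),
        "multi_variant_samples": multi_samples,
        "multi_variant_pct_of_cases": headline_rate(multi_samples, n_cases) if n_cases else 0.0,
        "pathogenic_cases": len(path_cases),
        "pathogenic_pct_of_cases": headline_rate(len(path_cases), n_cases) if n_cases else 0.0,
        "mmr_pathogenic_cases": len(mmr_path),
        "seed": cfg.seed,
    }


@dataclass(frozen=True)
class RunManifest:
    config_hash: str
    seed: int
    input_checksums: dict[str, str]
    stages: dict[str, str]
    outputs: tuple[str, ...]

    def write(self, path: str | Path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "input_checksums": dict(sorted(self.input_checksums.items())),
            "stages": dict(self.stages),
            "outputs": sorted(self.outputs),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def load_bundle(bundle_dir: str | Path) -> CohortBundle:
    """Re-assemble a CohortBundle from its written artifacts."""
    from .simulate import CohortBundle as CB
    from .tiering import PopulationFrequencyTable

    bundle_dir = Path(bundle_dir)
    samples = ptio.read_metadata(bundle_dir / "samples.tsv")
    targets = read_targets(bundle_dir / "targets.bed")
    variants = ptio.read_vcf_variants(bundle_dir / "cohort.vcf")
    freqs = PopulationFrequencyTable.read(bundle_dir / "frequencies.tsv")
    evidence = ptio.read_evidence(bundle_dir / "evidence.tsv")
    coverage = None
    cov_path = bundle_dir / "coverage.tsv"
    if cov_path.exists():
        coverage = CoverageMatrix.read(cov_path, targets)
    truth = ptio.read_truth(bundle_dir)
    return CB(
        samples=samples, targets=targets, variants=variants,
        frequencies=freqs, evidence=evidence, coverage=coverage, truth=truth,
    )


def write_reports(result: PipelineResult, outdir: str | Path) -> list[str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        df.to_csv(outdir / name, sep="\t", index=False)
        written.append(name)

    emit(result.qc_report, "qc_exclusions.tsv")
    tier_rows = pd.DataFrame(
        [
            {
                "sample_id": a.sample_id, "variant_key": a.variant_key, "gene": a.gene,
                "consequence": a.consequence, "filter_status": a.filter_status,
                "tier": a.tier or "",
            }
            for a in result.assignments
        ]
    )
    emit(tier_rows, "tier_assignments.tsv")
    emit(
        tier1_overview(result.assignments, result.groups, result.group_sizes,
                       group_order=GROUP_DISPLAY_ORDER),
        "tier1_overview.tsv",
    )
    cls_rows = pd.DataFrame(
        [
            {
                "variant_key": k, "class": c.cls, "rule_fired": c.rule_fired,
                "predicted_damaging": int(c.predicted_damaging),
                "review_flag": int(c.review_flag),
            }
            for k, c in sorted(result.classifications.items())
        ]
    )
    emit(cls_rows, "classifications.tsv")
    emit(
        tier2_overview(result.assignments, result.classifications, result.groups,
                       result.group_sizes, group_order=GROUP_DISPLAY_ORDER),
        "tier2_overview.tsv",
    )
    emit(
        carrier_table(result.assignments, result.groups, result.group_sizes, TIER1,
                      group_order=GROUP_DISPLAY_ORDER),
        "tier1_carriers.tsv",
    )
    emit(
        carrier_table(result.assignments, result.groups, result.group_sizes, TIER2,
                      group_order=GROUP_DISPLAY_ORDER),
        "tier2_carriers.tsv",
    )
    emit(calls_to_frame(result.cnv_calls), "cnv_calls.tsv")
    multi_rows = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id, "gene": m.gene, "pattern": m.pattern,
                "variant_keys": ";".join(m.variant_keys), "labels": ";".join(m.labels),
            }
            for m in result.multi_carriers
        ],
        columns=["sample_id", "gene", "pattern", "variant_keys", "labels"],
    )
    emit(multi_rows, "multi_variant_carriers.tsv")
    result.log.write(outdir / "decisions.tsv")
    written.append("decisions.tsv")
    (outdir / "summary.json").write_text(
        json.dumps(result.summary, indent=2, sort_keys=True) + "\n"
    )
    written.append("summary.json")
    return written


def run_pipeline(
    bundle_dir: str | Path,
    outdir: str | Path,
    cfg: PipelineConfig | None = None,
) -> RunManifest:
    """Read a bundle directory, run every stage, write reports + manifest."""
    cfg = cfg or PipelineConfig()
    bundle_dir = Path(bundle_dir)
    stages: dict[str, str] = {}
    inputs = {
        p.name: _checksum(p)
        for p in sorted(bundle_dir.iterdir())
        if p.is_file() and p.suffix in (".tsv", ".bed", ".vcf")
    }
    bundle = load_bundle(bundle_dir)
    if bundle.coverage is None:
        stages["cnv"] = "skipped:no_coverage_matrix"
    result = run_bundle(bundle, cfg)
    for name in ("qc", "tier", "classify", "carriers"):
        stages[name] = "ok"
    stages.setdefault("cnv", "ok")
    outputs = write_reports(result, outdir)
    manifest = RunManifest(
        config_hash=config_fingerprint(cfg),
        seed=cfg.seed,
        input_checksums=inputs,
        stages=stages,
        outputs=tuple(outputs),
    )
    manifest.write(Path(outdir) / "manifest.json")
    return manifest
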