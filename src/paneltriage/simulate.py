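"""Synthetic cohort generator with embedded truth.

Emulates the statistical structure the triage pipeline assumes: a
case-control cohort split into five case subgroups plus controls, a
multi-sample VCF of panel variants with per-genotype DP/GQ, population
allele-frequency and annotation-evidence snapshots, and a samples x
targets coverage matrix with injected exon-level deletions. Every planted
artifact is recorded in a :class:`TruthSet` so recovery can be measured.

Default sizes and spectra mirror the study conditions this pipeline
re-implements: retained group sizes 153 / 548 / 333 / 68 / 129 cases and
93 controls plus 6 planted QC failures; 92 unique protein-disrupting
(Tier 1) variants (29 nonsense, 43 frameshift, 13 splice, 6 initiator,
1 stop-loss); 658 missense designed to classify as 13 pathogenic-side,
61 benign-side and 584 VUS of which 144 carry REVEL >= 0.5; 17 in-frame
indels; plus synonymous/intronic decoys and instances planted to fail the
depth, quality, frequency or sample-QC filters.

The coverage model is per-sample depth factor x per-target capture
efficiency x lognormal noise, which is exactly the pattern structure the
CNV caller learns. Phase is never emitted as known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .carriers import (
    ALL_GROUPS,
    CONTROL,
    DMMR,
    FCCTX,
    GROUP_PRIORITY,
    PMMR,
    UNSELECTED,
    YOUNG_ONSET,
)
from .classify import (
    AnnotationEvidence,
    CLINVAR_2STAR,
    FREQ_BENIGN,
    INSIGHT,
    INTERNAL_RECENT,
    LIKELY_NOT_PATHOGENIC,
    LIKELY_PATHOGENIC,
    NO_ANNOTATION,
    NOT_PATHOGENIC,
    PATHOGENIC,
    REVIEW_REQUIRED,
    VUS,
)
from .cnv import CoverageMatrix
from .config import PipelineConfig
from .targets import PANEL_GENES, TargetInterval, build_panel, targets_by_gene, write_targets
from .tiering import (
    FRAMESHIFT,
    INFRAME_INDEL,
    INITIATOR_CODON,
    INTRONIC,
    MISSENSE,
    NONSENSE,
    PopulationFrequencyTable,
    SPLICE_SITE,
    STOP_LOSS,
    SYNONYMOUS,
    VariantRecord,
)

ETHNICITIES = ("Caucasian", "African American", "Asian", "Admix")
# case-ethnicity mix of the emulated cohort (931/139/44/117 of 1231)
ETHNICITY_PROBS = (0.756, 0.113, 0.036, 0.095)

POPULATIONS = {
    "KG": ("EUR", "AFR", "EAS", "AMR"),
    "ESP": ("EA", "AA"),
    "EXAC": ("NFE", "AFR", "EAS", "SAS"),
}
AFR_POPULATIONS = (("KG", "AFR"), ("ESP", "AA"), ("EXAC", "AFR"))

GROUP_DISPLAY_ORDER = (CONTROL, FCCTX, UNSELECTED, YOUNG_ONSET, PMMR, DMMR)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    eligibility: tuple[str, ...]  # groups this sample qualifies for
    group: str  # assigned group (resolved by priority)
    ethnicity: str
    age_at_dx: int | None  # None for controls
    ascertainment: str  # population | clinic
    cov10x: float
    cov40x: float
    concordance: float
    ihc: tuple[tuple[str, str], ...]  # (protein, result) pairs
    msi: str  # MSS | MSI | ND


@dataclass
class CohortSpec:
    """Cohort size and spectrum parameters (defaults = study conditions)."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {
            FCCTX: 153, UNSELECTED: 548, YOUNG_ONSET: 333,
            PMMR: 68, DMMR: 129, CONTROL: 93,
        }
    )
    n_qc_fail: int = 6
    tier1_spectrum: dict[str, int] = field(
        default_factory=lambda: {
            NONSENSE: 29, FRAMESHIFT: 43, SPLICE_SITE: 13,
            INITIATOR_CODON: 6, STOP_LOSS: 1,
        }
    )
    n_missense: int = 658
    n_pathogenic_side: int = 13  # pathogenic + likely pathogenic missense
    n_benign_side: int = 61  # not/likely-not pathogenic missense
    n_freq_benign: int = 30  # of the benign side, called on frequency alone
    n_vus_damaging: int = 144  # VUS with REVEL >= cutoff
    n_inframe_indel: int = 17
    n_synonymous: int = 120
    n_intronic: int = 120
    n_maf_excluded: int = 40  # decoys at >= 5% in some population
    n_low_dp: int = 10
    n_low_gq: int = 10
    afr_restricted_fraction: float = 0.10  # variants seen only in African-ancestry panels
    coverage_sigma: float = 0.10
    mean_depth: float = 100.0
    plant_multivariant: bool = True
    plant_cnvs: bool = True

    def validate(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if self.n_pathogenic_side + self.n_benign_side > self.n_missense:
            raise ValueError("missense class design exceeds n_missense")
        if self.n_freq_benign > self.n_benign_side:
            raise ValueError("n_freq_benign exceeds n_benign_side")
        n_vus = self.n_missense - self.n_pathogenic_side - self.n_benign_side
        if self.n_vus_damaging > n_vus:
            raise ValueError("n_vus_damaging exceeds the VUS count")


@dataclass
class TruthSet:
    """Planted ground truth: what the pipeline is expected to recover."""

    variants: pd.DataFrame  # unique variants with intended fate
    carriers: pd.DataFrame  # per (sample, variant) instance with expected fate
    cnvs: pd.DataFrame  # planted coverage events
    qc_fail: pd.DataFrame  # planted QC failures with reasons
    multi: pd.DataFrame  # planted homozygote / compound-het / multi-gene cases

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.variants.to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)
        self.carriers.to_csv(outdir / "truth_carriers.tsv", sep="\t", index=False)
        self.cnvs.to_csv(outdir / "truth_cnvs.tsv", sep="\t", index=False)
        self.qc_fail.to_csv(outdir / "truth_qc_fail.tsv", sep="\t", index=False)
        self.multi.to_csv(outdir / "truth_multi.tsv", sep="\t", index=False)


@dataclass
class CohortBundle:
    samples: list[SampleMeta]
    targets: list[TargetInterval]
    variants: list[VariantRecord]  # per-sample instances (the VCF content)
    frequencies: PopulationFrequencyTable
    evidence: dict[str, AnnotationEvidence]
    coverage: CoverageMatrix | None
    truth: TruthSet

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row = {
                "sample_id": s.sample_id,
                "group": s.group,
                "eligibility": ",".join(s.eligibility),
                "ethnicity": s.ethnicity,
                "age_at_dx": "" if s.age_at_dx is None else s.age_at_dx,
                "ascertainment": s.ascertainment,
                "cov10x": round(s.cov10x, 4),
                "cov40x": round(s.cov40x, 4),
                "concordance": round(s.concordance, 4),
                "msi": s.msi,
            }
            for protein, result in s.ihc:
                row[f"ihc_{protein.lower()}"] = result
            rows.append(row)
        return pd.DataFrame(rows)

    def evidence_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.evidence):
            ev = self.evidence[key]
            rows.append(
                {
                    "variant_key": key,
                    "insight_class": "" if ev.insight_class is None else ev.insight_class,
                    "clinvar_class": ev.clinvar_class or "",
                    "clinvar_stars": "" if ev.clinvar_stars is None else ev.clinvar_stars,
                    "hgmd": int(ev.hgmd),
                    "internal_class": ev.internal_class or "",
                    "internal_review_year": ""
                    if ev.internal_review_year is None
                    else ev.internal_review_year,
                    "revel": "" if ev.revel is None else round(ev.revel, 4),
                    "max_maf": round(ev.max_maf, 6),
                }
            )
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        """Write every artifact (VCF, tables, matrix, truth) to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.metadata_frame().to_csv(outdir / "samples.tsv", sep="\t", index=False)
        write_targets(self.targets, outdir / "targets.bed")
        write_vcf(self, outdir / "cohort.vcf")
        self.frequencies.write(outdir / "frequencies.tsv")
        self.evidence_frame().to_csv(outdir / "evidence.tsv", sep="\t", index=False)
        if self.coverage is not None:
            self.coverage.write(outdir / "coverage.tsv")
        self.truth.write(outdir)


# ---------------------------------------------------------------------------
# samples


def _make_samples(spec: CohortSpec, rng: np.random.Generator) -> tuple[list[SampleMeta], pd.DataFrame]:
    samples: list[SampleMeta] = []
    qc_rows: list[dict[str, object]] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"s{counter:05d}"

    def base_sample(group: str, qc_fail_reasons: tuple[str, ...]) -> SampleMeta:
        ethnicity = ETHNICITIES[rng.choice(4, p=ETHNICITY_PROBS)]
        if group == CONTROL:
            age = None
        elif group == YOUNG_ONSET:
            age = int(rng.integers(18, 50))
        elif group == PMMR:
            age = int(np.clip(round(rng.normal(62, 7)), 50, 90))
        else:
            age = int(np.clip(round(rng.normal(48, 12)), 16, 90))
        eligibility = [group]
        if group in GROUP_PRIORITY:
            lower = GROUP_PRIORITY[GROUP_PRIORITY.index(group) + 1 :]
            if lower and rng.random() < 0.15:
                eligibility.append(str(rng.choice(list(lower))))
        cov10x = float(rng.uniform(0.96, 1.0))
        cov40x = float(rng.uniform(0.70, 0.95))
        conc = float(rng.uniform(0.97, 1.0))
        if qc_fail_reasons:
            if "low_cov_10x" in qc_fail_reasons:
                cov10x = float(rng.uniform(0.80, 0.949))
            if "low_cov_40x" in qc_fail_reasons:
                cov40x = float(rng.uniform(0.30, 0.599))
            if "low_concordance" in qc_fail_reasons:
                conc = float(rng.uniform(0.85, 0.949))
        if group == DMMR:
            lost = str(rng.choice(["MLH1", "MSH2", "MSH6", "PMS2"]))
            ihc = tuple(
                (p, "Loss" if p == lost else "Normal") for p in ("MLH1", "MSH2", "MSH6", "PMS2")
            )
            msi = "MSI"
        elif group in (PMMR, FCCTX):
            ihc = tuple((p, "Normal") for p in ("MLH1", "MSH2", "MSH6", "PMS2"))
            msi = "MSS"
        else:
            ihc = tuple((p, "ND") for p in ("MLH1", "MSH2", "MSH6", "PMS2"))
            msi = "ND"
        return SampleMeta(
            sample_id=new_id(),
            eligibility=tuple(eligibility),
            group=group,
            ethnicity=ethnicity,
            age_at_dx=age,
            ascertainment="population" if group == CONTROL or rng.random() < 0.74 else "clinic",
            cov10x=cov10x,
            cov40x=cov40x,
            concordance=conc,
            ihc=ihc,
            msi=msi,
        )

    for group in GROUP_DISPLAY_ORDER:
        for _ in range(spec.group_sizes.get(group, 0)):
            samples.append(base_sample(group, ()))
    fail_reason_cycle = (
        ("low_cov_10x",), ("low_cov_40x",), ("low_concordance",),
        ("low_cov_10x", "low_cov_40x"),
    )
    case_groups = [g for g in GROUP_DISPLAY_ORDER if g != CONTROL and spec.group_sizes.get(g, 0) > 0]
    for k in range(spec.n_qc_fail):
        group = case_groups[k % len(case_groups)] if case_groups else CONTROL
        reasons = fail_reason_cycle[k % len(fail_reason_cycle)]
        s = base_sample(group, reasons)
        samples.append(s)
        qc_rows.append({"sample_id": s.sample_id, "reasons": ",".join(reasons)})
    qc_df = pd.DataFrame(qc_rows, columns=["sample_id", "reasons"])
    return samples, qc_df


# ---------------------------------------------------------------------------
# variants


_BASES = ("A", "C", "G", "T")


class _PositionAllocator:
    """Unique genomic positions inside panel targets, by consequence type."""

    def __init__(self, targets: list[TargetInterval], rng: np.random.Generator):
        self.by_gene = targets_by_gene(targets)
        self.rng = rng
        self.used: set[tuple[str, int]] = set()

    def allocate(self, gene: str, consequence: str) -> tuple[str, int]:
        ts = self.by_gene[gene]
        for _ in range(1000):
            t = ts[int(self.rng.integers(len(ts)))]
            if consequence == SPLICE_SITE:
                # 1-2 intronic bases beyond a boundary
                off = int(self.rng.integers(1, 3))
                pos = t.exon_end - 1 + off if self.rng.random() < 0.5 else t.exon_start - off
            elif consequence == INTRONIC:
                off = int(self.rng.integers(3, 31))
                pos = t.exon_end - 1 + off if self.rng.random() < 0.5 else t.exon_start - off
            else:
                pos = int(self.rng.integers(t.exon_start + 3, t.exon_end - 6))
            key = (t.chrom, pos)
            if key not in self.used:
                self.used.add(key)
                return t.chrom, pos
        raise RuntimeError(f"could not place a variant in {gene}")  # pragma: no cover


def _alleles(consequence: str, rng: np.random.Generator) -> tuple[str, str]:
    ref = str(rng.choice(_BASES))
    if consequence == FRAMESHIFT:
        return ref + "".join(rng.choice(_BASES, 1)), ref  # 1 bp deletion
    if consequence == INFRAME_INDEL:
        return ref + "".join(rng.choice(_BASES, 3)), ref  # 3 bp deletion
    alt = str(rng.choice([b for b in _BASES if b != ref]))
    return ref, alt


def _protein_label(consequence: str, idx: int) -> str:
    tag = {
        NONSENSE: "Ter", FRAMESHIFT: "fs", SPLICE_SITE: "splice",
        INITIATOR_CODON: "Met1?", STOP_LOSS: "ext", MISSENSE: "mis",
        INFRAME_INDEL: "del", SYNONYMOUS: "syn", INTRONIC: "intron",
    }[consequence]
    return f"p.{tag}{idx}"


@dataclass
class _PlannedVariant:
    gene: str
    consequence: str
    intended_tier: str  # TIER1 | TIER2 | EXCLUDED | FILTERED
    maf_band: str  # novel | rare | benign | excluded
    intended_class: str = ""
    intended_rule: str = ""
    intended_damaging: bool = False
    revel: float | None = None
    force_fail: str = ""  # "", "dp", "gq", "qc_sample"


def _plan_missense(spec: CohortSpec, genes: list[str], rng: np.random.Generator) -> list[_PlannedVariant]:
    """Design the missense evidence database to yield the intended tallies."""
    plans: list[_PlannedVariant] = []
    n_vus = spec.n_missense - spec.n_pathogenic_side - spec.n_benign_side

    # reserved qualifying variants so multi-variant carriers can be planted
    reserved = [("MUTYH", PATHOGENIC, INSIGHT), ("MUTYH", PATHOGENIC, INSIGHT)]
    reserved_damaging = ["MUTYH", "MUTYH", "MUTYH", "MUTYH", "PMS1", "PMS1"]

    def pick_gene() -> str:
        return str(rng.choice(genes))

    # pathogenic side: InSiGHT class 4/5, recent internal, or 2-star ClinVar
    for k in range(spec.n_pathogenic_side):
        if spec.plant_multivariant and k < len(reserved):
            gene, cls, rule = reserved[k]
        else:
            gene = pick_gene()
            rule = (INSIGHT, INTERNAL_RECENT, CLINVAR_2STAR)[k % 3]
            cls = PATHOGENIC if k % 2 == 0 else LIKELY_PATHOGENIC
        plans.append(
            _PlannedVariant(gene, MISSENSE, "TIER2", "novel" if k % 2 else "rare",
                            cls, rule, revel=float(rng.uniform(0.3, 1.0)))
        )
    # benign side: first the frequency-benign band, then database benign
    for k in range(spec.n_benign_side):
        if k < spec.n_freq_benign:
            cls, rule, band = NOT_PATHOGENIC, FREQ_BENIGN, "benign"
        else:
            rule = (INSIGHT, INTERNAL_RECENT, CLINVAR_2STAR)[k % 3]
            cls = NOT_PATHOGENIC if k % 2 == 0 else LIKELY_NOT_PATHOGENIC
            band = "rare"
        plans.append(
            _PlannedVariant(pick_gene(), MISSENSE, "TIER2", band, cls, rule,
                            revel=float(rng.uniform(0.0, 1.0)))
        )
    # VUS: damaging first (REVEL above cutoff), reserving a few for MUTYH/PMS1
    for k in range(n_vus):
        damaging = k < spec.n_vus_damaging
        if spec.plant_multivariant and damaging and k < len(reserved_damaging):
            gene = reserved_damaging[k]
        else:
            gene = pick_gene()
        r = k % 5
        if r in (0, 1):
            rule = NO_ANNOTATION
        elif r == 2:
            rule = REVIEW_REQUIRED  # internal pre-2015
        elif r == 3:
            rule = REVIEW_REQUIRED  # ClinVar < 2 stars
        else:
            rule = INSIGHT  # InSiGHT class 3 stays uncertain
        revel = float(rng.uniform(0.5, 1.0)) if damaging else float(rng.uniform(0.0, 0.499))
        plans.append(
            _PlannedVariant(gene, MISSENSE, "TIER2", "novel" if k % 3 else "rare",
                            VUS, rule, intended_damaging=damaging, revel=revel)
        )
    return plans


def _evidence_for_plan(
    plan: _PlannedVariant, key: str, max_maf: float, rng: np.random.Generator, variant_index: int
) -> AnnotationEvidence | None:
    """Build an evidence row consistent with the intended precedence branch."""
    cls, rule = plan.intended_class, plan.intended_rule
    revel = plan.revel if plan.consequence == MISSENSE else None
    if not rule or rule == NO_ANNOTATION:
        if plan.consequence in (MISSENSE, INFRAME_INDEL):
            return AnnotationEvidence(key, revel=revel, max_maf=max_maf)
        return None  # non-Tier-2 variants mostly lack curation
    if rule == FREQ_BENIGN:
        # nothing else needed; occasionally add a (shadowed) database entry
        insight = 5 if variant_index % 7 == 0 else None
        return AnnotationEvidence(key, insight_class=insight, revel=revel, max_maf=max_maf)
    if rule == INSIGHT:
        inv = {PATHOGENIC: 5, LIKELY_PATHOGENIC: 4, VUS: 3,
               LIKELY_NOT_PATHOGENIC: 2, NOT_PATHOGENIC: 1}
        return AnnotationEvidence(key, insight_class=inv[cls], revel=revel, max_maf=max_maf)
    if rule == INTERNAL_RECENT:
        return AnnotationEvidence(
            key, internal_class=cls, internal_review_year=int(rng.integers(2015, 2018)),
            revel=revel, max_maf=max_maf,
        )
    if rule == CLINVAR_2STAR:
        return AnnotationEvidence(
            key, clinvar_class=cls, clinvar_stars=int(rng.integers(2, 4)),
            revel=revel, max_maf=max_maf,
        )
    if rule == REVIEW_REQUIRED:
        mode = variant_index % 3
        if mode == 0:
            return AnnotationEvidence(
                key, internal_class=VUS, internal_review_year=int(rng.integers(2005, 2015)),
                revel=revel, max_maf=max_maf,
            )
        if mode == 1:
            return AnnotationEvidence(
                key, clinvar_class=VUS, clinvar_stars=int(rng.integers(0, 2)),
                revel=revel, max_maf=max_maf,
            )
        return AnnotationEvidence(key, hgmd=True, revel=revel, max_maf=max_maf)
    raise ValueError(f"unknown rule {rule!r}")  # pragma: no cover


def _draw_frequencies(
    plan: _PlannedVariant, key: str, ethnic_restricted: bool,
    freqs: PopulationFrequencyTable, rng: np.random.Generator,
) -> float:
    """Populate the frequency table for one variant; returns the max AF."""
    if plan.maf_band == "novel":
        return 0.0
    if plan.maf_band == "excluded":
        lo, hi = 0.05, 0.30
    elif plan.maf_band == "benign":
        lo, hi = 0.02, 0.0499
    else:  # rare
        lo, hi = 1e-4, 0.015
    max_af = float(rng.uniform(lo, hi))
    pairs = (
        list(AFR_POPULATIONS)
        if ethnic_restricted
        else [(s, p) for s, pops in POPULATIONS.items() for p in pops]
    )
    k = int(rng.integers(1, min(3, len(pairs)) + 1))
    chosen = [pairs[i] for i in rng.choice(len(pairs), size=k, replace=False)]
    freqs.add(key, chosen[0][0], chosen[0][1], max_af)
    for src, pop in chosen[1:]:
        freqs.add(key, src, pop, float(rng.uniform(0.0, max_af)))
    return max_af


# ---------------------------------------------------------------------------
# coverage


def _base_coverage(
    sample_ids: list[str], targets: list[TargetInterval], spec: CohortSpec,
    rng: np.random.Generator,
) -> CoverageMatrix:
    n, m = len(sample_ids), len(targets)
    sample_factor = rng.lognormal(0.0, 0.15, size=(n, 1))
    target_eff = rng.lognormal(0.0, 0.5, size=(1, m))
    noise = rng.lognormal(0.0, spec.coverage_sigma, size=(n, m))
    depths = spec.mean_depth * sample_factor * target_eff * noise
    df = pd.DataFrame(depths, index=sample_ids, columns=[t.target_id for t in targets])
    return CoverageMatrix(df, targets)


def inject_cnv(
    matrix: CoverageMatrix,
    sample_id: str,
    gene: str,
    target_range: tuple[int, int],
    copy_number: int,
    rng: np.random.Generator | None = None,
    noise_sigma: float = 0.05,
) -> tuple[CoverageMatrix, dict[str, object]]:
    """Scale a sample's depth over a gene's target range by copy_number/2.

    ``target_range`` is (start, end] over the gene's own target list,
    0-based half-open. Returns the modified matrix and a truth entry; a
    diploid injection (copy_number=2) leaves the matrix unchanged and
    yields a no-effect truth entry.
    """
    if copy_number not in (0, 1, 2, 3, 4):
        raise ValueError("copy_number must be in 0..4")
    if sample_id not in matrix.depths.index:
        raise ValueError(f"sample {sample_id!r} not in coverage matrix")
    gene_targets = [t for t in matrix.targets if t.gene == gene]
    lo, hi = target_range
    if not (0 <= lo < hi <= len(gene_targets)):
        raise ValueError(f"target range {target_range} outside {gene} ({len(gene_targets)} targets)")
    truth = {
        "sample_id": sample_id, "gene": gene, "start_index": lo, "end_index": hi,
        "copy_number": copy_number, "n_targets": hi - lo,
        "expected_call": "deletion" if copy_number < 2 else ("amplification" if copy_number > 2 else "none"),
    }
    if copy_number == 2:
        return matrix, truth
    rng = rng or np.random.default_rng(0)
    out = matrix.copy()
    cols = [t.target_id for t in gene_targets[lo:hi]]
    scale = (copy_number / 2.0) * rng.lognormal(0.0, noise_sigma, size=len(cols))
    if copy_number == 0:
        scale = 0.01 * rng.lognormal(0.0, noise_sigma, size=len(cols))  # residual mismapping
    out.depths.loc[sample_id, cols] = out.depths.loc[sample_id, cols].to_numpy() * scale
    return out, truth


# ---------------------------------------------------------------------------
# the generator


def generate_cohort(
    cfg: PipelineConfig | None = None,
    spec: CohortSpec | None = None,
    seed: int | None = None,
) -> CohortBundle:
    """Build a deterministic synthetic cohort bundle with embedded truth."""
    cfg = cfg or PipelineConfig()
    spec = spec or CohortSpec()
    spec.validate()
    if seed is None:
        seed = cfg.seed
    ss = np.random.SeedSequence(seed)
    meta_rng, var_rng, carrier_rng, cov_rng, cnv_rng = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    samples, qc_df = _make_samples(spec, meta_rng)
    targets = build_panel()
    genes = list(PANEL_GENES)
    alloc = _PositionAllocator(targets, var_rng)

    retained = [s for s in samples if s.sample_id not in set(qc_df["sample_id"])]
    retained_cases = [s for s in retained if s.group != CONTROL]
    qc_fail_ids = list(qc_df["sample_id"])

    # ---- plan unique variants ------------------------------------------------
    plans: list[_PlannedVariant] = []
    for conseq, n in spec.tier1_spectrum.items():
        for k in range(n):
            plans.append(_PlannedVariant(str(var_rng.choice(genes)), conseq, "TIER1",
                                         "novel" if k % 2 else "rare"))
    plans.extend(_plan_missense(spec, genes, var_rng))
    for k in range(spec.n_inframe_indel):
        rule = (INSIGHT, NO_ANNOTATION, REVIEW_REQUIRED)[k % 3]
        cls = PATHOGENIC if (rule == INSIGHT and k == 0) else (VUS if rule != INSIGHT else NOT_PATHOGENIC)
        plans.append(_PlannedVariant(str(var_rng.choice(genes)), INFRAME_INDEL, "TIER2",
                                     "rare", cls, rule))
    for _ in range(spec.n_synonymous):
        plans.append(_PlannedVariant(str(var_rng.choice(genes)), SYNONYMOUS, "EXCLUDED", "rare"))
    for _ in range(spec.n_intronic):
        plans.append(_PlannedVariant(str(var_rng.choice(genes)), INTRONIC, "EXCLUDED", "rare"))
    for k in range(spec.n_maf_excluded):
        conseq = (NONSENSE, MISSENSE, FRAMESHIFT)[k % 3]
        plans.append(_PlannedVariant(str(var_rng.choice(genes)), conseq, "FILTERED", "excluded"))
    for _ in range(spec.n_low_dp):
        plans.append(_PlannedVariant(str(var_rng.choice(genes)), NONSENSE, "FILTERED",
                                     "novel", force_fail="dp"))
    for _ in range(spec.n_low_gq):
        plans.append(_PlannedVariant(str(var_rng.choice(genes)), MISSENSE, "FILTERED",
                                     "novel", force_fail="gq"))
    for _ in range(min(spec.n_qc_fail, len(qc_fail_ids))):
        plans.append(_PlannedVariant(str(var_rng.choice(genes)), NONSENSE, "FILTERED",
                                     "novel", force_fail="qc_sample"))

    # ---- realize unique variants, frequencies and evidence -------------------
    freqs = PopulationFrequencyTable()
    evidence: dict[str, AnnotationEvidence] = {}
    truth_var_rows: list[dict[str, object]] = []
    realized: list[tuple[_PlannedVariant, VariantRecord]] = []  # template records
    for idx, plan in enumerate(plans):
        chrom, pos = alloc.allocate(plan.gene, plan.consequence)
        ref, alt = _alleles(plan.consequence, var_rng)
        key = f"{chrom}:{pos}:{ref}:{alt}"
        restricted = var_rng.random() < spec.afr_restricted_fraction
        max_af = _draw_frequencies(plan, key, restricted, freqs, var_rng)
        ev = _evidence_for_plan(plan, key, max_af, var_rng, idx)
        if ev is not None:
            evidence[key] = ev
        template = VariantRecord(
            sample_id="", chrom=chrom, pos=pos, ref=ref, alt=alt,
            gene=plan.gene, transcript=f"NM_{plan.gene}",
            consequence=plan.consequence,
            protein_change=_protein_label(plan.consequence, idx),
            dp=0, gq=0, zygosity="het",
        )
        realized.append((plan, template))
        truth_var_rows.append(
            {
                "variant_key": key, "gene": plan.gene, "consequence": plan.consequence,
                "intended_tier": plan.intended_tier, "maf_band": plan.maf_band,
                "intended_class": plan.intended_class, "intended_rule": plan.intended_rule,
                "intended_damaging": plan.intended_damaging,
                "force_fail": plan.force_fail,
            }
        )

    # ---- carriers ------------------------------------------------------------
    case_ids = [s.sample_id for s in retained_cases]
    control_ids = [s.sample_id for s in retained if s.group == CONTROL]
    instances: list[VariantRecord] = []
    truth_carrier_rows: list[dict[str, object]] = []
    qc_plan_iter = iter(qc_fail_ids)

    def add_instance(template: VariantRecord, sample_id: str, zygosity: str,
                     dp: int, gq: int, fate: str) -> None:
        rec = VariantRecord(
            sample_id=sample_id, chrom=template.chrom, pos=template.pos,
            ref=template.ref, alt=template.alt, gene=template.gene,
            transcript=template.transcript, consequence=template.consequence,
            protein_change=template.protein_change, dp=dp, gq=gq, zygosity=zygosity,
        )
        instances.append(rec)
        truth_carrier_rows.append(
            {"sample_id": sample_id, "variant_key": rec.variant_key,
             "zygosity": zygosity, "expected_fate": fate}
        )

    def draw_dp_gq(fail: str) -> tuple[int, int]:
        if fail == "dp":
            return int(carrier_rng.integers(5, cfg.dp_min)), int(carrier_rng.integers(60, 100))
        if fail == "gq":
            return int(carrier_rng.integers(40, 200)), int(carrier_rng.integers(5, cfg.gq_min))
        return int(carrier_rng.integers(40, 200)), int(carrier_rng.integers(60, 100))

    for plan, template in realized:
        if plan.force_fail == "qc_sample":
            sid = next(qc_plan_iter)
            dp, gq = draw_dp_gq("")
            add_instance(template, sid, "het", dp, gq, "excluded_sample")
            continue
        n_extra = int(carrier_rng.choice([0, 1, 2, 3], p=[0.88, 0.07, 0.03, 0.02]))
        n_carriers = 1 + n_extra
        pool = control_ids if (carrier_rng.random() < 0.05 and control_ids) else case_ids
        chosen = carrier_rng.choice(len(pool), size=min(n_carriers, len(pool)), replace=False)
        for c in chosen:
            sid = pool[int(c)]
            dp, gq = draw_dp_gq(plan.force_fail)
            zyg = "hom_alt" if carrier_rng.random() < 0.02 else "het"
            if plan.force_fail == "dp":
                fate = "excluded_dp"
            elif plan.force_fail == "gq":
                fate = "excluded_gq"
            elif plan.maf_band == "excluded":
                fate = "excluded_maf"
            elif plan.intended_tier == "EXCLUDED":
                fate = "excluded_consequence"
            else:
                fate = "retained"
            add_instance(template, sid, zyg, dp, gq, fate)

    # ---- planted multi-variant carriers -------------------------------------
    multi_rows: list[dict[str, object]] = []
    if spec.plant_multivariant:
        qualifying_by_gene: dict[str, list[tuple[_PlannedVariant, VariantRecord]]] = {}
        for plan, template in realized:
            if plan.consequence == MISSENSE and (
                plan.intended_class in (PATHOGENIC, LIKELY_PATHOGENIC) or plan.intended_damaging
            ):
                qualifying_by_gene.setdefault(plan.gene, []).append((plan, template))
        mutyh = qualifying_by_gene.get("MUTYH", [])
        pms1 = qualifying_by_gene.get("PMS1", [])
        carrier_ids = {r["sample_id"] for r in truth_carrier_rows}
        fresh = [s.sample_id for s in retained_cases if s.sample_id not in carrier_ids]

        def plant(gene: str, pair: list[tuple[_PlannedVariant, VariantRecord]], pattern: str) -> None:
            if not fresh:
                return
            sid = fresh.pop(0)
            if pattern == "homozygous":
                _, template = pair[0]
                dp, gq = draw_dp_gq("")
                add_instance(template, sid, "hom_alt", dp, gq, "retained")
                keys = (template.variant_key, template.variant_key)
            else:
                keys_list = []
                for _, template in pair:
                    dp, gq = draw_dp_gq("")
                    add_instance(template, sid, "het", dp, gq, "retained")
                    keys_list.append(template.variant_key)
                keys = tuple(keys_list)
            multi_rows.append(
                {"sample_id": sid, "gene": gene, "pattern": pattern,
                 "variant_keys": ";".join(keys)}
            )

        if len(mutyh) >= 2:
            for k in range(5):
                plant("MUTYH", [mutyh[k % len(mutyh)]], "homozygous")
            for k in range(5):
                a, b = mutyh[k % len(mutyh)], mutyh[(k + 1) % len(mutyh)]
                plant("MUTYH", [a, b], "suspected_compound_het")
        if pms1:
            plant("PMS1", [pms1[0]], "homozygous")
        if mutyh and pms1:
            for k in range(3):
                plant("", [mutyh[k % len(mutyh)], pms1[k % len(pms1)]], "multi_gene")

    # ---- coverage matrix and planted deletions -------------------------------
    coverage = None
    cnv_rows: list[dict[str, object]] = []
    if spec.plant_cnvs:
        all_ids = [s.sample_id for s in samples]
        coverage = _base_coverage(all_ids, targets, spec, cov_rng)
        gene_sizes = {g: len(ts) for g, ts in targets_by_gene(targets).items()}
        # multi-exon heterozygous deletions (one homozygous), then two
        # single-target events that the default caller is expected to miss
        del_plan = [
            ("MLH1", 1, 4), ("MLH1", 1, 5), ("MSH2", 1, 3), ("MSH2", 1, 6),
            ("MSH6", 1, 3), ("MLH1", 0, 2), ("MSH2", 1, 4), ("MSH6", 1, 10),
            ("MLH1", 1, 1), ("MSH2", 1, 1),
        ]
        pool = [s.sample_id for s in retained_cases]
        picked = cnv_rng.choice(len(pool), size=len(del_plan), replace=False)
        for (gene, cn, width), c in zip(del_plan, picked):
            size = gene_sizes[gene]
            width = min(width, size)
            lo = int(cnv_rng.integers(0, size - width + 1))
            coverage, truth_entry = inject_cnv(
                coverage, pool[int(c)], gene, (lo, lo + width), cn, rng=cnv_rng
            )
            truth_entry["expected_detected"] = bool(width >= 2)
            cnv_rows.append(truth_entry)

    truth = TruthSet(
        variants=pd.DataFrame(truth_var_rows),
        carriers=pd.DataFrame(truth_carrier_rows),
        cnvs=pd.DataFrame(
            cnv_rows,
            columns=["sample_id", "gene", "start_index", "end_index", "copy_number",
                     "n_targets", "expected_call", "expected_detected"],
        ),
        qc_fail=qc_df,
        multi=pd.DataFrame(multi_rows, columns=["sample_id", "gene", "pattern", "variant_keys"]),
    )
    instances.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt, v.sample_id))
    return CohortBundle(
        samples=samples, targets=targets, variants=instances,
        frequencies=freqs, evidence=evidence, coverage=coverage, truth=truth,
    )


# ---------------------------------------------------------------------------
# VCF writing


def write_vcf(bundle: CohortBundle, path: str | Path) -> None:
    """Write the per-sample variant instances as a multi-sample VCF 4.2.

    Positions convert back to 1-based; genotype columns carry GT:DP:GQ with
    a constant reference-call filler for non-carriers. Consequence
    annotation travels in INFO (GENE/CSQ/TX/PCH), mirroring a pre-annotated
    VCF from an external effect predictor.
    """
    sample_ids = [s.sample_id for s in bundle.samples]
    col_of = {sid: i for i, sid in enumerate(sample_ids)}
    by_site: dict[tuple[str, int, str, str], list[VariantRecord]] = {}
    for v in bundle.variants:
        by_site.setdefault((v.chrom, v.pos, v.ref, v.alt), []).append(v)

    chroms = sorted({t.chrom for t in bundle.targets}, key=lambda c: (len(c), c))
    lines = [
        "##fileformat=VCFv4.2",
        "##source=paneltriage-simulator",
        *[f"##contig=<ID={c}>" for c in chroms],
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Panel gene">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence on the canonical transcript">',
        '##INFO=<ID=TX,Number=1,Type=String,Description="Canonical transcript">',
        '##INFO=<ID=PCH,Number=1,Type=String,Description="Protein change label">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids),
    ]
    filler = "0/0:60:80"
    for (chrom, pos, ref, alt) in sorted(by_site, key=lambda k: (k[0], k[1], k[2], k[3])):
        carriers = by_site[(chrom, pos, ref, alt)]
        v0 = carriers[0]
        cells = [filler] * len(sample_ids)
        for v in carriers:
            gt = "1/1" if v.zygosity == "hom_alt" else "0/1"
            cells[col_of[v.sample_id]] = f"{gt}:{v.dp}:{v.gq}"
        info = f"GENE={v0.gene};CSQ={v0.consequence};TX={v0.transcript};PCH={v0.protein_change}"
        lines.append(
            f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t100\tPASS\t{info}\tGT:DP:GQ\t" + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")
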