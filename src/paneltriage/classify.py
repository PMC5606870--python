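"""Evidence-based pathogenicity classification of Tier 2 variants.

Each retained Tier 2 variant (missense or in-frame indel) receives exactly
one class from a fixed-precedence walk over the available evidence:

1. ``FREQ_BENIGN`` — frequency in the 2-5% band in any reference
   population: called not pathogenic on frequency alone, nothing else is
   consulted.
2. ``INSIGHT`` — an InSiGHT class (the expert-curated mismatch-repair gene
   database) takes precedence over all other databases: class 5 pathogenic,
   4 likely pathogenic, 3 uncertain, 2 likely not pathogenic, 1 not
   pathogenic.
3. ``INTERNAL_RECENT`` — an internal clinical-laboratory classification
   reviewed in 2015 or later.
4. ``CLINVAR_2STAR`` — a ClinVar assertion with a review status of at
   least two stars (multiple concordant submitters).
5. ``REVIEW_REQUIRED`` — weaker evidence only (internal classification
   last reviewed before 2015, ClinVar below two stars, or presence in HGMD
   alone): the variant stays a VUS and is flagged for human ACMG review;
   that review itself is outside this pipeline.
6. ``NO_ANNOTATION`` — nothing known: VUS.

REVEL (0-1 ensemble missense deleteriousness score) is then layered onto
VUS calls only: a VUS with REVEL >= 0.5 is flagged predicted damaging.
REVEL never changes a class, and in-frame indels (which have no REVEL
score) are never flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import PipelineConfig
from .decisions import DecisionLog
from .tiering import (
    INFRAME_INDEL,
    MISSENSE,
    TIER2,
    TierAssignment,
    VariantRecord,
)
from .util import round_half_even

# Classes
PATHOGENIC = "PATHOGENIC"
LIKELY_PATHOGENIC = "LIKELY_PATHOGENIC"
VUS = "VUS"
LIKELY_NOT_PATHOGENIC = "LIKELY_NOT_PATHOGENIC"
NOT_PATHOGENIC = "NOT_PATHOGENIC"
CLASSES = (PATHOGENIC, LIKELY_PATHOGENIC, VUS, LIKELY_NOT_PATHOGENIC, NOT_PATHOGENIC)

# Precedence branches
FREQ_BENIGN = "FREQ_BENIGN"
INSIGHT = "INSIGHT"
INTERNAL_RECENT = "INTERNAL_RECENT"
CLINVAR_2STAR = "CLINVAR_2STAR"
REVIEW_REQUIRED = "REVIEW_REQUIRED"
NO_ANNOTATION = "NO_ANNOTATION"
RULES = (FREQ_BENIGN, INSIGHT, INTERNAL_RECENT, CLINVAR_2STAR, REVIEW_REQUIRED, NO_ANNOTATION)

INSIGHT_CLASS_MAP = {
    5: PATHOGENIC,
    4: LIKELY_PATHOGENIC,
    3: VUS,
    2: LIKELY_NOT_PATHOGENIC,
    1: NOT_PATHOGENIC,
}

INTERNAL_REVIEW_YEAR = 2015


@dataclass(frozen=True)
class AnnotationEvidence:
    """External evidence snapshot for one variant (absent fields are None)."""

    variant_key: str
    insight_class: int | None = None
    clinvar_class: str | None = None
    clinvar_stars: int | None = None
    hgmd: bool = False
    internal_class: str | None = None
    internal_review_year: int | None = None
    revel: float | None = None
    max_maf: float = 0.0

    def __post_init__(self) -> None:
        if self.insight_class is not None and self.insight_class not in INSIGHT_CLASS_MAP:
            raise ValueError(f"insight_class must be 1..5, got {self.insight_class}")
        if self.clinvar_class is not None and self.clinvar_class not in CLASSES:
            raise ValueError(f"bad clinvar_class {self.clinvar_class!r}")
        if self.clinvar_stars is not None and self.clinvar_class is None:
            raise ValueError("clinvar_stars without clinvar_class")
        if self.clinvar_stars is not None and not (0 <= self.clinvar_stars <= 4):
            raise ValueError("clinvar_stars must be 0..4")
        if self.internal_class is not None and self.internal_class not in CLASSES:
            raise ValueError(f"bad internal_class {self.internal_class!r}")
        if self.revel is not None and not (0.0 <= self.revel <= 1.0):
            raise ValueError("revel must be in [0,1]")
        if not (0.0 <= self.max_maf <= 1.0):
            raise ValueError("max_maf must be in [0,1]")


@dataclass(frozen=True)
class Classification:
    variant_key: str
    cls: str
    rule_fired: str
    predicted_damaging: bool = False
    review_flag: bool = False

    def __post_init__(self) -> None:
        if self.cls not in CLASSES:
            raise ValueError(f"bad class {self.cls!r}")
        if self.rule_fired not in RULES:
            raise ValueError(f"bad rule {self.rule_fired!r}")
        if self.predicted_damaging and self.cls != VUS:
            raise ValueError("predicted_damaging is defined for VUS only")


def classify_missense(
    v: VariantRecord,
    ev: AnnotationEvidence | None,
    cfg: PipelineConfig,
    log: DecisionLog | None = None,
) -> Classification:
    """Assign a pathogenicity class by fixed precedence, first match wins."""
    key = v.variant_key
    if ev is None:
        # no evidence row at all: same outcome as an all-absent row, logged
        if log is not None:
            log.record(v.sample_id, key, "classify", "missing_evidence_row", VUS)
        ev = AnnotationEvidence(variant_key=key)
    if cfg.maf_benign_low <= ev.max_maf < cfg.maf_exclude:
        result = Classification(key, NOT_PATHOGENIC, FREQ_BENIGN)
    elif ev.insight_class is not None:
        result = Classification(key, INSIGHT_CLASS_MAP[ev.insight_class], INSIGHT)
    elif (
        ev.internal_class is not None
        and ev.internal_review_year is not None
        and ev.internal_review_year >= INTERNAL_REVIEW_YEAR
    ):
        result = Classification(key, ev.internal_class, INTERNAL_RECENT)
    elif ev.clinvar_stars is not None and ev.clinvar_stars >= 2:
        result = Classification(key, ev.clinvar_class, CLINVAR_2STAR)
    elif ev.internal_class is not None or ev.clinvar_class is not None or ev.hgmd:
        # evidence too weak to adopt automatically: VUS pending human review
        result = Classification(key, VUS, REVIEW_REQUIRED, review_flag=True)
    else:
        result = Classification(key, VUS, NO_ANNOTATION)
    if log is not None:
        log.record(
            v.sample_id, key, "classify", result.rule_fired, result.cls,
            evidence_ref=f"max_maf={ev.max_maf:g}",
        )
    return result


def apply_revel(
    c: Classification,
    ev: AnnotationEvidence | None,
    cfg: PipelineConfig,
    log: DecisionLog | None = None,
    sample_id: str = "",
) -> Classification:
    """Set the predicted-damaging flag on VUS calls; other classes unchanged."""
    if c.cls != VUS:
        return c
    revel = ev.revel if ev is not None else None
    damaging = revel is not None and revel >= cfg.revel_cutoff
    if log is not None:
        outcome = "predicted_damaging" if damaging else "not_damaging"
        rule = "revel_threshold" if revel is not None else "revel_absent"
        log.record(sample_id, c.variant_key, "revel", rule, outcome,
                   evidence_ref="" if revel is None else f"revel={revel:g}")
    return replace(c, predicted_damaging=damaging)


def classify_cohort(
    variants: Iterable[VariantRecord],
    assignments: Sequence[TierAssignment],
    evidence: Mapping[str, AnnotationEvidence],
    cfg: PipelineConfig,
    log: DecisionLog | None = None,
) -> dict[str, Classification]:
    """Classify every unique retained Tier 2 variant; returns key -> verdict.

    Classification operates on unique variants (evidence is per variant,
    not per carrier); missense variants get the REVEL layer, in-frame
    indels flow through the same precedence but are never flagged damaging.
    """
    retained_t2 = {
        a.variant_key for a in assignments if a.retained and a.tier == TIER2
    }
    out: dict[str, Classification] = {}
    seen: set[str] = set()
    for v in variants:
        key = v.variant_key
        if key not in retained_t2 or key in seen:
            continue
        seen.add(key)
        ev = evidence.get(key)
        c = classify_missense(v, ev, cfg, log=log)
        if v.consequence == MISSENSE:
            c = apply_revel(c, ev, cfg, log=log, sample_id=v.sample_id)
        out[key] = c
    return out


def class_tally(
    classifications: Mapping[str, Classification],
    keys: set[str] | None = None,
) -> dict[str, int]:
    """Aggregate tally over unique variants (optionally a key subset).

    Returns pathogenic-side (pathogenic + likely pathogenic), benign-side
    (not pathogenic + likely not pathogenic), VUS, and VUS with the
    predicted-damaging flag.
    """
    sel = [
        c for k, c in classifications.items() if keys is None or k in keys
    ]
    path = sum(1 for c in sel if c.cls in (PATHOGENIC, LIKELY_PATHOGENIC))
    benign = sum(1 for c in sel if c.cls in (NOT_PATHOGENIC, LIKELY_NOT_PATHOGENIC))
    vus = sum(1 for c in sel if c.cls == VUS)
    damaging = sum(1 for c in sel if c.cls == VUS and c.predicted_damaging)
    return {
        "pathogenic_or_likely": path,
        "benign_side": benign,
        "vus": vus,
        "vus_predicted_damaging": damaging,
        "total": len(sel),
    }


def missense_keys(assignments) -> set[str]:
    """Unique retained missense variant keys (the tally denominator)."""
    return {
        a.variant_key
        for a in assignments
        if a.retained and a.tier == TIER2 and a.consequence == MISSENSE
    }


def vus_damaging_percent(tally: Mapping[str, int], ndigits: int = 0) -> float:
    """Share of VUS flagged predicted damaging, as a percentage."""
    if tally["vus"] == 0:
        return 0.0
    return round_half_even(100.0 * tally["vus_predicted_damaging"] / tally["vus"], ndigits)


def tier2_overview(
    assignments: Sequence[TierAssignment],
    classifications: Mapping[str, Classification],
    groups: Mapping[str, str],
    group_sizes: Mapping[str, int],
    group_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per gene x group Tier 2 table: in-frame indels, missense, REVEL-flagged.

    Cells hold ``unique variants (carrier individuals)`` counts; the
    percent column is the share of the group carrying a REVEL-flagged VUS.
    """
    t2 = [a for a in assignments if a.retained and a.tier == TIER2]
    order = list(group_order) if group_order is not None else sorted(group_sizes)
    genes = sorted({a.gene for a in t2})
    damaging_keys = {
        k for k, c in classifications.items() if c.cls == VUS and c.predicted_damaging
    }
    rows = []
    for gene in genes + ["Total"]:
        row: dict[str, object] = {"gene": gene}
        for grp in order:
            cell = [
                a
                for a in t2
                if (gene == "Total" or a.gene == gene) and groups.get(a.sample_id) == grp
            ]
            for label, conseq in (("indel", INFRAME_INDEL), ("missense", MISSENSE)):
                sub = [a for a in cell if a.consequence == conseq]
                row[f"{grp}_{label}_variants"] = len({a.variant_key for a in sub})
                row[f"{grp}_{label}_individuals"] = len({a.sample_id for a in sub})
            dmg = [a for a in cell if a.variant_key in damaging_keys]
            row[f"{grp}_revel_variants"] = len({a.variant_key for a in dmg})
            dmg_carriers = len({a.sample_id for a in dmg})
            row[f"{grp}_revel_individuals"] = dmg_carriers
            size = group_sizes.get(grp, 0)
            row[f"{grp}_pct_revel_carriers"] = (
                round_half_even(100.0 * dmg_carriers / size, 1) if size and dmg_carriers else ""
            )
        rows.append(row)
    return pd.DataFrame(rows)
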