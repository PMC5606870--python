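"""Subgroup assignment and carrier summarization.

Samples eligible for several case subgroups are assigned to exactly one by
a fixed priority (FCCTX > young onset > pMMR > dMMR > unselected; controls
stay controls). Carrier tables count unique variants and distinct carrier
individuals per gene x group, and the multi-variant detector surfaces
homozygotes, suspected compound heterozygotes (two distinct heterozygous
qualifying variants in one gene — phase is never known here) and
multi-gene carriers among the qualifying set: Tier 1 variants, pathogenic
or likely pathogenic Tier 2 variants, and predicted-damaging VUS.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import Classification, LIKELY_PATHOGENIC, PATHOGENIC, VUS
from .tiering import TIER1, TIER2, TierAssignment, VariantRecord
from .util import round_half_even

# group labels
FCCTX = "FCCTX"
UNSELECTED = "unselected"
YOUNG_ONSET = "young_onset"
PMMR = "pMMR"
DMMR = "dMMR"
CONTROL = "control"

GROUP_PRIORITY = (FCCTX, YOUNG_ONSET, PMMR, DMMR, UNSELECTED)
ALL_GROUPS = GROUP_PRIORITY + (CONTROL,)

HOMOZYGOUS = "homozygous"
COMPOUND_HET = "suspected_compound_het"
MULTI_GENE = "multi_gene"


def assign_group(
    eligibility: Mapping[str, bool], priority: Sequence[str] = GROUP_PRIORITY
) -> str:
    """Resolve eligibility flags to a single group by priority.

    A control flag wins outright (controls are never cases); otherwise the
    highest-priority eligible case group is chosen. No flags at all is an
    error.
    """
    if eligibility.get(CONTROL):
        return CONTROL
    for grp in priority:
        if eligibility.get(grp):
            return grp
    raise ValueError("sample has no eligibility flag set")


@dataclass(frozen=True)
class MultiVariantCarrier:
    sample_id: str
    gene: str  # "" for multi-gene records
    variant_keys: tuple[str, ...]
    pattern: str  # homozygous | suspected_compound_het | multi_gene
    labels: tuple[str, ...] = ()  # protein-change labels when available


def qualifying_variant_keys(
    assignments: Sequence[TierAssignment],
    classifications: Mapping[str, Classification],
) -> set[str]:
    """Tier 1, pathogenic/likely-pathogenic Tier 2, or damaging-VUS keys."""
    keys: set[str] = set()
    for a in assignments:
        if not a.retained:
            continue
        if a.tier == TIER1:
            keys.add(a.variant_key)
        elif a.tier == TIER2:
            c = classifications.get(a.variant_key)
            if c is None:
                continue
            if c.cls in (PATHOGENIC, LIKELY_PATHOGENIC) or (
                c.cls == VUS and c.predicted_damaging
            ):
                keys.add(a.variant_key)
    return keys


def find_multi_variant_carriers(
    variants: Iterable[VariantRecord],
    qualifying: set[str],
) -> tuple[list[MultiVariantCarrier], dict[int, int]]:
    """Detect homozygotes, suspected compound hets and multi-gene carriers.

    ``variants`` are per-sample records; only those whose key is in
    ``qualifying`` participate. Returns the carrier records plus a
    histogram {k: number of samples carrying k distinct qualifying
    variants, k >= 2} (a homozygote counts its variant once but still
    represents two alleles and is listed).
    """
    per_sample: dict[str, dict[str, VariantRecord]] = defaultdict(dict)
    for v in variants:
        if v.variant_key in qualifying:
            per_sample[v.sample_id].setdefault(v.variant_key, v)

    records: list[MultiVariantCarrier] = []
    histogram: dict[int, int] = defaultdict(int)
    for sample_id in sorted(per_sample):
        by_key = per_sample[sample_id]
        n_distinct = len(by_key)
        n_alleles = sum(2 if v.zygosity == "hom_alt" else 1 for v in by_key.values())
        if n_alleles >= 2 and n_distinct >= 2:
            histogram[n_distinct] += 1
        by_gene: dict[str, list[VariantRecord]] = defaultdict(list)
        for v in by_key.values():
            by_gene[v.gene].append(v)
        for gene in sorted(by_gene):
            vs = sorted(by_gene[gene], key=lambda v: v.variant_key)
            homs = [v for v in vs if v.zygosity == "hom_alt"]
            for v in homs:
                records.append(
                    MultiVariantCarrier(
                        sample_id, gene, (v.variant_key, v.variant_key),
                        HOMOZYGOUS, (v.protein_change, v.protein_change),
                    )
                )
            hets = [v for v in vs if v.zygosity == "het"]
            if len(hets) >= 2:
                records.append(
                    MultiVariantCarrier(
                        sample_id, gene, tuple(v.variant_key for v in hets),
                        COMPOUND_HET, tuple(v.protein_change for v in hets),
                    )
                )
        if len(by_gene) >= 2 and n_distinct >= 2:
            keys = tuple(sorted(by_key))
            records.append(
                MultiVariantCarrier(
                    sample_id, "", keys, MULTI_GENE,
                    tuple(by_key[k].protein_change for k in keys),
                )
            )
    return records, dict(histogram)


def two_variant_carriers(
    records: Sequence[MultiVariantCarrier], gene: str
) -> set[str]:
    """Samples with two qualifying alleles in one gene (hom or compound het)."""
    return {
        r.sample_id
        for r in records
        if r.gene == gene and r.pattern in (HOMOZYGOUS, COMPOUND_HET)
    }


def carrier_table(
    assignments: Sequence[TierAssignment],
    groups: Mapping[str, str],
    group_sizes: Mapping[str, int],
    tier: str,
    group_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Gene x group table of ``unique variants (individuals)`` with totals.

    The totals row counts distinct individuals once per group even when a
    sample carries variants in several genes.
    """
    sel = [a for a in assignments if a.retained and a.tier == tier]
    order = list(group_order) if group_order is not None else sorted(group_sizes)
    rows = []
    for gene in sorted({a.gene for a in sel}) + ["Total"]:
        row: dict[str, object] = {"gene": gene}
        for grp in order:
            cell = [
                a
                for a in sel
                if (gene == "Total" or a.gene == gene) and groups.get(a.sample_id) == grp
            ]
            uniq = len({a.variant_key for a in cell})
            carriers = len({a.sample_id for a in cell})
            row[f"{grp}"] = f"{uniq} ({carriers})" if uniq else ""
            if gene == "Total":
                size = group_sizes.get(grp, 0)
                row[f"{grp}_pct"] = (
                    round_half_even(100.0 * carriers / size, 1) if size and carriers else ""
                )
        rows.append(row)
    return pd.DataFrame(rows)


def headline_rate(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage with half-even rounding; zero denominator is an error."""
    if denominator == 0:
        raise ValueError("denominator must be non-zero")
    return round_half_even(100.0 * numerator / denominator, ndigits)
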