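"""Variant-level filtering and Tier 1 / Tier 2 assignment.

Genotype calls are kept only at read depth >= 20 and genotype quality >= 30
(boundary values retained), and a variant is dropped entirely when its
frequency reaches 5% in any reference population (1000 Genomes, ESP or ExAC
style per-population snapshots; the maximum over all populations is tested).

Of the retained variants, the protein-disrupting classes — nonsense,
frameshift, splice site within 2 bp of an exon-intron boundary, initiator
codon and stop-loss — form Tier 1; missense and in-frame indels form Tier 2
and go on to evidence-based classification. Synonymous, intronic, UTR and
intergenic calls are excluded by consequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import PipelineConfig
from .decisions import DecisionLog
from .targets import TargetInterval, targets_by_gene
from .util import round_half_even

# Consequence vocabulary
NONSENSE = "nonsense"
FRAMESHIFT = "frameshift"
SPLICE_SITE = "splice_site"
INITIATOR_CODON = "initiator_codon"
STOP_LOSS = "stop_loss"
MISSENSE = "missense"
INFRAME_INDEL = "inframe_indel"
SYNONYMOUS = "synonymous"
INTRONIC = "intronic"
UTR = "UTR"
INTERGENIC = "intergenic"

TIER1_CONSEQUENCES = frozenset(
    {NONSENSE, FRAMESHIFT, SPLICE_SITE, INITIATOR_CODON, STOP_LOSS}
)
TIER2_CONSEQUENCES = frozenset({MISSENSE, INFRAME_INDEL})
EXCLUDED_CONSEQUENCES = frozenset({SYNONYMOUS, INTRONIC, UTR, INTERGENIC})
ALL_CONSEQUENCES = TIER1_CONSEQUENCES | TIER2_CONSEQUENCES | EXCLUDED_CONSEQUENCES

# Tier labels
TIER1 = "TIER1"
TIER2 = "TIER2"
EXCLUDED = "EXCLUDED"

# Filter statuses
RETAINED = "retained"
EXCLUDED_DP = "excluded_dp"
EXCLUDED_GQ = "excluded_gq"
EXCLUDED_MAF = "excluded_maf"
EXCLUDED_CONSEQUENCE = "excluded_consequence"


@dataclass(frozen=True)
class VariantRecord:
    """One called variant in one sample, with genotype-level quality.

    ``pos`` is 0-based (converted from the 1-based VCF coordinate on read);
    ``zygosity`` is ``het`` or ``hom_alt``.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str
    consequence: str
    protein_change: str
    dp: int
    gq: int
    zygosity: str

    def __post_init__(self) -> None:
        if self.consequence not in ALL_CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.dp < 0 or self.gq < 0:
            raise ValueError("DP and GQ must be non-negative")
        if self.zygosity not in ("het", "hom_alt"):
            raise ValueError(f"bad zygosity {self.zygosity!r}")

    @property
    def variant_key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


class PopulationFrequencyTable:
    """Per-population allele frequencies keyed by variant.

    Absent variants are treated as frequency 0 ("novel"). Stored as
    variant_key -> {(source, population): AF}.
    """

    SOURCES = ("KG", "ESP", "EXAC")

    def __init__(self, data: Mapping[str, Mapping[tuple[str, str], float]] | None = None):
        self._data: dict[str, dict[tuple[str, str], float]] = {}
        if data:
            for key, freqs in data.items():
                for (src, pop), af in freqs.items():
                    self.add(key, src, pop, af)

    def add(self, variant_key: str, source: str, population: str, af: float) -> None:
        if not (0.0 <= af <= 1.0):
            raise ValueError(f"allele frequency out of [0,1]: {af}")
        self._data.setdefault(variant_key, {})[(source, population)] = af

    def max_af(self, variant_key: str) -> float:
        freqs = self._data.get(variant_key)
        return max(freqs.values()) if freqs else 0.0

    def is_novel(self, variant_key: str) -> bool:
        return variant_key not in self._data

    def __len__(self) -> int:
        return len(self._data)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (key, src, pop, af)
            for key in sorted(self._data)
            for (src, pop), af in sorted(self._data[key].items())
        ]
        return pd.DataFrame(rows, columns=["variant_key", "source", "population", "af"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "PopulationFrequencyTable":
        df = pd.read_csv(path, sep="\t", dtype={"variant_key": str})
        table = cls()
        for row in df.itertuples(index=False):
            table.add(row.variant_key, row.source, row.population, float(row.af))
        return table


@dataclass(frozen=True)
class TierAssignment:
    sample_id: str
    variant_key: str
    gene: str
    consequence: str
    filter_status: str
    tier: str | None  # None unless retained

    @property
    def retained(self) -> bool:
        return self.filter_status == RETAINED


def filter_variant(
    v: VariantRecord, freqs: PopulationFrequencyTable, cfg: PipelineConfig
) -> str:
    """First failing rule in fixed order DP -> GQ -> MAF; else retained."""
    if v.dp < cfg.dp_min:
        return EXCLUDED_DP
    if v.gq < cfg.gq_min:
        return EXCLUDED_GQ
    if freqs.max_af(v.variant_key) >= cfg.maf_exclude:
        return EXCLUDED_MAF
    return RETAINED


def assign_tier(v: VariantRecord) -> tuple[str, str]:
    """Map a retained variant's consequence to (tier, filter_status)."""
    if v.consequence in TIER1_CONSEQUENCES:
        return TIER1, RETAINED
    if v.consequence in TIER2_CONSEQUENCES:
        return TIER2, RETAINED
    if v.consequence in EXCLUDED_CONSEQUENCES:
        return EXCLUDED, EXCLUDED_CONSEQUENCE
    raise ValueError(f"unknown consequence {v.consequence!r}")


def tier_variants(
    variants: Iterable[VariantRecord],
    freqs: PopulationFrequencyTable,
    cfg: PipelineConfig,
    log: DecisionLog | None = None,
) -> list[TierAssignment]:
    """Filter then tier every per-sample variant record."""
    out: list[TierAssignment] = []
    for v in variants:
        status = filter_variant(v, freqs, cfg)
        if status == RETAINED:
            tier, status = assign_tier(v)
            if status == EXCLUDED_CONSEQUENCE:
                tier_label = EXCLUDED
            else:
                tier_label = tier
        else:
            tier_label = None
        if status == RETAINED:
            rule = {TIER1: "tier1_consequence", TIER2: "tier2_consequence"}[tier_label]
            outcome = f"{tier_label}:{v.consequence}"
        elif status == EXCLUDED_CONSEQUENCE:
            rule, outcome = "consequence_excluded", f"{EXCLUDED}:{v.consequence}"
            tier_label = EXCLUDED
        else:
            rule, outcome = status, status
        if log is not None:
            log.record(
                v.sample_id, v.variant_key, "tier", rule, outcome,
                evidence_ref=f"dp={v.dp};gq={v.gq};max_af={freqs.max_af(v.variant_key):g}",
            )
        out.append(
            TierAssignment(
                sample_id=v.sample_id,
                variant_key=v.variant_key,
                gene=v.gene,
                consequence=v.consequence,
                filter_status=status,
                tier=tier_label if status in (RETAINED, EXCLUDED_CONSEQUENCE) else None,
            )
        )
    return out


def splice_distance(
    chrom: str, pos: int, gene: str, targets: Sequence[TargetInterval]
) -> int:
    """Signed distance from ``pos`` (0-based) to the nearest exon boundary.

    0 or negative values lie inside an exon (negative = bases from the
    nearest edge); positive values count intronic bases beyond the boundary
    (1 = first intronic base). Positions outside every captured target of
    the gene raise ``ValueError``.
    """
    gene_targets = [t for t in targets if t.gene == gene and t.chrom == chrom]
    if not gene_targets:
        raise ValueError(f"no targets for gene {gene} on {chrom}")
    covering = [t for t in gene_targets if t.start <= pos < t.end]
    if not covering:
        raise ValueError(f"position {chrom}:{pos} outside all captured targets of {gene}")
    t = covering[0]
    estart, eend = t.exon_start, t.exon_end
    if estart <= pos < eend:
        # inside the exon: negative distance to the closest edge, 0 at edges
        return -min(pos - estart, eend - 1 - pos)
    if pos < estart:
        return estart - pos  # bases upstream into the intron
    return pos - (eend - 1)  # bases downstream into the intron


def is_splice_region(distance: int) -> bool:
    """Intronic and within 2 bases of the boundary."""
    return 0 < distance <= 2


def validate_splice_annotation(
    v: VariantRecord, targets: Sequence[TargetInterval]
) -> bool:
    """Check a splice_site-annotated variant sits within +/-2 intronic bases."""
    if v.consequence != SPLICE_SITE:
        return True
    return is_splice_region(splice_distance(v.chrom, v.pos, v.gene, targets))


def tier1_overview(
    assignments: Sequence[TierAssignment],
    groups: Mapping[str, str],
    group_sizes: Mapping[str, int],
    group_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per gene x group Tier 1 table of ``unique (individuals)`` plus % carriers.

    ``groups`` maps sample_id -> group label; ``group_sizes`` gives each
    group's denominator. The total row counts distinct carrier individuals
    once per group, and the percentage is rounded half-even to 1 decimal.
    """
    tier1 = [a for a in assignments if a.retained and a.tier == TIER1]
    order = list(group_order) if group_order is not None else sorted(group_sizes)
    genes = sorted({a.gene for a in tier1})
    rows = []
    for gene in genes:
        row: dict[str, object] = {"gene": gene}
        for grp in order:
            cell = [a for a in tier1 if a.gene == gene and groups.get(a.sample_id) == grp]
            uniq = len({a.variant_key for a in cell})
            carriers = len({a.sample_id for a in cell})
            row[f"{grp}_variants"] = uniq
            row[f"{grp}_individuals"] = carriers
        rows.append(row)
    total: dict[str, object] = {"gene": "Total"}
    for grp in order:
        cell = [a for a in tier1 if groups.get(a.sample_id) == grp]
        uniq = len({a.variant_key for a in cell})
        carriers = len({a.sample_id for a in cell})
        total[f"{grp}_variants"] = uniq
        total[f"{grp}_individuals"] = carriers
        size = group_sizes.get(grp, 0)
        total[f"{grp}_pct_carriers"] = (
            round_half_even(100.0 * carriers / size, 1) if size and carriers else ""
        )
    rows.append(total)
    return pd.DataFrame(rows)


def percent_carriers(n_carriers: int, group_size: int) -> float:
    """Distinct carriers as a percentage of the group, 1-decimal half-even."""
    if group_size <= 0:
        raise ValueError("group size must be positive")
    return round_half_even(100.0 * n_carriers / group_size, 1)
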