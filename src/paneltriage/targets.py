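"""Panel target intervals: the 36-gene capture design and its BED-like I/O.

Targets are exons padded by 30 bp on each side (so splice-region positions
up to the pad are captured). Coordinates are 0-based half-open internally;
files use the same convention (BED-like). Reported tables convert to
1-based inclusive.

The synthetic panel geometry in :func:`build_panel` places each gene at a
fixed, non-overlapping location with realistic exon counts; it is the
coordinate system for the cohort simulator and the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

EXON_PAD = 30

# 36 genes screened for colorectal-cancer susceptibility: chromosome and
# exon count per gene (counts approximate the canonical transcripts).
PANEL_GENES: dict[str, tuple[str, int]] = {
    "APC": ("chr5", 16),
    "AXIN1": ("chr16", 11),
    "AXIN2": ("chr17", 11),
    "BLM": ("chr15", 22),
    "BMP4": ("chr14", 4),
    "BMPR1A": ("chr10", 13),
    "BUB1": ("chr2", 25),
    "CDH1": ("chr16", 16),
    "CDKN1B": ("chr12", 3),
    "CDKN2A": ("chr9", 3),
    "CHEK2": ("chr22", 15),
    "CTNNB1": ("chr3", 15),
    "FLCN": ("chr17", 14),
    "GALNT12": ("chr9", 11),
    "MLH1": ("chr3", 19),
    "MLH3": ("chr14", 13),
    "MSH2": ("chr2", 16),
    "MSH3": ("chr5", 24),
    "MSH6": ("chr2", 10),
    "MUTYH": ("chr1", 16),
    "NUDT1": ("chr7", 5),
    "OGG1": ("chr3", 8),
    "PALB2": ("chr16", 13),
    "PMS1": ("chr2", 13),
    "PTEN": ("chr10", 9),
    "RECQL5": ("chr17", 19),
    "SMAD1": ("chr4", 7),
    "SMAD2": ("chr18", 12),
    "SMAD3": ("chr15", 9),
    "SMAD4": ("chr18", 12),
    "STK11": ("chr19", 10),
    "STK11IP": ("chr2", 21),
    "TGFB1": ("chr19", 7),
    "TGFBR1": ("chr9", 9),
    "TGFBR2": ("chr3", 8),
    "TP53": ("chr17", 11),
}

_EXON_LEN = 150
_EXON_SPACING = 1200  # exon start to next exon start; leaves >900 bp introns
_GENE_SLOT = 1_000_000


class TargetError(ValueError):
    """Invalid target interval set."""


@dataclass(frozen=True, order=True)
class TargetInterval:
    """One capture target: an exon padded by ``EXON_PAD`` on each side."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    gene: str
    feature: str  # e.g. "exon 3"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise TargetError(
                f"interval start must be < end: {self.gene} {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def target_id(self) -> str:
        return f"{self.gene}:{self.feature.replace(' ', '')}"

    @property
    def exon_start(self) -> int:
        """Start of the unpadded exon."""
        return self.start + EXON_PAD

    @property
    def exon_end(self) -> int:
        """End (exclusive) of the unpadded exon."""
        return self.end - EXON_PAD


def build_panel(genes: Iterable[str] | None = None) -> list[TargetInterval]:
    """Deterministic synthetic geometry for the capture panel.

    Gene ``i`` of the panel occupies a private 1 Mb slot on its chromosome;
    exons are 150 bp at a 1200 bp spacing, each target padded by 30 bp.
    """
    wanted = list(genes) if genes is not None else list(PANEL_GENES)
    unknown = [g for g in wanted if g not in PANEL_GENES]
    if unknown:
        raise TargetError(f"unknown panel gene(s): {', '.join(sorted(unknown))}")
    out: list[TargetInterval] = []
    for idx, gene in enumerate(PANEL_GENES):
        if gene not in wanted:
            continue
        chrom, n_exons = PANEL_GENES[gene]
        gene_start = (idx + 1) * _GENE_SLOT
        for e in range(n_exons):
            estart = gene_start + e * _EXON_SPACING
            out.append(
                TargetInterval(
                    chrom=chrom,
                    start=estart - EXON_PAD,
                    end=estart + _EXON_LEN + EXON_PAD,
                    gene=gene,
                    feature=f"exon {e + 1}",
                )
            )
    return out


def validate_targets(targets: Sequence[TargetInterval]) -> None:
    """Check per-gene sorted, non-overlapping structure."""
    by_gene: dict[str, list[TargetInterval]] = {}
    for t in targets:
        by_gene.setdefault(t.gene, []).append(t)
    for gene, ts in by_gene.items():
        for a, b in zip(ts, ts[1:]):
            if b.start < a.end:
                if b.start < a.start:
                    raise TargetError(f"targets of {gene} are not sorted by start")
                raise TargetError(
                    f"overlapping targets in {gene}: "
                    f"{a.chrom}:{a.start}-{a.end} and {b.chrom}:{b.start}-{b.end}"
                )


def read_targets(
    path: str | Path, gene_whitelist: Iterable[str] | None = None
) -> list[TargetInterval]:
    """Read a BED-like target file (chrom, start, end, gene, feature; TSV)."""
    whitelist = set(gene_whitelist) if gene_whitelist is not None else None
    targets: list[TargetInterval] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise TargetError(f"{path}:{lineno}: expected 5 tab-separated columns")
        chrom, start, end, gene, feature = parts
        if whitelist is not None and gene not in whitelist:
            raise TargetError(f"{path}:{lineno}: unknown gene {gene!r}")
        targets.append(TargetInterval(chrom, int(start), int(end), gene, feature))
    validate_targets(targets)
    return targets


def write_targets(targets: Sequence[TargetInterval], path: str | Path) -> None:
    lines = [
        f"{t.chrom}\t{t.start}\t{t.end}\t{t.gene}\t{t.feature}" for t in targets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def targets_by_gene(targets: Sequence[TargetInterval]) -> dict[str, list[TargetInterval]]:
    out: dict[str, list[TargetInterval]] = {}
    for t in targets:
        out.setdefault(t.gene, []).append(t)
    for ts in out.values():
        ts.sort(key=lambda t: t.start)
    return out
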