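"""Packaged transcriptions of the published worked-example tables.

Three small tables ship with the package as TSV snapshots: the cohort
characteristics (per-registry group sizes), the large-exonic-deletion cases
and the homozygous / suspected-compound-heterozygote cases. They serve as
desk-check inputs: the carrier detector and summary arithmetic are run
against them and must reproduce the published tallies.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .targets import PANEL_GENES
from .tiering import (
    FRAMESHIFT,
    MISSENSE,
    NONSENSE,
    SPLICE_SITE,
    VariantRecord,
)

_GROUP_ALIASES = {
    "Unselected": "unselected",
    "FCCTX": "FCCTX",
    "Young Onset": "young_onset",
    "Young onset": "young_onset",
    "pMMR": "pMMR",
    "dMMR": "dMMR",
    "Negative control": "control",
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("paneltriage.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def table1_sample_characteristics() -> pd.DataFrame:
    """Cohort composition per registry site (ethnicity, ascertainment, group)."""
    return _read("table1_sample_characteristics.tsv")


def table1_group_sizes() -> dict[str, int]:
    """Post-QC group sizes keyed by internal group label."""
    df = table1_sample_characteristics()
    grp = df[df["section"] == "group"]
    return {_GROUP_ALIASES[row.row]: int(row.All) for row in grp.itertuples(index=False)}


def table3_deletions() -> pd.DataFrame:
    """The 13 published large-exonic-deletion events (one case twice)."""
    return _read("table3_exonic_deletions.tsv")


def table5_two_variant_carriers() -> pd.DataFrame:
    """The 24 published two-variant (homozygous / compound-het) cases."""
    return _read("table5_two_variant_carriers.tsv")


def _label_consequence(label: str) -> str:
    if label.endswith("*"):
        return NONSENSE
    if label.endswith("fs"):
        return FRAMESHIFT
    if "A>G" in label or "splice" in label:
        return SPLICE_SITE
    return MISSENSE


def table5_variant_records() -> list[VariantRecord]:
    """Expand the two-variant table into per-sample variant records.

    Identical variant pairs become one homozygous record; distinct pairs
    become two heterozygous records. Positions are synthetic but stable per
    (gene, protein-change) pair, so shared variants share a variant key.
    """
    df = table5_two_variant_carriers()
    keys: dict[tuple[str, str], int] = {}
    records: list[VariantRecord] = []
    for row in df.itertuples(index=False):
        pair = [(row.gene, row.variant1), (row.gene, row.variant2)]
        hom = row.variant1 == row.variant2
        for gene, label in pair[: 1 if hom else 2]:
            pos = keys.setdefault((gene, label), 1000 + len(keys))
            records.append(
                VariantRecord(
                    sample_id=row.sample_id,
                    chrom=PANEL_GENES[gene][0],
                    pos=pos,
                    ref="A",
                    alt="G",
                    gene=gene,
                    transcript=f"NM_{gene}",
                    consequence=_label_consequence(label),
                    protein_change=label,
                    dp=100,
                    gq=99,
                    zygosity="hom_alt" if hom else "het",
                )
            )
    return records
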