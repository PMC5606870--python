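"""Readers for the on-disk cohort bundle (VCF, metadata, evidence, truth).

The VCF reader converts 1-based VCF coordinates to the 0-based internal
convention and decomposes multi-allelic sites into biallelic records.
Consequence annotation is taken from the INFO fields (GENE/CSQ/TX/PCH) —
the pipeline consumes pre-annotated calls and does not predict effects.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .classify import AnnotationEvidence
from .simulate import SampleMeta, TruthSet
from .tiering import VariantRecord


def read_vcf_variants(path: str | Path) -> list[VariantRecord]:
    """Extract per-sample variant records with genotype-level DP/GQ."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out: list[VariantRecord] = []
    for v in vcf:
        dp = v.format("DP")
        gq = v.format("GQ")
        dp = None if dp is None else np.asarray(dp).reshape(len(samples), -1)[:, 0]
        gq = None if gq is None else np.asarray(gq).reshape(len(samples), -1)[:, 0]
        gene = v.INFO.get("GENE") or ""
        csq = v.INFO.get("CSQ") or ""
        tx = v.INFO.get("TX") or ""
        pch = v.INFO.get("PCH") or ""
        for alt_idx, alt in enumerate(v.ALT, start=1):
            for si, genotype in enumerate(v.genotypes):
                alleles = [a for a in genotype[:-1] if a is not None and a >= 0]
                n_alt = sum(1 for a in alleles if a == alt_idx)
                if n_alt == 0:
                    continue
                zyg = "hom_alt" if n_alt >= 2 else "het"
                out.append(
                    VariantRecord(
                        sample_id=samples[si],
                        chrom=v.CHROM,
                        pos=v.POS - 1,
                        ref=v.REF,
                        alt=alt,
                        gene=gene,
                        transcript=tx,
                        consequence=csq,
                        protein_change=pch,
                        dp=int(dp[si]) if dp is not None else 0,
                        gq=int(gq[si]) if gq is not None else 0,
                        zygosity=zyg,
                    )
                )
    return out


def read_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    ihc_cols = [c for c in df.columns if c.startswith("ihc_")]
    out: list[SampleMeta] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        age = d.get("age_at_dx")
        age = None if age is None or (isinstance(age, float) and np.isnan(age)) or age == "" else int(age)
        out.append(
            SampleMeta(
                sample_id=d["sample_id"],
                eligibility=tuple(str(d["eligibility"]).split(",")),
                group=d["group"],
                ethnicity=d["ethnicity"],
                age_at_dx=age,
                ascertainment=d["ascertainment"],
                cov10x=float(d["cov10x"]),
                cov40x=float(d["cov40x"]),
                concordance=float(d["concordance"]),
                ihc=tuple((c[4:].upper(), str(d[c])) for c in ihc_cols),
                msi=d["msi"],
            )
        )
    return out


def _opt_int(x) -> int | None:
    if x is None or x == "" or (isinstance(x, float) and np.isnan(x)):
        return None
    return int(x)


def _opt_float(x) -> float | None:
    if x is None or x == "" or (isinstance(x, float) and np.isnan(x)):
        return None
    return float(x)


def read_evidence(path: str | Path) -> dict[str, AnnotationEvidence]:
    df = pd.read_csv(path, sep="\t", dtype={"variant_key": str})
    out: dict[str, AnnotationEvidence] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        cls = d.get("clinvar_class")
        internal = d.get("internal_class")
        out[d["variant_key"]] = AnnotationEvidence(
            variant_key=d["variant_key"],
            insight_class=_opt_int(d.get("insight_class")),
            clinvar_class=None if not isinstance(cls, str) or not cls else cls,
            clinvar_stars=_opt_int(d.get("clinvar_stars")),
            hgmd=bool(int(d.get("hgmd", 0))),
            internal_class=None if not isinstance(internal, str) or not internal else internal,
            internal_review_year=_opt_int(d.get("internal_review_year")),
            revel=_opt_float(d.get("revel")),
            max_maf=float(d.get("max_maf", 0.0)),
        )
    return out


def read_truth(bundle_dir: str | Path) -> TruthSet:
    bundle_dir = Path(bundle_dir)
    return TruthSet(
        variants=pd.read_csv(bundle_dir / "truth_variants.tsv", sep="\t"),
        carriers=pd.read_csv(bundle_dir / "truth_carriers.tsv", sep="\t"),
        cnvs=pd.read_csv(bundle_dir / "truth_cnvs.tsv", sep="\t"),
        qc_fail=pd.read_csv(bundle_dir / "truth_qc_fail.tsv", sep="\t"),
        multi=pd.read_csv(bundle_dir / "truth_multi.tsv", sep="\t"),
    )
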