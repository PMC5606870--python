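"""Sample-level quality control applied before any variant analysis.

A sample fails when its fraction of targeted bases at 10x depth is below
0.95, its fraction at 40x is below 0.60, or its concordance with an
orthogonal SNP genotyping panel is below 0.95 (strict ``<``; samples
exactly at a threshold pass). Fractions arrive as metadata — coverage is
not recomputed from alignments here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .config import PipelineConfig
from .decisions import DecisionLog

LOW_COV_10X = "low_cov_10x"
LOW_COV_40X = "low_cov_40x"
LOW_CONCORDANCE = "low_concordance"
REASONS = (LOW_COV_10X, LOW_COV_40X, LOW_CONCORDANCE)


@dataclass(frozen=True)
class QCResult:
    sample_id: str
    passed: bool
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("pass flag must match empty reasons")


def assess_sample(meta, cfg: PipelineConfig) -> QCResult:
    """Evaluate one sample's QC metadata; all violated thresholds listed.

    ``meta`` needs ``sample_id``, ``cov10x``, ``cov40x`` and
    ``concordance`` attributes; a missing (None) fraction is an error, a
    sample never passes silently.
    """
    values = {}
    for attr in ("cov10x", "cov40x", "concordance"):
        val = getattr(meta, attr)
        if val is None or (isinstance(val, float) and val != val):
            raise ValueError(f"sample {meta.sample_id}: missing QC metric {attr}")
        values[attr] = float(val)
    reasons = []
    if values["cov10x"] < cfg.cov10x_min:
        reasons.append(LOW_COV_10X)
    if values["cov40x"] < cfg.cov40x_min:
        reasons.append(LOW_COV_40X)
    if values["concordance"] < cfg.concordance_min:
        reasons.append(LOW_CONCORDANCE)
    return QCResult(meta.sample_id, passed=not reasons, reasons=tuple(reasons))


def apply_sample_qc(
    samples: Iterable, cfg: PipelineConfig, log: DecisionLog | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Assess every sample; returns (retained ids, exclusion report).

    The report has one row per excluded sample with its reasons, plus
    aggregate counts are recoverable by value_counts on the reason column.
    """
    retained: list[str] = []
    excluded_rows: list[dict[str, object]] = []
    for meta in samples:
        result = assess_sample(meta, cfg)
        if log is not None:
            log.record(
                result.sample_id, "", "qc",
                "coverage_concordance",
                "pass" if result.passed else "fail:" + ",".join(result.reasons),
            )
        if result.passed:
            retained.append(result.sample_id)
        else:
            excluded_rows.append(
                {"sample_id": result.sample_id, "reasons": ",".join(result.reasons)}
            )
    report = pd.DataFrame(excluded_rows, columns=["sample_id", "reasons"])
    return retained, report
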