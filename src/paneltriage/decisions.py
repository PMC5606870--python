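"""Append-only decision log: which rule fired for every sample and variant.

Every exclusion, tier assignment, classification and CNV call appends one
:class:`DecisionRecord`; downstream reports must be reconstructible from the
record stream alone (tested by replay).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

COLUMNS = ("sample_id", "variant_key", "stage", "rule", "outcome", "evidence_ref")


@dataclass(frozen=True)
class DecisionRecord:
    sample_id: str
    variant_key: str  # empty for sample-level decisions
    stage: str  # qc | filter | tier | classify | revel | cnv
    rule: str
    outcome: str
    evidence_ref: str = ""


class DecisionLog:
    """Append-only stream of decisions with TSV round-trip."""

    def __init__(self) -> None:
        self._records: list[DecisionRecord] = []

    def append(self, record: DecisionRecord) -> None:
        self._records.append(record)

    def record(
        self,
        sample_id: str,
        variant_key: str,
        stage: str,
        rule: str,
        outcome: str,
        evidence_ref: str = "",
    ) -> None:
        self._records.append(
            DecisionRecord(sample_id, variant_key, stage, rule, outcome, evidence_ref)
        )

    @property
    def records(self) -> tuple[DecisionRecord, ...]:
        return tuple(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def filter(self, stage: str) -> list[DecisionRecord]:
        return [r for r in self._records if r.stage == stage]

    def write(self, path: str | Path) -> None:
        lines = ["\t".join(COLUMNS)]
        for r in self._records:
            lines.append(
                "\t".join(
                    (r.sample_id, r.variant_key, r.stage, r.rule, r.outcome, r.evidence_ref)
                )
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "DecisionLog":
        log = cls()
        lines = Path(path).read_text().splitlines()
        if not lines or lines[0] != "\t".join(COLUMNS):
            raise ValueError(f"{path}: missing decision-log header")
        for raw in lines[1:]:
            parts = raw.split("\t")
            if len(parts) != len(COLUMNS):
                raise ValueError(f"{path}: malformed decision record {raw!r}")
            log.append(DecisionRecord(*parts))
        return log


def replay_outcomes(log: DecisionLog, stage: str) -> dict[tuple[str, str], str]:
    """Map (sample_id, variant_key) -> outcome for one stage.

    The stream is append-only, so for replay the last record per key wins
    (stages never re-decide a key in practice; this is a formality).
    """
    out: dict[tuple[str, str], str] = {}
    for r in log.filter(stage):
        out[(r.sample_id, r.variant_key)] = r.outcome
    return out
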