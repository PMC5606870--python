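#!/usr/bin/env python
"""Run the full triage pipeline on the simulated bundle.

Reads scratch/bundle/ (written by 01_simulate_cohort.py), runs QC ->
filter/tier -> classify -> CNV -> carriers, writes all stage reports to
scratch/reports/, and copies the overview tables plus the run summary to
results/.
"""

import shutil
import sys
from pathlib import Path

from paneltriage import PipelineConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]
BUNDLE_DIR = ROOT / "scratch" / "bundle"
REPORTS = ROOT / "scratch" / "reports"
RESULTS = ROOT / "results"


def main() -> None:
    if not BUNDLE_DIR.exists():
        sys.exit("no bundle found - run analysis/01_simulate_cohort.py first")
    cfg = PipelineConfig(seed=1)
    manifest = run_pipeline(BUNDLE_DIR, REPORTS, cfg)
    RESULTS.mkdir(exist_ok=True)
    for name in ("tier1_overview.tsv", "tier2_overview.tsv", "cnv_calls.tsv",
                 "multi_variant_carriers.tsv", "summary.json"):
        shutil.copy(REPORTS / name, RESULTS / f"pipeline_{name}")
    print("stages:", manifest.stages)
    print((REPORTS / "summary.json").read_text())


if __name__ == "__main__":
    main()
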