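#!/usr/bin/env python
"""Multi-seed CNV property suite on small coverage matrices.

Fifty seeds, each planting three multi-exon heterozygous deletions (4, 2
and 3 targets in MLH1/MSH2/MSH6) and one single-target deletion in a
40-sample matrix at lognormal noise sigma = 0.1. Reports the fraction of
seeds with perfect multi-exon sensitivity and zero false calls, how often
the single-target event is missed at default settings, and how often it is
recovered with singleton smoothing off and single-target segments allowed.
"""

from pathlib import Path

from paneltriage.evaluation import cnv_seed_suite

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    suite = cnv_seed_suite(n_seeds=50, base_seed=1000)
    RESULTS.mkdir(exist_ok=True)
    suite.to_csv(RESULTS / "cnv_suite.tsv", sep="\t", index=False)
    ok = ((suite.multi_exon_sensitivity == 1.0) & (suite.false_calls == 0)).mean()
    print(f"seeds with sensitivity 1.0 and no false calls: {100 * ok:.0f}%")
    print(f"single-exon deletions missed at defaults:      {100 * suite.single_missed_default.mean():.0f}%")
    print(f"single-exon recovered with relaxed settings:   {100 * suite.single_recovered_relaxed.mean():.0f}%")


if __name__ == "__main__":
    main()
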