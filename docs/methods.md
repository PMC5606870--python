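# Methods

`paneltriage` re-implements, as a tested pipeline, a germline variant
triage analysis for a 36-gene colorectal-cancer (CRC) susceptibility
panel: sample quality control, variant filtering, two-tier variant
classification, evidence-precedence missense review with a REVEL
prediction layer, read-depth exon-level CNV calling, and carrier
summarization across case subgroups. Because the underlying cohort data
are not public, the package ships a synthetic-cohort generator with
embedded truth; every claim the test suite makes is a claim about
recovery of planted structure under stated noise models, plus desk checks
against transcribed published tables.

## Cohort model

Samples belong to exactly one of five case subgroups or the control
group. Eligibility can overlap (a family meeting Amsterdam I criteria may
also be young-onset), so assignment uses a fixed priority:

    FCCTX > young onset > pMMR > dMMR > unselected;  controls stay controls.

The first three ranks are the analysis's stated rule; placing dMMR above
unselected extends it by specificity of ascertainment (dMMR requires
tumor triage, unselected requires none). The priority vector is a
parameter for anyone who wants the other order.

Default group sizes are the study conditions the pipeline emulates: 153
FCCTX, 548 unselected, 333 young-onset, 68 pMMR, 129 dMMR cases and 93
controls after QC, plus 6 planted QC failures (1330 sequenced, 1324
retained, 1231 cases).

## Sample QC

A sample fails when cov10x < 0.95, cov40x < 0.60, or SNP-panel
concordance < 0.95 — strict inequalities, so boundary values pass. The
fractions are consumed as metadata; recomputing them from alignments is
out of scope. A missing metric raises rather than passing silently.

## Variant filtering and tiers

Per-genotype filters run in fixed order DP -> GQ -> MAF (the retained set
is order-independent because the rules are conjunctive; only the recorded
reason depends on order):

- read depth: exclude iff DP < 20 (DP = 20 retained);
- genotype quality: exclude iff GQ < 30;
- population frequency: exclude iff the maximum allele frequency over
  all (source, population) pairs — 1000 Genomes-, ESP- and ExAC-style
  snapshots — is >= 0.05. A variant absent from every snapshot counts as
  frequency 0 ("novel"). A variant exactly at 5% is excluded (the
  exclusion rule is ">= 0.05" and wins over the "< 5%" benign band).

Retained variants are tiered by annotated consequence: nonsense,
frameshift, splice-site (within 2 bp of an exon-intron boundary),
initiator-codon and stop-loss variants are Tier 1 (presumed protein
disrupting); missense and in-frame indels are Tier 2 (require evidence
review); synonymous, intronic, UTR and intergenic calls are excluded.
Consequences arrive pre-annotated in the VCF (INFO fields); the package
validates splice annotations against the target geometry (distance to the
nearest exon boundary, intronic side, <= 2 bp) but does not predict
effects from sequence. Multi-allelic records are decomposed to biallelic
rows on read.

## Missense classification precedence

Each unique retained Tier 2 variant gets exactly one class
(PATHOGENIC, LIKELY_PATHOGENIC, VUS, LIKELY_NOT_PATHOGENIC,
NOT_PATHOGENIC) from a first-match precedence walk:

1. **FREQ_BENIGN** — max frequency in [2%, 5%): not pathogenic on
   frequency alone. This fires before any database because the review
   protocol treats it as a pre-filter applied to the candidate list.
2. **INSIGHT** — an InSiGHT class (expert MMR-gene curation) maps 5->P,
   4->LP, 3->VUS, 2->LNP, 1->NP and overrides all other databases.
3. **INTERNAL_RECENT** — an internal clinical-laboratory class last
   reviewed in 2015 or later.
4. **CLINVAR_2STAR** — a ClinVar assertion at >= 2 stars (multiple
   concordant submitters).
5. **REVIEW_REQUIRED** — weaker evidence only (internal pre-2015,
   ClinVar < 2 stars, or HGMD presence alone): the class stays VUS and a
   review flag is raised. The original analysis resolved these by human
   genetic-counselor ACMG review; an automated scorer would fabricate
   judgment, so this pipeline surfaces the aggregated evidence instead.
6. **NO_ANNOTATION** — VUS.

A missing evidence row behaves like branch 6 but is logged. REVEL (a
0-1 ensemble random-forest score for missense deleteriousness) is layered
onto VUS calls only: predicted damaging iff REVEL >= 0.5. The boundary is
">=" (one source in the original text says "> 0.5"; the methods wording
">= 0.5" is adopted and the cutoff is configurable). REVEL never changes
a class, and in-frame indels, which have no REVEL score, are never
flagged. Whether frequency-benign should be NOT_PATHOGENIC or
LIKELY_NOT_PATHOGENIC is not stated anywhere; NOT_PATHOGENIC was chosen.

## CNV calling

Input is a samples x targets matrix of mean depths over the padded exon
targets. The caller:

1. normalizes each sample by its own median depth over all targets;
2. learns a cross-sample reference pattern — per-target median of the
   normalized depths — and a per-target dispersion (MAD), giving weights
   w_t = 1/(MAD_t + 1e-3) that down-weight erratically captured targets;
3. computes per-target log2 ratios log2((norm + eps)/(pattern + eps));
4. smooths singleton outliers (below);
5. segments each gene's profile per sample by circular binary
   segmentation (CBS) with a weighted two-sample t statistic: for every
   arc of width >= 2, t = (m_in - m_out) / sqrt(s^2 (1/W_in + 1/W_out))
   with pooled weighted residual variance s^2; the maximal |t| is tested
   with a Bonferroni-corrected Gaussian tail at alpha = 0.01 and
   significant arcs split the segment recursively;
6. calls a segment a deletion iff its weighted mean log2 ratio <= -0.5,
   an amplification iff >= +0.5, restricted to the genes whose capture
   supports dosage analysis (MLH1, MSH2, MSH6 by default). Calls must
   span at least the minimum arc width (2 targets); boundaries are
   reported 1-based inclusive with exon labels and an "at panel edge"
   flag when the segment touches the first or last target of a gene.

Numerical choices worth stating:

- **Why not a permutation p-value by default.** Within-gene permutation
  of the max-arc statistic has a combinatorial floor: a k-target event in
  an n-target gene reappears intact in a random permutation with
  probability ~ k!(n-k)!(n-k+1)/n! (about 2/n ~ 0.1 for k = 2, n = 19),
  so no 2-exon deletion can ever reach alpha = 0.01 on these short
  profiles regardless of effect size. The analytic max-t test has no such
  floor; a permutation mode remains available (`cbs_p_method =
  permutation`) and agrees on wide events.
- **Gaussian rather than t tail.** With n <= 19 targets the residual df
  is small; a t tail plus Bonferroni over ~170 arcs is conservative
  enough to miss clear 3-exon events in 10-target genes. The Gaussian
  tail treats the variance as known; the resulting liberal splits are
  harmless because a call additionally requires the segment mean to
  clear +/-0.5.
- **Singleton smoothing.** A target farther than 3 robust SD (successive-
  difference MAD estimate) from every neighbor in its +/-2 window is
  pulled to its nearest neighbor +/- 1 SD. Adjacent shifted targets
  protect each other, so multi-target events are untouched. This both
  suppresses false width-1 calls from extreme noise cells and reproduces
  a documented limitation of the original analysis: single-exon
  deletions are not called at default settings (two of ten known
  positive-control deletions were missed for exactly this size reason).
  Setting `cnv_smooth_outliers = false` and `cbs_min_width = 1` recovers
  most single-target events; relaxing alpha alone does not, under either
  p-value method.
- Whole-gene deletions need no change-point: the single gene-spanning
  segment's mean (~ -1) clears the cutoff directly, because a deletion of
  ~20 of ~450 panel targets barely moves the sample's median.
- GC correction is omitted (not part of the described method); the
  pattern/weight machinery is the extension point.

## Synthetic data: what it emulates and what it does not

The generator plants, per unique variant: gene, consequence, a frequency
band (novel / rare < 2% / benign 2-5% / excluded >= 5%, with a
configurable fraction restricted to African-ancestry reference panels to
exercise the "any population" filter), an evidence branch consistent with
an intended class, a REVEL score on the intended side of the cutoff, and
carriers with planted DP/GQ. Decoys are planted to fail each filter:
low-DP, low-GQ, frequent, synonymous/intronic, and variants carried only
by QC-failed samples. Defaults reproduce the emulated study's spectrum:
92 unique Tier 1 variants (29/43/13/6/1 by class), 658 missense designed
to classify 13 pathogenic-side / 61 benign-side / 584 VUS with 144 VUS at
REVEL >= 0.5, and 17 in-frame indels. Coverage is mean depth x per-sample
factor (lognormal sigma 0.15) x per-target capture efficiency (lognormal
sigma 0.5) x lognormal noise (sigma 0.1); deletions scale affected cells
by copy_number/2 (copy 0 leaves ~1% residual "mismapping" depth). Ten
deletions are planted by default: eight spanning >= 2 targets, two
single-target events expected to be missed. Phase is never generated as
known: two heterozygous variants in one gene are only ever a *suspected*
compound heterozygote.

Not emulated: read-level artifacts (no FASTQ/BAM; depth is simulated at
target resolution), linkage between variants and coverage, pedigree
structure, real per-gene mutation spectra (genes are drawn uniformly
except the reserved MUTYH/PMS1 qualifying variants used to plant
biallelic carriers), and real population-frequency correlation
structure. Passing tests therefore demonstrate that the *decision logic*
is faithful under the assumed noise models, not that the caller would
perform identically on real capture data.

## Carrier analysis

The qualifying set is Tier 1 variants, pathogenic / likely-pathogenic
Tier 2 variants, and predicted-damaging VUS. Per sample the detector
emits homozygous records, suspected compound heterozygotes (>= 2 distinct
heterozygous qualifying variants in one gene), and multi-gene records,
plus a histogram of samples carrying 2/3/4 distinct qualifying variants.
Decomposed multi-allelic duplicates are de-duplicated by variant key
before counting; detection is symmetric in variant order and idempotent.
Carrier tables count unique variants and distinct individuals per gene x
group; totals count an individual once per group even with variants in
several genes. Percentages are half-even rounded to one decimal (the
"biallelic MUTYH" headline count requires two qualifying MUTYH alleles,
homozygous or suspected compound het).

## Determinism and provenance

All randomness flows from one seed through named `numpy` generator
streams (metadata / variants / carriers / coverage / CNV injection);
outputs carry no timestamps and every iteration is over sorted or
insertion-ordered containers, so a fixed seed reproduces byte-identical
bundles and reports across processes. Every QC verdict, filter reason,
tier, classification branch, REVEL flag and CNV call appends one record
to an append-only decision log; the tests replay the log and reconstruct
the reports from it alone. A run manifest records the config hash, input
checksums and stage statuses.

## Problem sizes

Defaults were chosen so the full cycle stays interactive: the default
bundle (1330 samples, ~1070 unique variants, 450-target coverage matrix)
generates in ~5 s and runs end to end in ~1 s; the 50-seed CNV property
suite uses 40-sample matrices over the three CNV-eligible genes and runs
in ~5 s; the whole test suite takes well under a minute.

## Known limitations

- Branch 5 (REVIEW_REQUIRED) intentionally stops at a flag; no automated
  ACMG scoring is attempted.
- CNV calling is honest only for the genes it is configured for; other
  panel genes' capture was not designed for dosage and segments there are
  dropped with a log record.
- The exon/intron feature labels in CNV reports come from the target
  annotations (padded exons), so boundary labels are exon-granular, not
  breakpoint-precise.
- Single-exon CNV events are by design not callable at defaults; see the
  smoothing discussion above for the recovery settings and their false-
  positive cost.
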