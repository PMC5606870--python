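"""Exon-level CNV detection from a samples x targets coverage matrix.

The caller learns a cross-sample coverage *pattern*: each sample is first
normalized by its own median depth, then the per-target median of the
normalized values forms the expected pattern and the per-target MAD its
dispersion. Targets with larger cross-sample variability are down-weighted
(weight = 1/(MAD + eps)), and each sample's per-target log2 ratio against
the pattern is segmented per gene by circular binary segmentation (CBS).
Segments with a weighted mean log2 ratio <= -0.5 are called deletions,
>= +0.5 amplifications; calls are restricted to the genes whose capture
depth was designed for dosage analysis (MLH1, MSH2, MSH6 by default).

Change-point significance uses a weighted two-sample t statistic (segment
vs complement, residual variance pooled) maximized over all arcs of width
>= ``cbs_min_width``. The default p-value is the Bonferroni-corrected
t-tail of the maximum ("maxt"); a permutation mode is available but note
that on short per-gene profiles a permutation p-value has a combinatorial
floor (a k-target arc can reappear intact in a random permutation with
probability ~ k!(n-k)!(n-k+1)/n!), which makes small events untestably
insignificant regardless of effect size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import PipelineConfig
from .decisions import DecisionLog
from .targets import TargetInterval, targets_by_gene

DELETION = "deletion"
AMPLIFICATION = "amplification"
NEUTRAL = "neutral"


class CNVError(ValueError):
    pass


class CoverageMatrix:
    """Mean depth per (sample, target); complete and non-negative."""

    def __init__(self, depths: pd.DataFrame, targets: Sequence[TargetInterval]):
        target_ids = [t.target_id for t in targets]
        if list(depths.columns) != target_ids:
            depths = depths.reindex(columns=target_ids)
        if depths.isna().any().any():
            raise CNVError("coverage matrix has missing cells")
        if (depths.to_numpy() < 0).any():
            raise CNVError("coverage matrix has negative depths")
        self.depths = depths.astype(float)
        self.targets = list(targets)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.depths.index)

    def copy(self) -> "CoverageMatrix":
        return CoverageMatrix(self.depths.copy(), self.targets)

    def write(self, path: str | Path) -> None:
        # on disk: targets as rows, samples as columns
        out = self.depths.T
        out.index.name = "target_id"
        out.to_csv(path, sep="\t", float_format="%.4f")

    @classmethod
    def read(cls, path: str | Path, targets: Sequence[TargetInterval]) -> "CoverageMatrix":
        df = pd.read_csv(path, sep="\t", index_col="target_id")
        return cls(df.T, targets)


@dataclass(frozen=True)
class ReferencePattern:
    """Per-target expected normalized coverage, dispersion and weight."""

    target_ids: tuple[str, ...]
    pattern: np.ndarray  # per-target median of median-normalized depth
    dispersion: np.ndarray  # per-target MAD
    weights: np.ndarray  # 1 / (MAD + eps)
    masked: np.ndarray  # bool, True where the target is unusable


@dataclass(frozen=True)
class CNVSegment:
    sample_id: str
    gene: str
    chrom: str
    start_index: int  # index into the gene's target list, inclusive
    end_index: int  # exclusive
    mean_log2: float
    call: str = NEUTRAL

    @property
    def n_targets(self) -> int:
        return self.end_index - self.start_index


@dataclass(frozen=True)
class CNVCall:
    """A reported deletion/amplification, boundaries 1-based inclusive."""

    sample_id: str
    gene: str
    chrom: str
    start: int
    end: int
    first_feature: str
    last_feature: str
    mean_log2: float
    call: str
    n_targets: int
    at_panel_edge: bool

    @property
    def boundaries(self) -> str:
        return f"{self.chrom}:{self.start}:{self.end}"

    @property
    def feature_span(self) -> str:
        if self.first_feature == self.last_feature:
            return self.first_feature
        return f"{self.first_feature} - {self.last_feature}"


def _normalize_samples(depths: pd.DataFrame) -> pd.DataFrame:
    med = depths.median(axis=1)
    if (med <= 0).any():
        bad = list(depths.index[med <= 0])
        raise CNVError(f"sample(s) with non-positive median depth: {bad}")
    return depths.div(med, axis=0)


def build_reference_pattern(m: CoverageMatrix, cfg: PipelineConfig) -> ReferencePattern:
    """Median/MAD pattern over median-normalized samples.

    Targets with zero depth in every sample are masked (logged upstream);
    weights are 1/(MAD + eps), so flat targets get the eps-capped maximum.
    """
    if len(m.sample_ids) < cfg.min_pattern_samples:
        raise CNVError(
            f"need >= {cfg.min_pattern_samples} samples to learn a coverage pattern, "
            f"got {len(m.sample_ids)}"
        )
    masked = (m.depths.to_numpy() == 0).all(axis=0)
    norm = _normalize_samples(m.depths).to_numpy()
    pattern = np.median(norm, axis=0)
    dispersion = np.median(np.abs(norm - pattern), axis=0)
    weights = 1.0 / (dispersion + cfg.pattern_epsilon)
    return ReferencePattern(
        target_ids=tuple(t.target_id for t in m.targets),
        pattern=pattern,
        dispersion=dispersion,
        weights=weights,
        masked=masked,
    )


def compute_log2_ratios(
    m: CoverageMatrix, ref: ReferencePattern, cfg: PipelineConfig
) -> pd.DataFrame:
    """Per-sample, per-target log2(normalized depth / pattern)."""
    norm = _normalize_samples(m.depths)
    eps = cfg.pattern_epsilon
    ratios = np.log2((norm.to_numpy() + eps) / (ref.pattern[None, :] + eps))
    return pd.DataFrame(ratios, index=m.depths.index, columns=m.depths.columns)


# ---------------------------------------------------------------------------
# circular binary segmentation

_SMOOTH_REGION = 2  # neighbors considered on each side
_OUTLIER_SD = 3.0  # a point this far from every neighbor is a singleton
_SMOOTH_SD = 1.0  # ... and is pulled to its nearest neighbor +/- this


def smooth_outliers(x: np.ndarray) -> np.ndarray:
    """Shrink singleton outliers toward their nearest neighbor.

    A point farther than 3 sigma from *every* other point in its +/-2
    window is pulled to the nearest such point plus 1 sigma in its own
    direction; sigma is a robust (successive-difference MAD) estimate.
    Two adjacent shifted targets protect each other, so real multi-target
    events are untouched while single-target spikes — noise or one-exon
    events, which single-probe dosage data cannot certify — are flattened.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        return x.copy()
    diffs = np.abs(np.diff(x))
    sigma = 1.4826 * np.median(diffs) / np.sqrt(2.0)
    if sigma <= 0:
        return x.copy()
    out = x.copy()
    for i in range(n):
        lo, hi = max(0, i - _SMOOTH_REGION), min(n, i + _SMOOTH_REGION + 1)
        others = np.r_[x[lo:i], x[i + 1 : hi]]
        gaps = np.abs(others - x[i])
        k = int(np.argmin(gaps))
        if gaps[k] > _OUTLIER_SD * sigma:
            out[i] = others[k] + np.sign(x[i] - others[k]) * _SMOOTH_SD * sigma
    return out


def _arc_stats(x: np.ndarray, w: np.ndarray, min_width: int):
    """Weighted two-sample t for every arc [i, j) vs its complement.

    Returns (i_idx, j_idx, t_values). Arcs narrower than ``min_width`` or
    covering the whole profile are excluded. The variance is the pooled
    weighted residual variance after fitting the two means (df = n - 2).
    """
    n = len(x)
    sw = np.concatenate(([0.0], np.cumsum(w)))
    swx = np.concatenate(([0.0], np.cumsum(w * x)))
    swxx = np.concatenate(([0.0], np.cumsum(w * x * x)))
    ii, jj = np.triu_indices(n + 1, k=min_width)
    keep = ~((ii == 0) & (jj == n))
    ii, jj = ii[keep], jj[keep]
    if len(ii) == 0:
        return ii, jj, np.empty(0)
    W, SX, SXX = sw[n], swx[n], swxx[n]
    w_in = sw[jj] - sw[ii]
    sx_in = swx[jj] - swx[ii]
    w_out = W - w_in
    m_in = sx_in / w_in
    m_out = (SX - sx_in) / w_out
    rss = SXX - w_in * m_in**2 - w_out * m_out**2
    df = max(n - 2, 1)
    s2 = np.maximum(rss, 1e-12) / df
    t = (m_in - m_out) / np.sqrt(s2 * (1.0 / w_in + 1.0 / w_out))
    return ii, jj, t


def _max_arc(x: np.ndarray, w: np.ndarray, min_width: int):
    ii, jj, t = _arc_stats(x, w, min_width)
    if len(t) == 0:
        return None
    k = int(np.argmax(np.abs(t)))
    return int(ii[k]), int(jj[k]), float(t[k]), len(t)


def _maxt_pvalue(t_obs: float, n: int, n_arcs: int) -> float:
    """Bonferroni-corrected Gaussian tail for the maximal arc statistic.

    The Gaussian tail (variance treated as known) keeps power on short
    per-gene profiles where a small-df t tail plus Bonferroni would be
    hopelessly conservative; liberal splits are harmless downstream
    because calls additionally require the segment mean to clear the
    +/-0.5 log2 cutoff.
    """
    return float(min(1.0, n_arcs * 2.0 * sps.norm.sf(abs(t_obs))))


def _permutation_pvalue(
    x: np.ndarray,
    w: np.ndarray,
    t_obs: float,
    min_width: int,
    n_perm: int,
    alpha: float,
    rng: np.random.Generator,
) -> float:
    """Permutation p for the max |t|; (value, weight) pairs permute jointly.

    Stops early once the exceedance count guarantees insignificance at
    ``alpha`` (the count can only grow).
    """
    n = len(x)
    count = 0
    done = 0
    block = 200
    futility = int(np.ceil(alpha * n_perm)) + 1
    while done < n_perm:
        b = min(block, n_perm - done)
        perms = np.argsort(rng.random((b, n)), axis=1)
        for p in perms:
            res = _max_arc(x[p], w[p], min_width)
            if res is not None and abs(res[2]) >= abs(t_obs) - 1e-12:
                count += 1
        done += b
        if count >= futility:
            break
    return (count + 1) / (done + 1)


def segment(
    ratios: np.ndarray,
    weights: np.ndarray,
    cfg: PipelineConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int, float]]:
    """CBS over one gene profile: recursive max-arc splitting.

    Returns ordered, non-overlapping ``(start, end, weighted_mean)`` tuples
    covering all targets. A single-target profile yields one segment.
    """
    x = np.asarray(ratios, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(x) != len(w):
        raise CNVError("ratios and weights must align")
    if np.any(w <= 0):
        raise CNVError("weights must be positive")
    if cfg.cbs_p_method == "permutation" and rng is None:
        rng = np.random.default_rng(cfg.seed)

    def wmean(lo: int, hi: int) -> float:
        return float(np.average(x[lo:hi], weights=w[lo:hi]))

    out: list[tuple[int, int, float]] = []

    def recurse(lo: int, hi: int) -> None:
        seg_len = hi - lo
        if seg_len < 2 * 1:  # nothing to split
            out.append((lo, hi, wmean(lo, hi)))
            return
        res = _max_arc(x[lo:hi], w[lo:hi], cfg.cbs_min_width)
        if res is None:
            out.append((lo, hi, wmean(lo, hi)))
            return
        i, j, t_obs, n_arcs = res
        if cfg.cbs_p_method == "permutation":
            p = _permutation_pvalue(
                x[lo:hi], w[lo:hi], t_obs, cfg.cbs_min_width,
                cfg.cbs_permutations, cfg.cbs_alpha, rng,
            )
        else:
            p = _maxt_pvalue(t_obs, seg_len, n_arcs)
        if p > cfg.cbs_alpha:
            out.append((lo, hi, wmean(lo, hi)))
            return
        cuts = [lo, lo + i, lo + j, hi]
        for a, b in zip(cuts, cuts[1:]):
            if b > a:
                recurse(a, b)

    recurse(0, len(x))
    out.sort()
    return out


def segment_gene_profiles(
    ratios: pd.DataFrame,
    ref: ReferencePattern,
    targets: Sequence[TargetInterval],
    cfg: PipelineConfig,
    genes: Iterable[str] | None = None,
    rng: np.random.Generator | None = None,
) -> list[CNVSegment]:
    """Run CBS per gene, per sample over the whole ratio matrix."""
    gene_map = targets_by_gene(targets)
    wanted = list(genes) if genes is not None else list(gene_map)
    col_index = {tid: k for k, tid in enumerate(ref.target_ids)}
    segs: list[CNVSegment] = []
    for gene in wanted:
        gts = gene_map.get(gene)
        if not gts:
            continue
        cols = [col_index[t.target_id] for t in gts]
        usable = [c for c in cols if not ref.masked[c]]
        if not usable:
            continue
        w = ref.weights[usable]
        sub = ratios.to_numpy()[:, usable]
        chrom = gts[0].chrom
        for row, sample_id in enumerate(ratios.index):
            profile = smooth_outliers(sub[row]) if cfg.cnv_smooth_outliers else sub[row]
            for lo, hi, mean in segment(profile, w, cfg, rng=rng):
                segs.append(
                    CNVSegment(
                        sample_id=str(sample_id),
                        gene=gene,
                        chrom=chrom,
                        start_index=lo,
                        end_index=hi,
                        mean_log2=mean,
                    )
                )
    return segs


def call_cnvs(
    segments: Sequence[CNVSegment],
    targets: Sequence[TargetInterval],
    cfg: PipelineConfig,
    log: DecisionLog | None = None,
) -> list[CNVCall]:
    """Threshold segment means; calls restricted to ``cfg.cnv_genes``.

    Boundaries are reported 1-based inclusive from the first to the last
    affected target; segments touching the first/last target of a gene are
    flagged as reaching the panel edge (the event may extend beyond the
    captured region).
    """
    gene_map = targets_by_gene(targets)
    calls: list[CNVCall] = []
    for seg in segments:
        if seg.n_targets < cfg.cbs_min_width:
            # width-1 remainder segments (complement-arc children) are noise
            # magnets; a call must span at least the minimum tested arc width
            if log is not None and (
                seg.mean_log2 <= cfg.cnv_del_cutoff or seg.mean_log2 >= cfg.cnv_amp_cutoff
            ):
                log.record(seg.sample_id, "", "cnv", "segment_below_min_width",
                           f"dropped:{seg.gene}",
                           evidence_ref=f"mean_log2={seg.mean_log2:.3f};targets={seg.n_targets}")
            continue
        if seg.gene not in cfg.cnv_genes:
            if log is not None and (
                seg.mean_log2 <= cfg.cnv_del_cutoff or seg.mean_log2 >= cfg.cnv_amp_cutoff
            ):
                log.record(seg.sample_id, "", "cnv", "gene_not_eligible",
                           f"dropped:{seg.gene}")
            continue
        if seg.mean_log2 <= cfg.cnv_del_cutoff:
            verdict = DELETION
        elif seg.mean_log2 >= cfg.cnv_amp_cutoff:
            verdict = AMPLIFICATION
        else:
            continue
        gts = gene_map[seg.gene]
        first, last = gts[seg.start_index], gts[seg.end_index - 1]
        call = CNVCall(
            sample_id=seg.sample_id,
            gene=seg.gene,
            chrom=seg.chrom,
            start=first.start + 1,
            end=last.end,
            first_feature=first.feature,
            last_feature=last.feature,
            mean_log2=seg.mean_log2,
            call=verdict,
            n_targets=seg.n_targets,
            at_panel_edge=(seg.start_index == 0 or seg.end_index == len(gts)),
        )
        calls.append(call)
        if log is not None:
            log.record(
                seg.sample_id, "", "cnv", "log2_cutoff",
                f"{verdict}:{seg.gene}:{call.boundaries}",
                evidence_ref=f"mean_log2={seg.mean_log2:.3f};targets={seg.n_targets}",
            )
    return calls


def calls_to_frame(calls: Sequence[CNVCall]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": c.sample_id,
            "gene": c.gene,
            "boundaries": c.boundaries,
            "features": c.feature_span,
            "call": c.call,
            "mean_log2": round(c.mean_log2, 3),
            "n_targets": c.n_targets,
            "at_panel_edge": c.at_panel_edge,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "gene", "boundaries", "features", "call",
            "mean_log2", "n_targets", "at_panel_edge",
        ],
    )
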