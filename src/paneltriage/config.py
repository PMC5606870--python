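"""Central threshold configuration for the panel-triage pipeline.

All stage thresholds live in a single immutable :class:`PipelineConfig` so
that every filter decision in the pipeline is traceable to one document.
Defaults correspond to the study conditions the pipeline emulates: genotypes
kept at read depth >= 20 and genotype quality >= 30, variants dropped at a
minor allele frequency >= 5% in any reference population, a 2-5% "benign by
frequency" band for missense review, a REVEL damaging cutoff of 0.5, and
+/-0.5 log2-ratio cutoffs for exon-level amplification/deletion calls in the
mismatch-repair genes MLH1, MSH2 and MSH6.

The on-disk format is a flat ``key = value`` document; unknown keys are an
error so that typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable


class ConfigError(ValueError):
    """Malformed or invariant-violating configuration."""


DEFAULT_CNV_GENES = ("MLH1", "MSH2", "MSH6")


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds shared by every pipeline stage.

    Parameters
    ----------
    dp_min:
        Minimum genotype read depth (reads); genotypes with ``DP < dp_min``
        are excluded, the boundary value is retained.
    gq_min:
        Minimum genotype quality (Phred); strict ``<`` comparison.
    maf_exclude:
        Variants with a frequency ``>= maf_exclude`` in *any* reference
        population are excluded outright (fraction).
    maf_benign_low:
        Lower edge of the frequency band ``[maf_benign_low, maf_exclude)``
        in which missense variants are called benign by frequency alone.
    revel_cutoff:
        REVEL score at or above which a VUS missense variant is flagged as
        predicted damaging (score in [0, 1]).
    cnv_del_cutoff, cnv_amp_cutoff:
        Segment-mean log2-ratio bounds for deletion (``<= del``) and
        amplification (``>= amp``) calls.
    cov10x_min, cov40x_min, concordance_min:
        Sample-level QC floors: fraction of targets at 10x / 40x depth and
        SNP-panel concordance; strict ``<`` fails.
    cnv_genes:
        Genes eligible for CNV calling (capture depth elsewhere on the panel
        is not designed for dosage analysis).
    cbs_alpha, cbs_permutations:
        Significance level and permutation count for the circular binary
        segmentation change-point test.
    pattern_epsilon:
        Stabilizer added to per-target dispersion when forming weights, and
        to depths inside the log2 ratio.
    min_pattern_samples:
        Minimum samples required to learn a stable coverage pattern.
    seed:
        Base RNG seed for every stochastic component.
    """

    dp_min: int = 20
    gq_min: int = 30
    maf_exclude: float = 0.05
    maf_benign_low: float = 0.02
    revel_cutoff: float = 0.5
    cnv_del_cutoff: float = -0.5
    cnv_amp_cutoff: float = 0.5
    cov10x_min: float = 0.95
    cov40x_min: float = 0.60
    concordance_min: float = 0.95
    cnv_genes: tuple[str, ...] = DEFAULT_CNV_GENES
    cbs_alpha: float = 0.01
    cbs_permutations: int = 10_000
    cbs_min_width: int = 2
    cbs_p_method: str = "maxt"
    cnv_smooth_outliers: bool = True
    pattern_epsilon: float = 1e-3
    min_pattern_samples: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cnv_genes", tuple(self.cnv_genes))
        self.validate()

    def validate(self) -> None:
        if not (0.0 < self.maf_benign_low < self.maf_exclude <= 1.0):
            raise ConfigError(
                "require 0 < maf_benign_low < maf_exclude <= 1 "
                f"(got maf_benign_low={self.maf_benign_low}, maf_exclude={self.maf_exclude})"
            )
        if not (self.cnv_del_cutoff < 0.0 < self.cnv_amp_cutoff):
            raise ConfigError(
                "require cnv_del_cutoff < 0 < cnv_amp_cutoff "
                f"(got {self.cnv_del_cutoff}, {self.cnv_amp_cutoff})"
            )
        if not (0.0 <= self.revel_cutoff <= 1.0):
            raise ConfigError(f"revel_cutoff must be in [0,1], got {self.revel_cutoff}")
        for key in ("cov10x_min", "cov40x_min", "concordance_min"):
            val = getattr(self, key)
            if not (0.0 <= val <= 1.0):
                raise ConfigError(f"{key} must be in [0,1], got {val}")
        if self.dp_min < 0 or self.gq_min < 0:
            raise ConfigError("dp_min and gq_min must be non-negative")
        if not (0.0 < self.cbs_alpha < 1.0):
            raise ConfigError(f"cbs_alpha must be in (0,1), got {self.cbs_alpha}")
        if self.cbs_permutations < 100:
            raise ConfigError("cbs_permutations must be >= 100")
        if self.cbs_min_width < 1:
            raise ConfigError("cbs_min_width must be >= 1")
        if self.cbs_p_method not in ("maxt", "permutation"):
            raise ConfigError(
                f"cbs_p_method must be 'maxt' or 'permutation', got {self.cbs_p_method!r}"
            )
        if self.min_pattern_samples < 2:
            raise ConfigError("min_pattern_samples must be >= 2")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


_INT_KEYS = {
    "dp_min",
    "gq_min",
    "cbs_permutations",
    "cbs_min_width",
    "min_pattern_samples",
    "seed",
}
_STR_KEYS = {"cbs_p_method"}
_BOOL_KEYS = {"cnv_smooth_outliers"}
_FLOAT_KEYS = {
    "maf_exclude",
    "maf_benign_low",
    "revel_cutoff",
    "cnv_del_cutoff",
    "cnv_amp_cutoff",
    "cov10x_min",
    "cov40x_min",
    "concordance_min",
    "cbs_alpha",
    "pattern_epsilon",
}
_LIST_KEYS = {"cnv_genes"}
_ALL_KEYS = _INT_KEYS | _FLOAT_KEYS | _LIST_KEYS | _STR_KEYS | _BOOL_KEYS


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Read a flat ``key = value`` config file; unset keys take the defaults.

    ``path=None`` (or an empty file) yields the default configuration.
    Unknown keys raise :class:`ConfigError` naming the offending key.
    """
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    values: dict[str, object] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in _ALL_KEYS:
            raise ConfigError(f"{path}:{lineno}: unknown config key {key!r}")
        if key in values:
            raise ConfigError(f"{path}:{lineno}: duplicate config key {key!r}")
        try:
            if key in _INT_KEYS:
                values[key] = int(value)
            elif key in _FLOAT_KEYS:
                values[key] = float(value)
            elif key in _STR_KEYS:
                values[key] = value
            elif key in _BOOL_KEYS:
                if value not in ("True", "False", "true", "false", "0", "1"):
                    raise ConfigError(f"{path}:{lineno}: bad boolean for {key!r}: {value!r}")
                values[key] = value in ("True", "true", "1")
            else:
                values[key] = tuple(g.strip() for g in value.split(",") if g.strip())
        except ValueError as exc:
            raise ConfigError(f"{path}:{lineno}: bad value for {key!r}: {value!r}") from exc
    try:
        return PipelineConfig(**values)
    except ConfigError:
        raise
    except TypeError as exc:  # pragma: no cover - guarded by _ALL_KEYS
        raise ConfigError(str(exc)) from exc


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write ``cfg`` as a flat key = value document (round-trips with load)."""
    lines = []
    for f in dataclasses.fields(cfg):
        value = getattr(cfg, f.name)
        if f.name in _LIST_KEYS:
            value = ",".join(value)
        lines.append(f"{f.name} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")


def config_fingerprint(cfg: PipelineConfig) -> str:
    """Stable hash of a config, used in run manifests."""
    import hashlib

    payload = ";".join(
        f"{f.name}={getattr(cfg, f.name)}" for f in dataclasses.fields(cfg)
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
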