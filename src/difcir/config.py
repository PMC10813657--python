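"""Run configuration for the eccDNA genic-profiling pipeline.

The defaults encode the analysis conditions the pipeline was designed
around: breakpoint clusters closer than 10 bp are coalesced, circles
supported by fewer than two split reads are discarded, mitochondrial
circles are excluded, circles above 10 kb are treated as outside the
small-circle regime, and differential calls require a one-unit log2
fold change at a 5% significance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class PipelineConfig:
    """Parameters shared across all pipeline stages.

    Attributes
    ----------
    d_min:
        Maximum breakpoint jitter, in bp, for two circles to be
        considered the same molecule and coalesced (strict ``<``).
    min_split_reads:
        Minimum split-read support for a (post-merge) circle to be kept.
    max_circle_len:
        Upper length cutoff, in bp, defining the small-circle regime.
        The boundary itself is kept; only strictly longer circles drop.
    excluded_chroms:
        Chromosome names removed before quantification (mitochondria by
        default).
    theta_dppgc:
        Selection threshold on the absolute difference of group-mean
        PpGC values (a log2 fold change).
    alpha_dppgc, alpha_cfs, alpha_gwas:
        Significance levels for the differential t-test, the fragile
        site enrichment, and the GWAS-trait enrichment respectively.
    seed:
        Seed feeding every stochastic operation in a run.
    """

    d_min: int = 10
    min_split_reads: int = 2
    max_circle_len: int = 10_000
    excluded_chroms: list[str] = field(default_factory=lambda: ["chrM"])
    theta_dppgc: float = 1.0
    alpha_dppgc: float = 0.05
    alpha_cfs: float = 0.05
    alpha_gwas: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_min < 0:
            raise ValueError("d_min must be >= 0")
        if self.min_split_reads < 0:
            raise ValueError("min_split_reads must be >= 0")
        if self.max_circle_len <= 0:
            raise ValueError("max_circle_len must be positive")
        if self.theta_dppgc < 0:
            raise ValueError("theta_dppgc must be >= 0")
        for name in ("alpha_dppgc", "alpha_cfs", "alpha_gwas"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {a}")
        self.excluded_chroms = list(self.excluded_chroms)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)
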