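"""Synthetic circulomics cohorts with known ground truth.

The generator emulates the data a split-read circle caller emits after
mapping plasma eccDNA libraries: per-sample tables of circle intervals
with split-read support.  Background circles fall uniformly over a
small synthetic genome; in the knockout group a chosen panel of effect
genes additionally excises circles at a multiple of its background
rate, which is what the differential (DPpGC) stage is meant to recover.
Circle lengths follow a truncated two-component normal mixture peaked
at mono- and di-nucleosomal sizes (180 and 360 bp), the dominant
feature of plasma eccDNA length profiles.  Optional breakpoint jitter
re-emits a circle with both coordinates perturbed by less than the
merge distance, exercising the coalescing step.

Defaults mirror the plasma study design the pipeline targets: 12
wild-type and 11 knockout samples, roughly 300 background circles per
sample, circles supported by 2+ split reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_circ import (
    CFS_AGENTS, CfsAnnotation, EccDnaRecord, GeneModel, HomologMap,
    write_cfs_table, write_eccdna_table, write_gene_models, write_manifest,
)


@dataclass
class SimConfig:
    """Knobs of the synthetic cohort.

    gene_length_range is log-uniform in bp (20–200 kb covers typical
    mammalian genes through the large fragile-site genes).  Group sizes
    default to the 12 vs 11 plasma design.  effect_multiplier is the
    fold elevation of an effect gene's per-gene excision rate in the
    knockout group; split_read_mean is the expected support beyond the
    2-read minimum; jitter_prob duplicates a circle with breakpoint
    jitter below d_min.
    """

    n_chroms: int = 5
    genes_per_chrom: int = 40
    gene_length_range: tuple[int, int] = (20_000, 200_000)
    intergenic_gap_range: tuple[int, int] = (5_000, 25_000)
    n_samples_per_group: tuple[int, int] = (12, 11)  # (WT, KO)
    background_rate: float = 300.0
    effect_genes: int = 20
    effect_multiplier: float = 8.0
    length_mixture_means: tuple[float, ...] = (180.0, 360.0)
    length_mixture_sds: tuple[float, ...] = (40.0, 60.0)
    length_mixture_weights: tuple[float, ...] = (0.7, 0.3)
    length_bounds: tuple[int, int] = (50, 10_000)
    split_read_mean: float = 2.0
    jitter_prob: float = 0.1
    d_min: int = 10
    cfs_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chroms", "genes_per_chrom"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(n <= 0 for n in self.n_samples_per_group):
            raise ValueError("group sizes must be positive")
        if self.effect_multiplier < 1:
            raise ValueError("effect_multiplier must be >= 1")
        if abs(sum(self.length_mixture_weights) - 1.0) > 1e-9:
            raise ValueError("length mixture weights must sum to 1")
        if not 0 <= self.jitter_prob <= 1:
            raise ValueError("jitter_prob must lie in [0, 1]")
        if not 0 <= self.cfs_fraction <= 1:
            raise ValueError("cfs_fraction must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticGenome:
    genes: list[GeneModel]
    chrom_lengths: dict[str, int]
    cfs: list[CfsAnnotation]
    homologs: HomologMap

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_lengths.values())


@dataclass
class GroundTruth:
    """What the simulator planted, for scoring pipeline recovery."""

    effect_gene_symbols: set[str]
    groups: dict[str, str]                    # sample -> WT|KO
    provenance: dict[str, list[str]]          # sample -> per-record origin labels
    cfs_table: list[CfsAnnotation] = field(default_factory=list)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    """Independent substream keyed by (seed, counter offsets)."""
    return np.random.default_rng([seed, *stream])


def simulate_genome(config: SimConfig) -> SyntheticGenome:
    """Place non-overlapping genes per chromosome; label a CFS fraction.

    Gene lengths are log-uniform within ``gene_length_range``; genes are
    laid down left to right with log-uniform-free uniform intergenic
    gaps, so placement can never collide.  A ``cfs_fraction`` of genes
    receives a synthetic fragile-site id and a random inducing agent.
    The homolog map is the identity (one synthetic species).
    """
    rng = _rng(config.seed, 0)
    lo, hi = config.gene_length_range
    if not 0 < lo <= hi:
        raise ValueError(f"bad gene_length_range {config.gene_length_range}")
    genes: list[GeneModel] = []
    chrom_lengths: dict[str, int] = {}
    for c in range(1, config.n_chroms + 1):
        chrom = f"chr{c}"
        pos = int(rng.integers(*config.intergenic_gap_range))
        for g in range(1, config.genes_per_chrom + 1):
            length = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            symbol = f"Gene{c}_{g:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(symbol, symbol, chrom, pos, pos + length, strand))
            pos += length + int(rng.integers(*config.intergenic_gap_range))
        chrom_lengths[chrom] = pos
    n_cfs = int(round(config.cfs_fraction * len(genes)))
    cfs_rows: list[CfsAnnotation] = []
    if n_cfs:
        picked = rng.choice(len(genes), size=n_cfs, replace=False)
        for j, gi in enumerate(sorted(picked)):
            g = genes[gi]
            agent = CFS_AGENTS[int(rng.integers(len(CFS_AGENTS)))]
            cfs_rows.append(CfsAnnotation(g.symbol, f"FRA{g.chrom[3:]}S{j:03d}",
                                          g.chrom, agent))
    return SyntheticGenome(genes, chrom_lengths, cfs_rows, HomologMap.identity())


def _draw_length(rng: np.random.Generator, config: SimConfig) -> int:
    lo, hi = config.length_bounds
    comp = rng.choice(len(config.length_mixture_weights), p=config.length_mixture_weights)
    for _ in range(1000):
        x = rng.normal(config.length_mixture_means[comp], config.length_mixture_sds[comp])
        if lo <= x <= hi:
            return int(round(x))
    return lo  # pathological mixture; fall back to the lower bound


def _place_circle(rng: np.random.Generator, genome: SyntheticGenome,
                  config: SimConfig, sample: str,
                  chrom: str | None = None,
                  within: tuple[int, int] | None = None) -> EccDnaRecord:
    length = _draw_length(rng, config)
    if chrom is None:
        chroms = list(genome.chrom_lengths)
        weights = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
        chrom = chroms[rng.choice(len(chroms), p=weights / weights.sum())]
    lo, hi = within if within is not None else (0, genome.chrom_lengths[chrom])
    length = min(length, hi - lo - 1) if hi - lo > 1 else 1
    start = int(rng.integers(lo, hi - length))
    sr = 2 + int(rng.poisson(config.split_read_mean))
    return EccDnaRecord(sample, chrom, start, start + length, sr)


def simulate_cohort(config: SimConfig, genome: SyntheticGenome
                    ) -> tuple[dict[str, list[EccDnaRecord]], GroundTruth]:
    """Emit per-sample circle tables plus the planted ground truth.

    Every sample draws Poisson(background_rate) circles uniformly over
    the genome.  Knockout samples additionally draw, for each effect
    gene, Poisson(lambda_g · effect_multiplier) circles inside the gene
    body, where lambda_g = background_rate · L_g / genome_length is the
    gene's expected background load.  With probability jitter_prob a
    circle is re-emitted with both breakpoints perturbed by less than
    d_min (so coalescing recovers it).
    """
    effect_rng = _rng(config.seed, 1)
    n_effect = min(config.effect_genes, len(genome.genes))
    effect_idx = sorted(effect_rng.choice(len(genome.genes), size=n_effect,
                                          replace=False)) if n_effect else []
    effect_genes = [genome.genes[i] for i in effect_idx]
    effect_symbols = {g.symbol for g in effect_genes}

    n_wt, n_ko = config.n_samples_per_group
    samples = [(f"WT_{i+1:02d}", "WT") for i in range(n_wt)] + \
              [(f"KO_{i+1:02d}", "KO") for i in range(n_ko)]
    genome_length = genome.genome_length
    cohort: dict[str, list[EccDnaRecord]] = {}
    provenance: dict[str, list[str]] = {}
    for s_idx, (sample, group) in enumerate(samples):
        rng = _rng(config.seed, 2, s_idx)
        records: list[EccDnaRecord] = []
        origins: list[str] = []
        for _ in range(int(rng.poisson(config.background_rate))):
            records.append(_place_circle(rng, genome, config, sample))
            origins.append("background")
        if group == "KO":
            for gene in effect_genes:
                lam = config.background_rate * gene.length / genome_length
                for _ in range(int(rng.poisson(lam * config.effect_multiplier))):
                    records.append(_place_circle(rng, genome, config, sample,
                                                 chrom=gene.chrom,
                                                 within=(gene.start, gene.end)))
                    origins.append(f"planted:{gene.symbol}")
        if config.jitter_prob > 0 and config.d_min > 1:
            jittered: list[EccDnaRecord] = []
            j_origins: list[str] = []
            for rec, origin in zip(list(records), list(origins)):
                if rng.random() < config.jitter_prob:
                    ds = int(rng.integers(-(config.d_min - 1), config.d_min))
                    de = int(rng.integers(-(config.d_min - 1), config.d_min))
                    start = max(0, rec.start + ds)
                    end = max(start + 1, rec.end + de)
                    sr = 2 + int(rng.poisson(config.split_read_mean))
                    jittered.append(EccDnaRecord(sample, rec.chrom, start, end, sr))
                    j_origins.append("jitter-dup")
            records.extend(jittered)
            origins.extend(j_origins)
        cohort[sample] = records
        provenance[sample] = origins
    truth = GroundTruth(
        effect_gene_symbols=effect_symbols,
        groups={s: g for s, g in samples},
        provenance=provenance,
        cfs_table=list(genome.cfs),
    )
    return cohort, truth


def write_cohort(out_dir: str | Path, config: SimConfig,
                 genome: SyntheticGenome,
                 cohort: dict[str, list[EccDnaRecord]],
                 truth: GroundTruth) -> None:
    """Write genes.bed, cfs.tsv, manifest.tsv, per-sample .ecc.tsv, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gene_models(genome.genes, out / "genes.bed")
    write_cfs_table(genome.cfs, out / "cfs.tsv")
    rows = []
    for sample, records in cohort.items():
        path = out / f"{sample}.ecc.tsv"
        write_eccdna_table(records, path, with_sample_id=False)
        rows.append({"sample_id": sample, "path": path.name,
                     "group": truth.groups[sample], "tissue": "plasma",
                     "protocol": "Tn"})
    write_manifest(pd.DataFrame(rows), out / "manifest.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump({
            "config": config.to_dict(),
            "effect_gene_symbols": sorted(truth.effect_gene_symbols),
            "groups": truth.groups,
            "provenance_counts": {
                s: {o: labels.count(o) for o in set(labels)}
                for s, labels in truth.provenance.items()
            },
        }, fh, indent=1)
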