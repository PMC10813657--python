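"""Set- and locus-level enrichment statistics.

All enrichment questions here reduce to an upper-tail hypergeometric
test reported as a mid-p-value, P(X > k) + 0.5·P(X = k): the mid-p
counts the observed outcome at half weight, which removes most of the
conservativeness of the discrete exact test.  Only enrichment (the
upper tail) is tested; depletion is reported descriptively through a
negative chromosome landscape percentage, not a lower-tail p-value.

Star labels follow decade brackets: one star for 0.01 ≥ p > 0.001, two
for 0.001 ≥ p > 0.0001, and so on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_circ import CfsAnnotation, EccDnaRecord, GeneModel, HomologMap


@dataclass(frozen=True)
class HypergeomQuery:
    """k successes seen in n_draws, from a population of N holding K successes."""

    k: int
    n_draws: int
    K: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.n_draws <= self.N):
            raise ValueError(f"invalid hypergeometric population: {self}")
        if not (max(0, self.n_draws + self.K - self.N) <= self.k <= min(self.n_draws, self.K)):
            raise ValueError(f"k={self.k} outside the support of {self}")


@dataclass
class ChromEnrichmentRow:
    """One chromosome of the DPpGC landscape."""

    chrom: str
    nd_c: int      # DPpGC genes on this chromosome
    n_c: int       # eccDNAs on this chromosome
    nd_g: int      # DPpGC genes genome-wide
    n_g: int       # eccDNAs genome-wide
    delta_c: float  # 100*(nd_c/n_c - nd_g/n_g)
    mid_p: float
    stars: str


@dataclass
class EnrichmentResult:
    """Category-level over-representation result."""

    label: str
    k: int
    n_draws: int
    K: int
    N: int
    percentage: float  # 100*k/n_draws
    mid_p: float
    stars: str
    members: list = field(default_factory=list)
    flagged: bool = False
    significant: bool = False


def hypergeom_midp(q: HypergeomQuery) -> float:
    """Upper-tail mid-p-value: P(X > k) + 0.5·P(X = k)."""
    dist = stats.hypergeom(q.N, q.K, q.n_draws)
    return float(dist.sf(q.k) + 0.5 * dist.pmf(q.k))


def significance_stars(p: float, max_stars: int = 12) -> str:
    """Decade star label: k stars when p in (10^-(k+2), 10^-(k+1)], empty above 0.01."""
    if not 0 < p <= 1:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    if p > 0.01:
        return ""
    k = 1
    while k < max_stars and p <= 10.0 ** -(k + 2):
        k += 1
    return "*" * k


# ---------------------------------------------------------------------------
# chromosome landscape
# ---------------------------------------------------------------------------

def chromosome_enrichment(dppgc_genes: Iterable[str],
                          eccdna_records: Iterable[EccDnaRecord],
                          genes: Sequence[GeneModel],
                          genes_as_units: bool = False) -> list[ChromEnrichmentRow]:
    """Chromosome landscape of DPpGC enrichment/depletion.

    For each chromosome c, the landscape percentage is
    Δc = 100·(Nd_c/N_c − Nd_g/N_g), with Nd_c the DPpGC genes on c and
    N_c the eccDNAs on c (cohort-wide post-filter records).  The
    companion mid-p uses the same counts (population N_g, successes
    N_c, draws Nd_g, observed Nd_c).  ``genes_as_units=True`` replaces
    eccDNA counts with annotated-gene counts for both denominator and
    population.  Chromosomes with zero eccDNAs are omitted.
    """
    by_symbol = {g.symbol: g.chrom for g in genes}
    dppgc_genes = list(dppgc_genes)
    for s in dppgc_genes:
        if s not in by_symbol:
            raise ValueError(f"DPpGC gene {s!r} absent from the gene models")
    if genes_as_units:
        n_per_chrom: dict[str, int] = {}
        for g in genes:
            n_per_chrom[g.chrom] = n_per_chrom.get(g.chrom, 0) + 1
    else:
        n_per_chrom = {}
        for r in eccdna_records:
            n_per_chrom[r.chrom] = n_per_chrom.get(r.chrom, 0) + 1
    nd_per_chrom: dict[str, int] = {}
    for s in dppgc_genes:
        c = by_symbol[s]
        nd_per_chrom[c] = nd_per_chrom.get(c, 0) + 1
    n_g = sum(n_per_chrom.values())
    nd_g = len(dppgc_genes)
    if n_g == 0:
        return []
    rows = []
    for chrom in sorted(n_per_chrom):
        n_c = n_per_chrom[chrom]
        nd_c = nd_per_chrom.get(chrom, 0)
        delta_c = 100.0 * (nd_c / n_c - nd_g / n_g)
        q = HypergeomQuery(k=nd_c, n_draws=nd_g, K=n_c, N=n_g)
        mp = hypergeom_midp(q)
        rows.append(ChromEnrichmentRow(chrom, nd_c, n_c, nd_g, n_g, delta_c,
                                       mp, significance_stars(mp)))
    return rows


def chromosome_enrichment_table(rows: Sequence[ChromEnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": r.chrom, "Nd_c": r.nd_c, "N_c": r.n_c,
        "Nd_g": r.nd_g, "N_g": r.n_g, "delta_c": r.delta_c,
        "mid_p": r.mid_p, "stars": r.stars,
    } for r in rows])


# ---------------------------------------------------------------------------
# set over-representation
# ---------------------------------------------------------------------------

def set_enrichment(hits: Iterable[str], universe: Iterable[str],
                   target_set: Iterable[str], label: str = "",
                   alpha: float = 0.05) -> EnrichmentResult:
    """Hypergeometric mid-p over-representation of ``target_set`` in ``hits``.

    ``hits`` must be a subset of ``universe``; target membership is
    evaluated within the universe.  The reported percentage is
    100·|hits ∩ target| / |hits|.  Empty hits give percentage 0 and
    mid-p 1, flagged.
    """
    hits = set(hits)
    universe = set(universe)
    target = set(target_set) & universe
    if not hits <= universe:
        stray = sorted(hits - universe)[:5]
        raise ValueError(f"hits not contained in universe, e.g. {stray}")
    if not hits:
        return EnrichmentResult(label, 0, 0, len(target), len(universe),
                                0.0, 1.0, "", [], flagged=True)
    k = len(hits & target)
    q = HypergeomQuery(k=k, n_draws=len(hits), K=len(target), N=len(universe))
    mp = hypergeom_midp(q)
    return EnrichmentResult(
        label=label, k=k, n_draws=len(hits), K=len(target), N=len(universe),
        percentage=100.0 * k / len(hits), mid_p=mp, stars=significance_stars(mp),
        members=sorted(hits & target), significant=mp <= alpha,
    )


def gmt_enrichment(hits: Iterable[str], universe: Iterable[str],
                   gene_sets: Mapping[str, set[str]],
                   alpha: float = 0.05) -> list[EnrichmentResult]:
    """Over-representation of every GMT set among the hits."""
    hits, universe = set(hits), set(universe)
    return [set_enrichment(hits, universe, members, label=name, alpha=alpha)
            for name, members in gene_sets.items()]


# ---------------------------------------------------------------------------
# fragile sites, GWAS, cross-species intersection
# ---------------------------------------------------------------------------

def annotate_cfs(genes: Iterable[str], cfs: Iterable[CfsAnnotation],
                 homologs: HomologMap | None = None) -> dict[str, list[tuple[str, str]]]:
    """Label each gene with its (fragile-site id, agent) pairs.

    Symbols pass through the homolog map first (identity when None);
    matching is case-insensitive after mapping.  Unmapped or unlisted
    genes come back with an empty list — pooled fragile-site membership
    is simply a non-empty label list.
    """
    homologs = homologs or HomologMap.identity()
    by_symbol: dict[str, list[tuple[str, str]]] = {}
    for row in cfs:
        by_symbol.setdefault(row.gene_symbol.casefold(), []).append((row.cfs_id, row.agent))
    out: dict[str, list[tuple[str, str]]] = {}
    for gene in genes:
        labels: list[tuple[str, str]] = []
        for mapped in homologs.lookup(gene):
            for pair in by_symbol.get(mapped.casefold(), []):
                if pair not in labels:
                    labels.append(pair)
        out[gene] = labels
    return out


def cfs_enrichment(hits: Iterable[str], universe: Iterable[str],
                   cfs: Iterable[CfsAnnotation],
                   homologs: HomologMap | None = None,
                   label: str = "CFS (pooled)",
                   alpha: float = 0.05) -> EnrichmentResult:
    """Pooled-agent fragile-site enrichment among the hits.

    Universe genes are homolog-mapped onto the fragile-site catalog;
    the pooled category is the union over all agents.
    """
    universe = set(universe)
    labels = annotate_cfs(universe, cfs, homologs)
    target = {g for g, pairs in labels.items() if pairs}
    result = set_enrichment(hits, universe, target, label=label, alpha=alpha)
    hit_labels = {g: labels[g] for g in result.members}
    result.members = [(g, hit_labels[g]) for g in result.members]
    return result


_GENE_CELL_SPLIT = re.compile(r"\s*(?:,|;|\s+-\s+)\s*")


def split_mapped_genes(cell: str) -> list[str]:
    """Split a GWAS mapped-gene cell on comma, semicolon, or ' - '."""
    return [g for g in _GENE_CELL_SPLIT.split(cell.strip()) if g]


def gwas_intersect(genes: Iterable[str], gwas_table: pd.DataFrame, trait: str,
                   universe: Iterable[str],
                   homologs: HomologMap | None = None,
                   alpha: float = 0.05) -> tuple[list[str], EnrichmentResult]:
    """Intersect query genes with a GWAS-Catalog trait's mapped genes.

    The trait is matched as an exact string against the DISEASE/TRAIT
    column.  Query symbols are homolog-mapped (identity when None) and
    compared case-insensitively with the trait's mapped genes.  Returns
    the common query symbols plus the enrichment within ``universe``.
    """
    homologs = homologs or HomologMap.identity()
    rows = gwas_table[gwas_table["DISEASE/TRAIT"] == trait]
    trait_genes: set[str] = set()
    for cell in rows["MAPPED_GENE"]:
        trait_genes.update(g.casefold() for g in split_mapped_genes(str(cell)))
    flagged = rows.empty

    def hits_trait(symbol: str) -> bool:
        return any(m.casefold() in trait_genes for m in homologs.lookup(symbol))

    genes = list(genes)
    common = [g for g in genes if hits_trait(g)]
    universe = set(universe)
    target = {g for g in universe if hits_trait(g)}
    result = set_enrichment(set(genes) & universe, universe, target,
                            label=trait, alpha=alpha)
    result.flagged = result.flagged or flagged
    result.members = common
    return common, result


def intersect_profiles(genes_a: Sequence[str], genes_b: Iterable[str],
                       homologs: HomologMap) -> list[tuple[str, str]]:
    """Cross-species intersection of two gene profiles.

    Maps each species-A symbol through the homolog map and keeps pairs
    whose target is present in ``genes_b`` (case-insensitive).
    Deduplicated, in the rank order of ``genes_a``.
    """
    b_by_fold = {g.casefold(): g for g in genes_b}
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for a in genes_a:
        for target in homologs.lookup(a):
            hit = b_by_fold.get(target.casefold())
            if hit is not None and (a, hit) not in seen:
                seen.add((a, hit))
                pairs.append((a, hit))
    return pairs
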