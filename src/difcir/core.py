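"""Circle-level preprocessing and group-level count/length statistics.

Split-read circle callers report the same molecule with a few base
pairs of breakpoint jitter between libraries.  ``merge_clusters``
coalesces such near-duplicates within one sample: circles whose start
coordinates differ by less than ``d_min`` AND whose end coordinates
differ by less than ``d_min`` are linked, clusters are the transitive
closure of that relation, and each cluster collapses onto its
best-supported member while split reads are summed.  Filtering then
removes weakly supported circles, excluded chromosomes (mitochondria),
and circles above the small-circle length cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb, sqrt
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .io_circ import EccDnaRecord


@dataclass
class GroupCountSummary:
    """Per-group summary of per-sample unique circle counts (mean ± sem)."""

    group: str
    n_samples: int
    per_sample_counts: list[int]
    mean: float
    sem: float


@dataclass
class LengthCdf:
    """Group-level cumulative length distribution with a per-bin sd band.

    ``per_sample_cumulative_percent`` is a samples × bins matrix of the
    cumulative percentage of circle lengths ≤ each edge; every row is
    non-decreasing and ends at 100 when the last edge covers the data.
    """

    group: str
    sample_ids: list[str]
    bin_edges: np.ndarray
    per_sample_cumulative_percent: np.ndarray
    mean_curve: np.ndarray
    sd_band: np.ndarray


# ---------------------------------------------------------------------------
# merging and filtering
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def merge_clusters(records: Sequence[EccDnaRecord], d_min: int) -> list[EccDnaRecord]:
    """Coalesce breakpoint-jittered duplicate circles within one sample.

    Two records link when they share a chromosome and both their start
    and end coordinates differ by strictly less than ``d_min``; clusters
    are the transitive closure.  Each cluster is replaced by the
    coordinates of the member with the most split reads (ties broken by
    smallest start, then smallest end) carrying the cluster's summed
    split reads, so total split-read support is conserved exactly.

    Output is sorted by (chrom, start, end); the operation is idempotent
    and invariant to input order.
    """
    if d_min < 0:
        raise ValueError("d_min must be >= 0")
    records = list(records)
    if not records:
        return []
    samples = {r.sample_id for r in records}
    if len(samples) > 1:
        raise ValueError(f"merge_clusters expects one sample, got {sorted(samples)}")
    # sort by (chrom, start): linkable pairs are within a d_min start window
    order = sorted(range(len(records)), key=lambda i: (records[i].chrom, records[i].start, records[i].end))
    uf = _UnionFind(len(records))
    for a in range(len(order)):
        i = order[a]
        ri = records[i]
        for b in range(a + 1, len(order)):
            j = order[b]
            rj = records[j]
            if rj.chrom != ri.chrom or rj.start - ri.start >= d_min:
                break
            if abs(rj.end - ri.end) < d_min:
                uf.union(i, j)
    clusters: dict[int, list[EccDnaRecord]] = {}
    for i, r in enumerate(records):
        clusters.setdefault(uf.find(i), []).append(r)
    merged = []
    for members in clusters.values():
        rep = min(members, key=lambda r: (-r.split_reads, r.start, r.end))
        total = sum(r.split_reads for r in members)
        merged.append(EccDnaRecord(rep.sample_id, rep.chrom, rep.start, rep.end, total))
    merged.sort(key=lambda r: (r.chrom, r.start, r.end))
    return merged


def apply_filters(records: Iterable[EccDnaRecord], config: PipelineConfig) -> list[EccDnaRecord]:
    """Drop weakly supported, excluded-chromosome, and over-long circles.

    Keeps records with ``split_reads >= min_split_reads``, chromosome
    not in ``excluded_chroms``, and ``length <= max_circle_len`` (the
    boundary is kept).  Order is preserved; output is a subset of input.
    """
    excluded = set(config.excluded_chroms)
    return [
        r for r in records
        if r.split_reads >= config.min_split_reads
        and r.chrom not in excluded
        and r.length <= config.max_circle_len
    ]


def preprocess_sample(records: Sequence[EccDnaRecord], config: PipelineConfig) -> list[EccDnaRecord]:
    """merge_clusters followed by apply_filters (the per-sample pipeline step)."""
    return apply_filters(merge_clusters(records, config.d_min), config)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def sample_counts(cohort: Mapping[str, Sequence[EccDnaRecord]],
                  groups: Mapping[str, str]) -> list[GroupCountSummary]:
    """Unique-circle counts per sample, summarised per group as mean ± sem.

    ``sem`` is the standard error of the mean, sd/sqrt(n) with the
    sample (n−1) standard deviation; it is 0 for a single-sample group.
    """
    missing = [s for s in cohort if s not in groups]
    if missing:
        raise ValueError(f"samples without a group assignment: {missing}")
    by_group: dict[str, list[int]] = {}
    for sample, records in cohort.items():
        by_group.setdefault(groups[sample], []).append(len(records))
    out = []
    for group in sorted(by_group):
        counts = by_group[group]
        n = len(counts)
        mean = float(np.mean(counts))
        sem = float(np.std(counts, ddof=1) / sqrt(n)) if n > 1 else 0.0
        out.append(GroupCountSummary(group, n, counts, mean, sem))
    return out


def mean_fold_ratio(x: Sequence[float], y: Sequence[float]) -> float:
    """Ratio of the two group means, mean(x)/mean(y)."""
    mx, my = float(np.mean(x)), float(np.mean(y))
    if my == 0:
        raise ValueError("mean of the denominator group is zero")
    return mx / my


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _exact_ranksum_pvalue(n_x: int, n_y: int, w: float) -> float:
    """Exact two-sided rank-sum p by counting rank subsets.

    ``counts[s]`` accumulates the number of n_x-subsets of ranks
    {1..n_x+n_y} summing to s; the p-value is
    2·min(P(W ≤ w), P(W ≥ w)) capped at 1.
    """
    n = n_x + n_y
    max_sum = n * (n + 1) // 2
    # dp[j][s]: subsets of size j with rank-sum s
    dp = np.zeros((n_x + 1, max_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for rank in range(1, n + 1):
        for j in range(min(rank, n_x), 0, -1):
            dp[j, rank:] += dp[j - 1, : max_sum + 1 - rank]
    counts = dp[n_x]
    total = comb(n, n_x)
    w_int = int(round(w))
    p_le = counts[: w_int + 1].sum() / total
    p_ge = counts[w_int:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W statistic, p-value).

    W is the sum of the ranks of ``x`` in the pooled sample (midranks
    for ties).  The p-value is exact (full enumeration of rank
    assignments) when n_x + n_y ≤ 16 and the pooled data are tie-free;
    otherwise a normal approximation with tie correction and a 0.5
    continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    n_x, n_y, n = x.size, y.size, pooled.size
    has_ties = np.unique(pooled).size < n
    if n <= 16 and not has_ties:
        return w, _exact_ranksum_pvalue(n_x, n_y, w)
    mu = n_x * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # every observation identical
        return w, 1.0
    z = max(abs(w - mu) - 0.5, 0.0) / sqrt(var)
    return w, float(min(1.0, 2.0 * stats.norm.sf(z)))


# ---------------------------------------------------------------------------
# length distribution
# ---------------------------------------------------------------------------

def length_cdf(cohort: Mapping[str, Sequence[EccDnaRecord]],
               groups: Mapping[str, str],
               bin_edges: Sequence[float]) -> list[LengthCdf]:
    """Per-sample cumulative length curves with a group mean and sd band.

    The curve value at edge e is the percentage of the sample's circle
    lengths ≤ e.  Samples with zero circles have no curve; they are
    skipped with a warning.  The sd band uses the across-sample (n−1)
    standard deviation per bin (zero for a single curve).
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size == 0 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing")
    by_group: dict[str, list[tuple[str, np.ndarray]]] = {}
    for sample, records in cohort.items():
        if sample not in groups:
            raise ValueError(f"sample {sample!r} has no group assignment")
        lengths = np.array([r.length for r in records], dtype=float)
        if lengths.size == 0:
            warnings.warn(f"sample {sample!r} has no circles; skipped in length CDF")
            continue
        counts = np.searchsorted(np.sort(lengths), edges, side="right")
        curve = 100.0 * counts / lengths.size
        by_group.setdefault(groups[sample], []).append((sample, curve))
    out = []
    for group in sorted(by_group):
        pairs = by_group[group]
        matrix = np.vstack([c for _, c in pairs])
        sd = matrix.std(axis=0, ddof=1) if matrix.shape[0] > 1 else np.zeros(edges.size)
        out.append(LengthCdf(
            group=group,
            sample_ids=[s for s, _ in pairs],
            bin_edges=edges,
            per_sample_cumulative_percent=matrix,
            mean_curve=matrix.mean(axis=0),
            sd_band=sd,
        ))
    return out
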