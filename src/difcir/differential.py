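"""The DifCir differential test: call DPpGCs between two sample groups.

For each gene the two group means of the (log2-scale) PpGC values are
compared.  A gene is a differentially produced per-gene circle (DPpGC)
when the absolute difference of the means — the log2 fold change —
reaches the selection threshold theta AND the two-sample Student t-test
(pooled variance, two-sided) reaches significance alpha.  "up in A"
means the A group has the higher mean.  Selected genes are ranked per
direction by ascending p-value, ties by descending |delta|, then by
symbol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .ppgc import PpGCMatrix


@dataclass
class DppgcRecord:
    """Per-gene differential result."""

    symbol: str
    mean_a: float
    mean_b: float
    delta: float       # mean_a - mean_b, the log2 fold change
    p_value: float
    neglog10_p: float
    direction: str     # "up_in_a" | "up_in_b"
    rank: int          # 1-based within direction


@dataclass
class DifCirResult:
    group_a: str
    group_b: str
    up_in_a: list[DppgcRecord]
    up_in_b: list[DppgcRecord]
    full_table: pd.DataFrame


def _pooled_ttest(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised equal-variance two-sample t-test over matrix rows.

    Returns (t, p, degenerate) where ``degenerate`` flags rows with zero
    variance in both groups; for those, p is 0 when the means differ
    and 1 when they coincide.
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    degenerate = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    p = np.empty_like(t)
    ok = ~degenerate
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=na + nb - 2)
    p[degenerate] = np.where(ma[degenerate] == mb[degenerate], 1.0, 0.0)
    t[degenerate] = np.where(ma[degenerate] == mb[degenerate], 0.0, np.inf)
    return t, p, degenerate


def _welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    degenerate = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = np.empty_like(t)
    ok = ~degenerate
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=df[ok])
    p[degenerate] = np.where(ma[degenerate] == mb[degenerate], 1.0, 0.0)
    t[degenerate] = np.where(ma[degenerate] == mb[degenerate], 0.0, np.inf)
    return t, p, degenerate


def call_dppgc(matrix: PpGCMatrix,
               groups: Mapping[str, str],
               config: PipelineConfig | None = None,
               group_a: str | None = None,
               group_b: str | None = None,
               welch: bool = False,
               benjamini_hochberg: bool = False) -> DifCirResult:
    """Call differentially produced per-gene eccDNAs between two groups.

    Parameters
    ----------
    matrix:
        PpGC matrix; genes with all-zero raw rows in both groups are
        excluded before testing.
    groups:
        sample id → group label; exactly the samples of the two
        compared groups are used, each needing ≥ 2 samples.
    group_a, group_b:
        Labels of the two groups.  Default: the first two labels in
        sorted order.
    welch:
        Use the Welch (unequal-variance) t-test instead of the
        classical pooled-variance Student test.
    benjamini_hochberg:
        Select on BH-adjusted q-values instead of raw p-values (the
        adjusted column ``q_value`` is added either way when enabled).

    Returns the two ranked selected lists plus the full per-gene table
    (columns: symbol, mean_a, mean_b, delta, p_value, neglog10_p,
    direction, selected, degenerate, rank) for volcano-style export.
    """
    config = config or PipelineConfig()
    labels = sorted({groups[s] for s in matrix.samples if s in groups})
    if group_a is None or group_b is None:
        if len(labels) < 2:
            raise ValueError("need two groups among the matrix samples")
        group_a = group_a or labels[0]
        group_b = group_b or (labels[1] if labels[1] != group_a else labels[0])
    samples_a = [s for s in matrix.samples if groups.get(s) == group_a]
    samples_b = [s for s in matrix.samples if groups.get(s) == group_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"each group needs >= 2 samples; got {len(samples_a)} in {group_a!r} "
            f"and {len(samples_b)} in {group_b!r}"
        )

    used = samples_a + samples_b
    nonzero = (matrix.raw[used].sum(axis=1) > 0).to_numpy()
    values = matrix.values.loc[nonzero]
    a = values[samples_a].to_numpy(dtype=float)
    b = values[samples_b].to_numpy(dtype=float)

    test = _welch_ttest if welch else _pooled_ttest
    _, p, degenerate = test(a, b)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    delta = mean_a - mean_b

    table = pd.DataFrame({
        "symbol": values.index,
        "mean_a": mean_a,
        "mean_b": mean_b,
        "delta": delta,
        "p_value": p,
        "degenerate": degenerate,
    }).reset_index(drop=True)
    with np.errstate(divide="ignore"):
        table["neglog10_p"] = -np.log10(table["p_value"].to_numpy())
    table["direction"] = np.where(table["delta"] >= 0, "up_in_a", "up_in_b")

    p_select = table["p_value"].to_numpy()
    if benjamini_hochberg:
        table["q_value"] = stats.false_discovery_control(
            np.clip(table["p_value"].to_numpy(), 0.0, 1.0), method="bh")
        p_select = table["q_value"].to_numpy()
    table["selected"] = (np.abs(table["delta"]) >= config.theta_dppgc) & \
                        (p_select <= config.alpha_dppgc)

    table["rank"] = 0
    lists: dict[str, list[DppgcRecord]] = {"up_in_a": [], "up_in_b": []}
    for direction in ("up_in_a", "up_in_b"):
        sel = table[table["selected"] & (table["direction"] == direction)]
        sel = sel.sort_values(
            by=["p_value", "delta", "symbol"],
            key=lambda col: -col.abs() if col.name == "delta" else col,
        )
        for rank, (idx, row) in enumerate(sel.iterrows(), start=1):
            table.loc[idx, "rank"] = rank
            lists[direction].append(DppgcRecord(
                symbol=row["symbol"],
                mean_a=float(row["mean_a"]),
                mean_b=float(row["mean_b"]),
                delta=float(row["delta"]),
                p_value=float(row["p_value"]),
                neglog10_p=float(row["neglog10_p"]),
                direction=direction,
                rank=rank,
            ))
    return DifCirResult(group_a, group_b, lists["up_in_a"], lists["up_in_b"], table)


def write_dppgc_table(result: DifCirResult, path) -> None:
    """Export the full per-gene table as TSV (volcano-plot quantities)."""
    cols = ["symbol", "mean_a", "mean_b", "delta", "p_value", "neglog10_p",
            "direction", "selected", "degenerate", "rank"]
    extra = [c for c in result.full_table.columns if c not in cols]
    result.full_table[cols + extra].to_csv(path, sep="\t", index=False)
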