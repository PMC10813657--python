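"""End-to-end orchestration: preprocess -> quantify -> differential -> enrich.

Given a cohort manifest, the pipeline runs every configured group pair
in both directions, writing per-stage TSVs and one reproducibility
manifest (JSON) per output directory.  All stages are deterministic
given the inputs and the configured seed, so re-running with an
identical manifest reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .core import length_cdf, preprocess_sample, sample_counts
from .differential import DifCirResult, call_dppgc, write_dppgc_table
from .enrichment import (
    cfs_enrichment, chromosome_enrichment, chromosome_enrichment_table,
    gmt_enrichment, gwas_intersect,
)
from .io_circ import (
    CfsAnnotation, EccDnaRecord, GeneModel, HomologMap,
    read_eccdna_table, read_gene_models, read_manifest, write_eccdna_table,
)
from .ppgc import PpGCMatrix, quantify

log = logging.getLogger("difcir")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_cohort(manifest: pd.DataFrame, base_dir: str | Path
                ) -> tuple[dict[str, list[EccDnaRecord]], dict[str, str]]:
    """Read every sample table listed in a manifest; returns (cohort, groups)."""
    base = Path(base_dir)
    cohort: dict[str, list[EccDnaRecord]] = {}
    groups: dict[str, str] = {}
    for _, row in manifest.iterrows():
        path = Path(row["path"])
        if not path.is_absolute():
            path = base / path
        cohort[row["sample_id"]] = read_eccdna_table(path, sample_id=row["sample_id"])
        groups[row["sample_id"]] = row["group"]
    return cohort, groups


def preprocess_cohort(cohort: Mapping[str, list[EccDnaRecord]],
                      config: PipelineConfig) -> dict[str, list[EccDnaRecord]]:
    """Merge and filter every sample, logging in/out record counts."""
    out = {}
    for sample, records in cohort.items():
        kept = preprocess_sample(records, config)
        log.info("preprocess %s: %d records in, %d out", sample, len(records), len(kept))
        out[sample] = kept
    return out


def run_pipeline(manifest_path: str | Path,
                 genes_path: str | Path,
                 out_dir: str | Path,
                 config: PipelineConfig | None = None,
                 genes_dialect: str = "bed",
                 cfs: Sequence[CfsAnnotation] = (),
                 homologs: HomologMap | None = None,
                 gwas: pd.DataFrame | None = None,
                 gwas_trait: str | None = None,
                 gene_sets: Mapping[str, set[str]] | None = None,
                 group_pairs: Sequence[tuple[str, str]] | None = None) -> Path:
    """Run every stage for every group pair, in both directions.

    Writes per-sample filtered circle tables, a counts summary, the
    PpGC matrix, per-comparison DPpGC tables, chromosome landscapes,
    a Table-1-style enrichment summary, and a run manifest.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    genes = read_gene_models(genes_path, dialect=genes_dialect)
    cohort_raw, groups = load_cohort(manifest, manifest_path.parent)

    labels = sorted(set(groups.values()))
    if len(labels) < 2:
        raise ValueError("pipeline needs at least two sample groups")
    if group_pairs is None:
        group_pairs = list(combinations(labels, 2))

    # stage 1: preprocess
    cohort = preprocess_cohort(cohort_raw, config)
    for sample, records in cohort.items():
        write_eccdna_table(records, out / f"{sample}.ecc.tsv", with_sample_id=False)
    counts = sample_counts(cohort, groups)
    pd.DataFrame([{
        "group": c.group, "n_samples": c.n_samples, "mean": c.mean, "sem": c.sem,
        "per_sample_counts": ",".join(map(str, c.per_sample_counts)),
    } for c in counts]).to_csv(out / "counts_summary.tsv", sep="\t", index=False)

    # stage 2: quantify
    matrix = quantify(cohort, genes)
    matrix.values.to_csv(out / "ppgc.tsv", sep="\t", index_label="symbol")
    matrix.raw.to_csv(out / "ppgc_raw.tsv", sep="\t", index_label="symbol")

    universe = [g for g in matrix.genes if g not in set(matrix.zero_genes)]
    all_records = [r for records in cohort.values() for r in records]

    # stages 3-4: differential + enrichment per pair, both directions
    summary_rows = []
    results: dict[tuple[str, str], DifCirResult] = {}
    for ga, gb in group_pairs:
        res = call_dppgc(matrix, groups, config, group_a=ga, group_b=gb)
        results[(ga, gb)] = res
        tag = f"{ga}_vs_{gb}"
        write_dppgc_table(res, out / f"dppgc_{tag}.tsv")
        for direction, records in (("up_in_" + ga, res.up_in_a),
                                   ("up_in_" + gb, res.up_in_b)):
            hits = [r.symbol for r in records]
            if hits:
                rows = chromosome_enrichment(hits, all_records, genes)
                chromosome_enrichment_table(rows).to_csv(
                    out / f"chrom_landscape_{tag}_{direction}.tsv", sep="\t", index=False)
            cfs_res = cfs_enrichment(hits, universe, cfs, homologs,
                                     alpha=config.alpha_cfs) if cfs else None
            if cfs_res is not None:
                pd.DataFrame([{"symbol": sym, "cfs_id": cid, "agent": agent}
                              for sym, pairs in cfs_res.members for cid, agent in pairs
                              ]).to_csv(out / f"cfs_{tag}_{direction}.tsv",
                                        sep="\t", index=False)
            summary_rows.append({
                "comparison": tag,
                "up_direction": direction,
                "n_dppgc": len(hits),
                "cfs_percentage": cfs_res.percentage if cfs_res else float("nan"),
                "cfs_mid_p": cfs_res.mid_p if cfs_res else float("nan"),
                "cfs_stars": cfs_res.stars if cfs_res else "",
                "flagged": (not hits) or (cfs_res.flagged if cfs_res else False),
            })
            if gwas is not None and gwas_trait and hits:
                common, gres = gwas_intersect(hits, gwas, gwas_trait, universe,
                                              homologs, alpha=config.alpha_gwas)
                pd.DataFrame({"symbol": common}).to_csv(
                    out / f"gwas_{tag}_{direction}.tsv", sep="\t", index=False)
            if gene_sets and hits:
                gmt_rows = gmt_enrichment(set(hits) & set(universe), universe, gene_sets)
                pd.DataFrame([{
                    "set": r.label, "k": r.k, "n": r.n_draws, "K": r.K, "N": r.N,
                    "percentage": r.percentage, "mid_p": r.mid_p, "stars": r.stars,
                } for r in gmt_rows]).to_csv(
                    out / f"gmt_{tag}_{direction}.tsv", sep="\t", index=False)
    pd.DataFrame(summary_rows).to_csv(out / "enrichment_summary.tsv",
                                      sep="\t", index=False)

    run_manifest = {
        "tool": "difcir",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "l_max": matrix.l_max,
        "inputs": {
            str(manifest_path): _sha256(manifest_path),
            str(genes_path): _sha256(Path(genes_path)),
        },
        "group_pairs": [list(p) for p in group_pairs],
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=1, sort_keys=True)
    return out
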