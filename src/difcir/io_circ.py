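"""Readers and writers for every external table the pipeline touches.

All genomic intervals are held internally in BED convention: 0-based,
half-open ``[start, end)``.  GTF input (1-based, closed) is converted on
read by decrementing the start; nothing else is ever shifted.  Printed
output is BED-convention TSV throughout.

Formats
-------
- eccDNA circle table ``.ecc.tsv``: ``chrom  start  end  split_reads
  [sample_id]``, BED3+1 compatible, ``#`` header lines allowed.
- gene models: BED6 or GTF restricted to ``gene`` features.
- fragile-site table: ``gene_symbol  cfs_id  chrom  agent`` TSV.
- homolog map: two-column symbol TSV (e.g. HomoloGene export).
- GWAS associations: GWAS-Catalog-style TSV (``MAPPED_GENE`` and
  ``DISEASE/TRAIT`` columns honored).
- gene sets: GMT.
- cohort manifest: ``sample_id  path  group  tissue  protocol`` TSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

#: Chemical agents used to induce chromosomal fragile sites.
CFS_AGENTS = ("aphidicolin", "folic acid", "BrdU", "5-azacytidine", "distamycinA")


class TableFormatError(ValueError):
    """A malformed row or an unusable input table."""


@dataclass(frozen=True)
class EccDnaRecord:
    """One detected circle in one sample: an interval plus its split-read support."""

    sample_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    split_reads: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise TableFormatError(
                f"circle start must be < end, got [{self.start}, {self.end})"
            )
        if self.split_reads < 1:
            raise TableFormatError(f"split_reads must be >= 1, got {self.split_reads}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A named genomic interval; its length L_i drives the PpGC scale factor."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise TableFormatError(
                f"gene {self.symbol}: start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise TableFormatError(f"gene {self.symbol}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CfsAnnotation:
    """Membership of one gene in one chromosomal fragile site.

    ``pooled`` is always true: any agent-specific membership implies
    membership in the pooled all-agent category.
    """

    gene_symbol: str
    cfs_id: str
    chrom: str
    agent: str
    pooled: bool = True

    def __post_init__(self) -> None:
        if self.agent not in CFS_AGENTS:
            raise TableFormatError(
                f"unknown fragile-site agent {self.agent!r}; "
                f"expected one of {', '.join(CFS_AGENTS)}"
            )


class HomologMap:
    """Case-insensitive symbol mapping between two species' gene names.

    A source symbol may map to one or more targets.  ``HomologMap.identity()``
    gives the within-species map (every symbol maps to itself).
    """

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self._map: dict[str, list[str]] = {}
        for src, dst in pairs:
            self.add(src, dst)
        self._identity = False

    @classmethod
    def identity(cls) -> "HomologMap":
        m = cls()
        m._identity = True
        return m

    def add(self, source: str, target: str) -> None:
        targets = self._map.setdefault(source.casefold(), [])
        if target not in targets:
            targets.append(target)

    def lookup(self, symbol: str) -> list[str]:
        if self._identity:
            return [symbol]
        return list(self._map.get(symbol.casefold(), []))

    def __contains__(self, symbol: str) -> bool:
        return self._identity or symbol.casefold() in self._map

    def __len__(self) -> int:
        return len(self._map)

    def pairs(self) -> list[tuple[str, str]]:
        return [(s, t) for s, ts in self._map.items() for t in ts]


# ---------------------------------------------------------------------------
# circle tables
# ---------------------------------------------------------------------------

def read_eccdna_table(path: str | Path, sample_id: str | None = None) -> list[EccDnaRecord]:
    """Read one per-sample circle table (TSV, BED3+1 compatible).

    Columns: chrom, start, end, split_reads, optional sample_id.  Rows
    are returned in file order.  When ``sample_id`` is None it is taken
    from the fifth column if present, else from the file stem
    (stripping a trailing ``.ecc``).
    """
    path = Path(path)
    default_sample = sample_id
    if default_sample is None:
        default_sample = re.sub(r"\.ecc$", "", path.stem)
    records: list[EccDnaRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise TableFormatError(f"{path}:{lineno}: expected >= 4 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end, sr = int(fields[1]), int(fields[2]), int(fields[3])
            except ValueError as exc:
                raise TableFormatError(f"{path}:{lineno}: non-integer field ({exc})") from None
            sid = fields[4] if len(fields) >= 5 and fields[4] else default_sample
            try:
                records.append(EccDnaRecord(sid, chrom, start, end, sr))
            except TableFormatError as exc:
                raise TableFormatError(f"{path}:{lineno}: {exc}") from None
    return records


def write_eccdna_table(records: Iterable[EccDnaRecord], path: str | Path,
                       with_sample_id: bool = True) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        cols = ["chrom", "start", "end", "split_reads"] + (["sample_id"] if with_sample_id else [])
        fh.write("#" + "\t".join(cols) + "\n")
        for r in records:
            row = [r.chrom, str(r.start), str(r.end), str(r.split_reads)]
            if with_sample_id:
                row.append(r.sample_id)
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gene_models(path: str | Path, dialect: str = "bed") -> list[GeneModel]:
    """Read gene models from BED6 (0-based half-open) or GTF (1-based closed).

    GTF rows are restricted to ``feature == "gene"`` and their start is
    decremented by one so that every returned interval is half-open.
    """
    path = Path(path)
    if dialect not in ("bed", "gtf"):
        raise ValueError(f"unknown gene-model dialect {dialect!r}; use 'bed' or 'gtf'")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if dialect == "bed":
                if len(f) < 4:
                    raise TableFormatError(f"{path}:{lineno}: BED needs >= 4 columns")
                chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
                strand = f[5] if len(f) >= 6 else "."
                gene = GeneModel(name, name, chrom, start, end, strand)
            else:
                if len(f) < 9:
                    continue
                if f[2] != "gene":
                    continue
                attrs = dict(_GTF_ATTR.findall(f[8]))
                gene_id = attrs.get("gene_id", f"{f[0]}:{f[3]}-{f[4]}")
                symbol = attrs.get("gene_name", gene_id)
                start = int(f[3]) - 1  # 1-based closed -> 0-based half-open
                end = int(f[4])
                gene = GeneModel(gene_id, symbol, f[0], start, end, f[6])
            if gene.length <= 0:
                raise TableFormatError(f"{path}:{lineno}: gene {gene.symbol} has non-positive length")
            if gene.symbol in seen:
                raise TableFormatError(f"{path}:{lineno}: duplicate gene symbol {gene.symbol}")
            seen.add(gene.symbol)
            genes.append(gene)
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as BED6."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.symbol}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

def read_cfs_table(path: str | Path) -> list[CfsAnnotation]:
    """Read a HumCFS-style TSV: gene_symbol, cfs_id, chrom, agent."""
    path = Path(path)
    out: list[CfsAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise TableFormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                out.append(CfsAnnotation(f[0], f[1], f[2], f[3]))
            except TableFormatError as exc:
                raise TableFormatError(f"{path}:{lineno}: {exc}") from None
    return out


def write_cfs_table(rows: Iterable[CfsAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_symbol\tcfs_id\tchrom\tagent\n")
        for r in rows:
            fh.write(f"{r.gene_symbol}\t{r.cfs_id}\t{r.chrom}\t{r.agent}\n")


def pooled_cfs_genes(rows: Iterable[CfsAnnotation]) -> set[str]:
    """The pooled all-agent fragile-site category: union over the five agents."""
    return {r.gene_symbol for r in rows}


def read_homolog_table(path: str | Path) -> HomologMap:
    """Two-column symbol TSV (source, target); extra columns ignored."""
    m = HomologMap()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) >= 2 and f[0] and f[1]:
                m.add(f[0], f[1])
    return m


def read_gwas_table(path: str | Path) -> pd.DataFrame:
    """GWAS-Catalog-style association TSV.

    Only ``MAPPED_GENE`` and ``DISEASE/TRAIT`` are required; all columns
    are carried through untouched.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("MAPPED_GENE", "DISEASE/TRAIT"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column {col!r}")
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: name, description, members."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise TableFormatError(f"{path}:{lineno}: GMT line needs name, description, members")
            sets[f[0]] = {g for g in f[2:] if g}
    return sets


def read_annotation_tables(cfs_path=None, homolog_path=None, gwas_path=None, gmt_path=None):
    """Convenience bundle loader; any path may be None.

    Returns (cfs annotations, homolog map, GWAS dataframe, gene sets);
    absent inputs come back as an empty container (identity map for the
    homologs).
    """
    cfs = read_cfs_table(cfs_path) if cfs_path else []
    homologs = read_homolog_table(homolog_path) if homolog_path else HomologMap.identity()
    gwas = read_gwas_table(gwas_path) if gwas_path else pd.DataFrame(
        columns=["MAPPED_GENE", "DISEASE/TRAIT"])
    gmt = read_gmt(gmt_path) if gmt_path else {}
    return cfs, homologs, gwas, gmt


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> pd.DataFrame:
    """Cohort manifest binding samples to groups: sample_id, path, group[, tissue, protocol]."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     comment=None)
    df.columns = [c.lstrip("#") for c in df.columns]
    for col in ("sample_id", "path", "group"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: manifest missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise TableFormatError(f"{path}: duplicate sample_id {dup!r}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
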