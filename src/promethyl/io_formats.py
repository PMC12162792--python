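"""Domain containers and readers/writers for the external formats.

Everything downstream of this module works on four containers:

* :class:`AnnotationSet` — genes with chromosome, TSS and strand,
* :class:`CpGCountTable` — per-CpG methylated/unmethylated read counts per pool,
* :class:`ExpressionMatrix` — gene x pool integer counts with TMM factors,
* :class:`Design` — pool labels, the pairwise comparisons and the analysis
  constants (promoter span, window sizes, thresholds).

Internal coordinates are 0-based, half-open everywhere.  1-based formats
(GFF3, Bismark coverage) are converted at the boundary and converted back on
write, so round-trips are exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GENOTYPES = ("transgenic", "non_transgenic")
TIMEPOINTS = ("Day0", "Day28", "Day41")

__all__ = [
    "AnnotationSet",
    "CpGCountTable",
    "ExpressionMatrix",
    "PoolLabel",
    "Comparison",
    "Design",
    "read_annotation",
    "write_annotation_bed",
    "read_cpg_counts",
    "write_cpg_counts",
    "read_expression",
    "write_expression",
    "write_table",
    "read_table",
    "default_design",
]


@dataclass(frozen=True)
class PoolLabel:
    """Identity of one sequencing pool (the replication unit)."""

    genotype: str
    timepoint: str
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")

    @property
    def name(self) -> str:
        return f"{self.genotype}_{self.timepoint}_r{self.replicate}"

    @classmethod
    def from_name(cls, name: str) -> "PoolLabel":
        stem, rep = name.rsplit("_r", 1)
        genotype, timepoint = stem.rsplit("_", 1)
        return cls(genotype, timepoint, int(rep))


class AnnotationSet:
    """Genes with chromosome, 0-based TSS position and strand."""

    def __init__(self, records: pd.DataFrame):
        required = ["gene_id", "chrom", "tss", "strand"]
        missing = [c for c in required if c not in records.columns]
        if missing:
            raise ValueError(f"annotation missing columns {missing}")
        df = records[required].reset_index(drop=True).copy()
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        bad = ~df["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(f"strand must be '+' or '-', got {df.loc[bad, 'strand'].iloc[0]!r}")
        if (df["tss"] < 0).any():
            raise ValueError("tss must be >= 0")
        df["tss"] = df["tss"].astype(np.int64)
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AnnotationSet) and self.records.equals(other.records)


@dataclass
class CpGCountTable:
    """Per-CpG methylated/unmethylated read counts for every pool.

    ``sites`` has columns ``chrom``/``pos`` (0-based cytosine position on the
    '+' strand after strand merging) and is sorted with no duplicates;
    ``meth`` and ``unmeth`` are (n_sites, n_pools) integer arrays aligned to
    ``pools``.  Pools lacking a site carry zero coverage there.
    """

    sites: pd.DataFrame
    meth: np.ndarray
    unmeth: np.ndarray
    pools: list[PoolLabel]

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.unmeth = np.asarray(self.unmeth, dtype=np.int64)
        n = len(self.sites)
        if self.meth.shape != (n, len(self.pools)) or self.unmeth.shape != self.meth.shape:
            raise ValueError("count array shapes do not match sites x pools")
        if (self.meth < 0).any() or (self.unmeth < 0).any():
            raise ValueError("negative counts")
        key = self.sites[["chrom", "pos"]]
        if key.duplicated().any():
            raise ValueError("duplicate CpG sites")
        order = key.sort_values(["chrom", "pos"]).index.to_numpy()
        if not np.array_equal(order, np.arange(n)):
            self.sites = self.sites.iloc[order].reset_index(drop=True)
            self.meth = self.meth[order]
            self.unmeth = self.unmeth[order]

    @property
    def coverage(self) -> np.ndarray:
        return self.meth + self.unmeth

    @property
    def fraction(self) -> np.ndarray:
        """Methylation fraction per site per pool; NaN where coverage is 0."""
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.meth / np.maximum(cov, 1), np.nan)

    def pool_index(self, label: PoolLabel) -> int:
        return self.pools.index(label)

    def subset(self, mask: np.ndarray) -> "CpGCountTable":
        return CpGCountTable(self.sites.loc[mask], self.meth[mask], self.unmeth[mask], list(self.pools))


@dataclass
class ExpressionMatrix:
    """Gene x pool integer counts plus TMM normalization factors."""

    counts: pd.DataFrame  # index gene_id, columns pool names
    pools: list[PoolLabel]
    norm_factors: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if list(self.counts.columns) != [p.name for p in self.pools]:
            raise ValueError("count columns do not match pool labels")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative expression counts")
        if self.norm_factors is None:
            self.norm_factors = np.ones(len(self.pools))
        self.norm_factors = np.asarray(self.norm_factors, dtype=float)
        if (self.norm_factors <= 0).any():
            raise ValueError("norm factors must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def lib_sizes(self) -> np.ndarray:
        return self.counts.to_numpy().sum(axis=0).astype(float)

    @property
    def effective_lib_sizes(self) -> np.ndarray:
        return self.lib_sizes * self.norm_factors

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(self.counts.loc[keep], list(self.pools), self.norm_factors.copy())


@dataclass(frozen=True)
class Comparison:
    """One two-group contrast: B vs A (effects reported as B - A)."""

    label: str
    pools_a: tuple[int, ...]
    pools_b: tuple[int, ...]


@dataclass
class Design:
    """Experiment design: pools, contrasts, and the analysis constants."""

    pools: list[PoolLabel]
    comparisons: list[Comparison]
    promoter_upstream: int = 2000
    promoter_downstream: int = 200
    metaplot_upstream: int = 5000
    metaplot_downstream: int = 1000
    window_sizes: tuple[float, ...] = (100.0, 50.0, 25.0, 12.5)
    min_coverage: int = 10
    q_cut_promoter: float = 0.01
    diff_cut: float = 25.0
    p_cut_window: float = 0.05
    fdr_cut_de: float = 0.05

    def comparison(self, label: str) -> Comparison:
        for c in self.comparisons:
            if c.label == label:
                return c
        raise KeyError(label)


def default_design(pools: Sequence[PoolLabel]) -> Design:
    """Build the nine pairwise contrasts of a 2-genotype x 3-time design.

    Three within-genotype time contrasts per genotype plus the three
    between-genotype contrasts at each time point.  Group B is the later
    time point (or the non-transgenic group), so hyper/up means higher in B.
    """
    pools = list(pools)

    def idx(genotype: str, timepoint: str) -> tuple[int, ...]:
        out = tuple(
            i for i, p in enumerate(pools) if p.genotype == genotype and p.timepoint == timepoint
        )
        if not out:
            raise ValueError(f"no pools for {genotype} {timepoint}")
        return out

    comparisons = []
    for g, gshort in (("transgenic", "TG"), ("non_transgenic", "NT")):
        for ta, tb in (("Day0", "Day28"), ("Day0", "Day41"), ("Day28", "Day41")):
            comparisons.append(Comparison(f"{gshort}_{ta}_vs_{tb}", idx(g, ta), idx(g, tb)))
    for t in TIMEPOINTS:
        comparisons.append(
            Comparison(f"TG_vs_NT_{t}", idx("transgenic", t), idx("non_transgenic", t))
        )
    return Design(pools=pools, comparisons=comparisons)


# ---------------------------------------------------------------------------
# annotation I/O


def read_annotation(path: str | Path, format: str = "BED6") -> AnnotationSet:
    """Read gene annotation from BED6 or GFF3.

    TSS convention (0-based): BED6 uses start for '+' genes and end-1 for '-'
    genes; GFF3 'gene' features use the 5' end of the 1-based closed interval.
    Records are deduplicated by gene_id keeping the first occurrence.
    """
    path = Path(path)
    fmt = format.upper()
    rows: list[tuple[str, str, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "BED6":
                    if len(fields) < 6:
                        raise ValueError("expected 6 BED columns")
                    chrom, start, end, name, _score, strand = fields[:6]
                    start_i, end_i = int(start), int(end)
                    if strand == "+":
                        tss = start_i
                    elif strand == "-":
                        tss = end_i - 1
                    else:
                        raise ValueError(f"unknown strand {strand!r}")
                    rows.append((name, chrom, tss, strand))
                elif fmt == "GFF3":
                    if len(fields) < 9:
                        raise ValueError("expected 9 GFF3 columns")
                    chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields[:9]
                    if ftype != "gene":
                        continue
                    if strand not in ("+", "-"):
                        raise ValueError(f"unknown strand {strand!r}")
                    gene_id = _gff3_attr(attrs, "ID")
                    start_i, end_i = int(start), int(end)
                    tss = start_i - 1 if strand == "+" else end_i - 1
                    rows.append((gene_id, chrom, tss, strand))
                else:
                    raise ValueError(f"unknown annotation format {format!r}")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from exc
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    df = df.drop_duplicates("gene_id", keep="first")
    if df.empty:
        raise ValueError(f"{path}: no gene records")
    return AnnotationSet(df)


def _gff3_attr(attrs: str, key: str) -> str:
    for part in attrs.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() == key:
                return v.strip()
    raise ValueError(f"GFF3 attribute {key!r} not found")


def write_annotation_bed(annotation: AnnotationSet, path: str | Path) -> None:
    """Write BED6 with a nominal 1 bp feature at the TSS-anchored convention."""
    with open(path, "w") as fh:
        for rec in annotation.records.itertuples():
            if rec.strand == "+":
                start, end = rec.tss, rec.tss + 1
            else:
                start, end = rec.tss, rec.tss + 1  # end-1 == tss under the '-' rule
            fh.write(f"{rec.chrom}\t{start}\t{end}\t{rec.gene_id}\t0\t{rec.strand}\n")


# ---------------------------------------------------------------------------
# CpG count I/O

_BISMARK_COLS = ["chrom", "start", "end", "pct_meth", "count_meth", "count_unmeth"]


def read_cpg_counts(
    paths: Sequence[str | Path],
    pools: Sequence[PoolLabel],
    format: str = "bismark_cov",
) -> CpGCountTable:
    """Read one coverage file per pool and union the sites.

    ``bismark_cov`` columns: chrom, start(1-based), end, %methylation,
    methylated count, unmethylated count.  ``tsv`` columns: chrom,
    pos(0-based), meth, unmeth.  Sites absent from a pool get zero coverage
    in that pool; if a %methylation field disagrees with its counts by more
    than 0.5 percentage points a warning is emitted and the counts win.
    """
    if len(paths) != len(pools):
        raise ValueError("one path per pool required")
    frames = []
    for path in paths:
        if format == "bismark_cov":
            df = pd.read_csv(path, sep="\t", header=None, names=_BISMARK_COLS)
            if df.empty:
                df = pd.DataFrame(columns=["chrom", "pos", "meth", "unmeth"])
            else:
                if (df[["count_meth", "count_unmeth"]].to_numpy() < 0).any():
                    raise ValueError(f"{path}: negative counts")
                cov = df["count_meth"] + df["count_unmeth"]
                with np.errstate(invalid="ignore"):
                    implied = 100.0 * df["count_meth"] / cov.where(cov > 0, 1)
                off = (df["pct_meth"] - implied).abs() > 0.5
                if off.any():
                    warnings.warn(
                        f"{path}: %methylation disagrees with counts at "
                        f"{int(off.sum())} site(s); counts win",
                        stacklevel=2,
                    )
                df = pd.DataFrame(
                    {
                        "chrom": df["chrom"].astype(str),
                        "pos": df["start"].astype(np.int64) - 1,
                        "meth": df["count_meth"].astype(np.int64),
                        "unmeth": df["count_unmeth"].astype(np.int64),
                    }
                )
        elif format == "tsv":
            df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
            df = df[["chrom", "pos", "meth", "unmeth"]]
        else:
            raise ValueError(f"unknown CpG count format {format!r}")
        if (df[["meth", "unmeth"]].to_numpy() < 0).any():
            raise ValueError(f"{path}: negative counts")
        frames.append(df.set_index(["chrom", "pos"]))
    union = frames[0].index
    for f in frames[1:]:
        union = union.union(f.index)
    union = union.sortlevel()[0] if union.nlevels > 1 else union
    n = len(union)
    meth = np.zeros((n, len(pools)), dtype=np.int64)
    unmeth = np.zeros((n, len(pools)), dtype=np.int64)
    for j, f in enumerate(frames):
        aligned = f.reindex(union)
        meth[:, j] = aligned["meth"].fillna(0).to_numpy(dtype=np.int64)
        unmeth[:, j] = aligned["unmeth"].fillna(0).to_numpy(dtype=np.int64)
    sites = pd.DataFrame(
        {"chrom": union.get_level_values(0), "pos": union.get_level_values(1).astype(np.int64)}
    )
    return CpGCountTable(sites, meth, unmeth, list(pools))


def write_cpg_counts(table: CpGCountTable, dir_path: str | Path) -> list[Path]:
    """Write one Bismark-coverage-style file per pool; returns the paths."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    cov = table.coverage
    out = []
    for j, pool in enumerate(table.pools):
        path = dir_path / f"{pool.name}.cov"
        has = cov[:, j] > 0
        sub = table.sites.loc[has]
        m = table.meth[has, j]
        u = table.unmeth[has, j]
        pct = np.where(m + u > 0, 100.0 * m / np.maximum(m + u, 1), 0.0)
        df = pd.DataFrame(
            {
                "chrom": sub["chrom"].to_numpy(),
                "start": sub["pos"].to_numpy() + 1,
                "end": sub["pos"].to_numpy() + 1,
                "pct": np.round(pct, 6),
                "meth": m,
                "unmeth": u,
            }
        )
        df.to_csv(path, sep="\t", header=False, index=False)
        out.append(path)
    return out


# ---------------------------------------------------------------------------
# expression I/O and generic result tables


def read_expression(path: str | Path, pools: Sequence[PoolLabel] | None = None) -> ExpressionMatrix:
    """Read a gene x pool TSV of integer counts (header = pool names)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: no genes")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.asarray(arr, dtype=float) == np.asarray(arr, dtype=float).astype(np.int64)):
            raise ValueError(f"{path}: non-integer expression cell")
        df = df.astype(np.int64)
    if pools is None:
        pools = [PoolLabel.from_name(c) for c in df.columns]
    df.index.name = "gene_id"
    return ExpressionMatrix(df.astype(np.int64), list(pools))


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with floats at 6 decimals (round-trip safe)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
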