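"""Strand-aware promoter definition, multi-resolution window tiling,
CpG-to-window aggregation and per-window differential methylation.

Promoter-local coordinates are signed bp from the TSS (upstream negative,
half-open) and the promoter is the fixed span [-2000, +200).  Window sizes
100/50/25/12.5 bp tile that span into exactly 22/44/88/176 windows; the
12.5 bp case is handled with half-bp integer arithmetic so no fractional
genomic coordinate ever materializes.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
import pandas as pd

from .io_formats import AnnotationSet, Comparison, CpGCountTable
from .methylation import call_dm, dm_test, summarize_dm_calls

__all__ = [
    "tss_relative_position",
    "define_promoter",
    "tile_windows",
    "promoter_cpg_assignment",
    "aggregate_window_counts",
    "window_dm",
    "positional_dmr_profile",
]

PROMOTER_SPAN = (-2000, 200)
WINDOW_SIZES = (100.0, 50.0, 25.0, 12.5)


def tss_relative_position(pos, tss, strand):
    """Signed bp from the TSS: negative upstream, strand-aware."""
    pos = np.asarray(pos)
    rel = np.where(np.asarray(strand) == "+", pos - tss, tss - pos)
    return rel if rel.ndim else int(rel)


def define_promoter(tss: int, strand: str, upstream: int = 2000, downstream: int = 200,
                    chrom_length: int | None = None) -> tuple[int, int]:
    """Genomic half-open interval covering promoter-relative [-up, +down).

    '+' genes: [tss-up, tss+down); '-' genes: [tss-down+1, tss+up+1).
    Clipped at the chromosome boundary (with a warning) when needed.
    """
    if strand == "+":
        start, end = tss - upstream, tss + downstream
    else:
        start, end = tss - downstream + 1, tss + upstream + 1
    if start < 0:
        warnings.warn(f"promoter at tss={tss} clipped at chromosome start", stacklevel=2)
        start = 0
    if chrom_length is not None and end > chrom_length:
        warnings.warn(f"promoter at tss={tss} clipped at chromosome end", stacklevel=2)
        end = chrom_length
    return start, end


def tile_windows(gene_id: str, size: float,
                 span: tuple[int, int] = PROMOTER_SPAN) -> pd.DataFrame:
    """Tile the promoter span into fixed-size windows (exact partition).

    Returns a frame with gene_id, window_index and the half-open relative
    bounds; errors if ``size`` does not evenly divide the span.
    """
    lo, hi = span
    size_f = Fraction(size).limit_denominator(1000)
    n = Fraction(hi - lo) / size_f
    if n.denominator != 1:
        raise ValueError(f"window size {size} does not divide the {hi - lo} bp span")
    n = int(n)
    rel_start = [float(lo + k * size_f) for k in range(n)]
    rel_end = [float(lo + (k + 1) * size_f) for k in range(n)]
    return pd.DataFrame(
        {
            "gene_id": gene_id,
            "window_index": np.arange(n),
            "rel_start": rel_start,
            "rel_end": rel_end,
            "size": float(size),
        }
    )


def window_index_of(rel, size: float, span: tuple[int, int] = PROMOTER_SPAN):
    """Window index for integer relative positions; exact for half-bp sizes."""
    lo, hi = span
    rel = np.asarray(rel)
    half = int(round(2 * size))
    if not np.isclose(half / 2, size):
        raise ValueError(f"size {size} is not a multiple of 0.5 bp")
    return (2 * (rel - lo)) // half


def promoter_cpg_assignment(
    table: CpGCountTable, annotation: AnnotationSet,
    span: tuple[int, int] = PROMOTER_SPAN,
) -> pd.DataFrame:
    """Map CpG sites into each gene's promoter span (per-gene duplication).

    A CpG inside two overlapping promoters appears once per gene.  Returns
    columns site_idx, gene_id, rel.
    """
    out_site, out_gene, out_rel = [], [], []
    pos_by_chrom = {
        c: (sub.index.to_numpy(), sub["pos"].to_numpy())
        for c, sub in table.sites.groupby("chrom", sort=False)
    }
    lo, hi = span
    for rec in annotation.records.itertuples():
        if rec.chrom not in pos_by_chrom:
            continue
        idx, pos = pos_by_chrom[rec.chrom]
        if rec.strand == "+":
            g_lo, g_hi = rec.tss + lo, rec.tss + hi
        else:
            g_lo, g_hi = rec.tss - hi + 1, rec.tss - lo + 1
        a, b = np.searchsorted(pos, [g_lo, g_hi])
        if a == b:
            continue
        sub_pos = pos[a:b]
        rel = tss_relative_position(sub_pos, rec.tss, rec.strand)
        inside = (rel >= lo) & (rel < hi)
        out_site.append(idx[a:b][inside])
        out_gene.append(np.full(int(inside.sum()), rec.gene_id, dtype=object))
        out_rel.append(rel[inside])
    if not out_site:
        return pd.DataFrame({"site_idx": pd.Series(dtype=int),
                             "gene_id": pd.Series(dtype=object),
                             "rel": pd.Series(dtype=int)})
    return pd.DataFrame(
        {
            "site_idx": np.concatenate(out_site),
            "gene_id": np.concatenate(out_gene),
            "rel": np.concatenate(out_rel),
        }
    )


def aggregate_window_counts(
    table: CpGCountTable,
    annotation: AnnotationSet,
    size: float | str,
    span: tuple[int, int] = PROMOTER_SPAN,
) -> pd.DataFrame:
    """Sum CpG counts into promoter windows (or the whole promoter).

    ``size`` is one of the window sizes or ``"promoter"`` for a single unit
    per gene.  Only windows containing at least one CpG appear (empty
    windows are excluded from testing).  Returns one row per (gene, window)
    with per-pool meth/unmeth columns and the relative bounds.
    """
    assign = promoter_cpg_assignment(table, annotation, span)
    if assign.empty:
        return pd.DataFrame()
    lo, hi = span
    if size == "promoter":
        widx = np.zeros(len(assign), dtype=np.int64)
        size_f = float(hi - lo)
        rel_of = lambda k: (float(lo), float(hi))
    else:
        size_f = float(size)
        widx = window_index_of(assign["rel"].to_numpy(), size_f, span).astype(np.int64)
        rel_of = lambda k: (lo + k * size_f, lo + (k + 1) * size_f)

    key = pd.DataFrame({"gene_id": assign["gene_id"], "window_index": widx})
    groups, uniq = pd.factorize(pd.MultiIndex.from_frame(key), sort=True)
    n_units = len(uniq)
    site_idx = assign["site_idx"].to_numpy()
    n_pools = len(table.pools)
    meth = np.zeros((n_units, n_pools), dtype=np.int64)
    unmeth = np.zeros((n_units, n_pools), dtype=np.int64)
    for j in range(n_pools):
        meth[:, j] = np.bincount(groups, weights=table.meth[site_idx, j], minlength=n_units)
        unmeth[:, j] = np.bincount(groups, weights=table.unmeth[site_idx, j], minlength=n_units)
    n_cpg = np.bincount(groups, minlength=n_units)

    gene_ids = [u[0] for u in uniq]
    w_idx = np.array([u[1] for u in uniq])
    rel_bounds = [rel_of(k) for k in w_idx]
    out = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "window_index": w_idx,
            "rel_start": [b[0] for b in rel_bounds],
            "rel_end": [b[1] for b in rel_bounds],
            "n_cpg": n_cpg,
        }
    )
    for j, pool in enumerate(table.pools):
        out[f"meth_{pool.name}"] = meth[:, j]
        out[f"unmeth_{pool.name}"] = unmeth[:, j]
    return out


def window_dm(
    aggregated: pd.DataFrame,
    comparison: Comparison,
    pools,
    mode: str = "window",
    q_cut: float = 0.01,
    diff_cut: float = 25.0,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Differential methylation per aggregated window for one comparison.

    ``promoter`` mode applies the q < 0.01 and 25-point dual threshold;
    ``window`` mode the plain p < 0.05 rule.
    """
    if aggregated.empty:
        return aggregated.copy()
    names = [p.name for p in pools]
    meth = np.stack([aggregated[f"meth_{n}"].to_numpy() for n in names], axis=1)
    unmeth = np.stack([aggregated[f"unmeth_{n}"].to_numpy() for n in names], axis=1)
    ia, ib = list(comparison.pools_a), list(comparison.pools_b)
    diff, statistic, p, ok = dm_test(meth[:, ia], unmeth[:, ia], meth[:, ib], unmeth[:, ib])
    cov_a = (meth + unmeth)[:, ia].sum(axis=1)
    cov_b = (meth + unmeth)[:, ib].sum(axis=1)
    res = pd.DataFrame(
        {
            "gene_id": aggregated["gene_id"],
            "window_index": aggregated["window_index"],
            "rel_start": aggregated["rel_start"],
            "rel_end": aggregated["rel_end"],
            "n_cpg": aggregated["n_cpg"],
            "meth_percent_A": 100.0 * meth[:, ia].sum(axis=1) / np.maximum(cov_a, 1),
            "meth_percent_B": 100.0 * meth[:, ib].sum(axis=1) / np.maximum(cov_b, 1),
            "meth_diff": diff,
            "statistic": statistic,
            "p_value": p,
        }
    )
    res = res[ok].reset_index(drop=True)
    return call_dm(res, q_cut=q_cut, diff_cut=diff_cut, mode=mode, p_cut=p_cut)


def positional_dmr_profile(window_dm_results: pd.DataFrame) -> pd.DataFrame:
    """Count significant windows per relative start position.

    Input is a window-mode DM table with calls; output has one row per
    rel_start with hypo/hyper/total counts (zero-count positions omitted).
    """
    sig = window_dm_results[window_dm_results["call"] != "ns"]
    if sig.empty:
        return pd.DataFrame({"rel_start": pd.Series(dtype=float),
                             "hypo": pd.Series(dtype=int),
                             "hyper": pd.Series(dtype=int),
                             "total": pd.Series(dtype=int)})
    tab = sig.groupby("rel_start")["call"].value_counts().unstack(fill_value=0)
    for col in ("hypo", "hyper"):
        if col not in tab:
            tab[col] = 0
    out = tab.reset_index()[["rel_start", "hypo", "hyper"]]
    out["total"] = out["hypo"] + out["hyper"]
    return out


def summarize_window_dm(called: pd.DataFrame) -> dict:
    return summarize_dm_calls(called)
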