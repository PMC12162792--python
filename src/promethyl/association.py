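"""Methylation-transcription association analyses and derived summary ratios.

Covers the headline analyses of the workflow: the TSS metaplot (aggregate
methylation vs distance from the TSS), the static association of promoter
methylation with log2-CPM, window-wise regressions of expression log-fold
change on methylation change, DEG-DMR overlap accounting, and the derived
percentages/ratios recomputable from published-style integer count tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnnotationSet, CpGCountTable
from .methylation import adjust_pvalues
from .windows import tss_relative_position

__all__ = [
    "metaplot",
    "static_association",
    "delta_association",
    "overlap_deg_dmr",
    "positional_overlap_profile",
    "derived_ratios",
]

SIGNIFICANCE_TIERS = (0.05, 0.01, 0.001)


def _closest_gene_rel(table: CpGCountTable, annotation: AnnotationSet,
                      span: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Relative position of each CpG to its closest gene's TSS.

    Closest by absolute genomic distance to the TSS, ties broken by lower
    gene_id; returns (mask of sites within the span, rel positions).
    """
    lo, hi = span
    rel_all = np.full(len(table.sites), np.nan)
    for chrom, sub in table.sites.groupby("chrom", sort=False):
        genes = annotation.records[annotation.records["chrom"] == chrom]
        if genes.empty:
            continue
        g = genes.sort_values(["tss", "gene_id"], kind="stable")
        tss = g["tss"].to_numpy()
        strand = g["strand"].to_numpy()
        pos = sub["pos"].to_numpy()
        j = np.searchsorted(tss, pos)
        left = np.clip(j - 1, 0, len(tss) - 1)
        right = np.clip(j, 0, len(tss) - 1)
        d_left = np.abs(pos - tss[left])
        d_right = np.abs(pos - tss[right])
        # ties at equal distance: lower gene_id, i.e. earlier sorted row
        pick = np.where(d_left <= d_right, left, right)
        rel = np.where(
            strand[pick] == "+", pos - tss[pick], tss[pick] - pos
        )
        rel_all[sub.index.to_numpy()] = rel
    mask = (rel_all >= lo) & (rel_all <= hi)
    return mask, rel_all


def metaplot(
    table: CpGCountTable,
    annotation: AnnotationSet,
    pool_indices: list[int] | None = None,
    span: tuple[int, int] = (-5000, 1000),
    bin_size: int = 25,
    smooth: bool = False,
    smooth_window: int = 5,
) -> pd.DataFrame:
    """Coverage-weighted mean methylation percent vs TSS distance.

    Each CpG is assigned to its closest gene's TSS; sites within ``span``
    are binned at ``bin_size`` bp and the per-bin mean is coverage-weighted
    over the selected pools.  Empty bins are omitted.  A centered moving
    average over ``smooth_window`` bins stands in for a GAM-style smoother.
    """
    if pool_indices is None:
        pool_indices = list(range(len(table.pools)))
    mask, rel = _closest_gene_rel(table, annotation, span)
    rel = rel[mask]
    meth = table.meth[mask][:, pool_indices].sum(axis=1)
    cov = table.coverage[mask][:, pool_indices].sum(axis=1)
    has = cov > 0
    rel, meth, cov = rel[has], meth[has], cov[has]
    lo, hi = span
    bin_idx = ((rel - lo) // bin_size).astype(int)
    n_bins = int(np.ceil((hi - lo) / bin_size))
    bin_idx = np.clip(bin_idx, 0, n_bins - 1)
    sum_m = np.bincount(bin_idx, weights=meth, minlength=n_bins)
    sum_c = np.bincount(bin_idx, weights=cov, minlength=n_bins)
    centers = lo + (np.arange(n_bins) + 0.5) * bin_size
    keep = sum_c > 0
    curve = pd.DataFrame(
        {
            "bin_center": centers[keep],
            "mean_meth_pct": 100.0 * sum_m[keep] / sum_c[keep],
            "n_reads": sum_c[keep].astype(int),
        }
    )
    if smooth:
        curve["mean_meth_pct_smooth"] = (
            curve["mean_meth_pct"].rolling(smooth_window, center=True, min_periods=1).mean()
        )
    return curve


def static_association(promoter_meth_pct: pd.Series, log2_cpm: pd.Series,
                       n_bins: int = 40) -> dict:
    """OLS of log2-CPM on promoter methylation percent across genes.

    Only genes present in both inputs are used.  Returns slope, intercept,
    the two-sided t-test p for the slope, n, and a binned 2-D density table
    for plotting.
    """
    joined = pd.concat(
        {"meth": promoter_meth_pct, "expr": log2_cpm}, axis=1, join="inner"
    ).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"need at least 3 genes with both values, got {n}")
    fit = stats.linregress(joined["meth"], joined["expr"])
    hist, xedges, yedges = np.histogram2d(joined["meth"], joined["expr"], bins=n_bins)
    xi, yi = np.nonzero(hist)
    density = pd.DataFrame(
        {
            "meth_bin_center": (xedges[xi] + xedges[xi + 1]) / 2,
            "expr_bin_center": (yedges[yi] + yedges[yi + 1]) / 2,
            "n_genes": hist[xi, yi].astype(int),
        }
    )
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "p_value": float(fit.pvalue),
        "r_value": float(fit.rvalue),
        "n": n,
        "density": density,
    }


def delta_association(
    window_meth_diff: pd.DataFrame,
    de_results: pd.DataFrame,
    min_genes: int = 10,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-window OLS of expression log2 fold change on methylation change.

    ``window_meth_diff`` needs gene_id, rel_start and meth_diff (percentage
    points, B - A) per window; ``de_results`` supplies gene_id and log2_fc.
    Windows with fewer than ``min_genes`` genes carrying both values, or a
    constant regressor, are skipped.  Direction is the slope sign and the
    significance tier is the smallest of 0.05/0.01/0.001 the p-value clears.
    ``adjust`` optionally BH-corrects across windows (off by default).
    """
    lfc = de_results.set_index("gene_id")["log2_fc"]
    rows = []
    for rel_start, sub in window_meth_diff.groupby("rel_start"):
        merged = sub.set_index("gene_id")[["meth_diff"]].join(lfc, how="inner").dropna()
        if len(merged) < min_genes:
            continue
        x = merged["meth_diff"].to_numpy()
        if np.allclose(x, x[0]):
            continue
        fit = stats.linregress(x, merged["log2_fc"].to_numpy())
        rows.append(
            {
                "rel_start": rel_start,
                "slope": fit.slope,
                "p_value": fit.pvalue,
                "n_genes": len(merged),
            }
        )
    out = pd.DataFrame(rows, columns=["rel_start", "slope", "p_value", "n_genes"])
    if out.empty:
        out["direction"] = pd.Series(dtype=object)
        out["tier"] = pd.Series(dtype=object)
        return out
    p = adjust_pvalues(out["p_value"].to_numpy()) if adjust else out["p_value"].to_numpy()
    out["direction"] = np.where(out["slope"] < 0, "negative", "positive")
    tier = np.full(len(out), "ns", dtype=object)
    for cut in SIGNIFICANCE_TIERS:  # descending cutoffs, tightest wins
        tier[p < cut] = f"p<{cut}"
    out["tier"] = tier
    return out


def overlap_deg_dmr(de_results: pd.DataFrame, dm_results: pd.DataFrame) -> dict:
    """Genes that are both differentially expressed and methylated.

    A gene overlaps iff its DE call is up/down and it has at least one
    significant DM unit in the given mode.  Returns the overlapping gene
    set, the count, and the per-window significant-unit count among
    overlapping genes (a gene with several significant windows contributes
    each of them to the positional profile).
    """
    deg = set(de_results.loc[de_results["call"] != "ns", "gene_id"])
    sig_dm = dm_results[dm_results["call"] != "ns"]
    dmr_genes = set(sig_dm["gene_id"])
    overlap = sorted(deg & dmr_genes)
    per_window = sig_dm[sig_dm["gene_id"].isin(overlap)]
    return {
        "overlap_genes": overlap,
        "overlap_count": len(overlap),
        "deg_count": len(deg),
        "dmr_gene_count": len(dmr_genes),
        "dmr_unit_count": int(len(sig_dm)),
        "overlap_units": per_window.reset_index(drop=True),
    }


def positional_overlap_profile(overlap: dict) -> pd.DataFrame:
    """Per-rel_start counts of significant windows belonging to overlapping genes."""
    units = overlap["overlap_units"]
    if units.empty:
        return pd.DataFrame({"rel_start": pd.Series(dtype=float),
                             "count": pd.Series(dtype=int)})
    out = units.groupby("rel_start").size().reset_index(name="count")
    return out


# ---------------------------------------------------------------------------
# derived arithmetic over published-style integer count tables


def derived_ratios(
    de_table: pd.DataFrame,
    dm_cpg_table: pd.DataFrame,
    dm_promoter_table: pd.DataFrame,
    overlap_table: pd.DataFrame,
    total_transcripts: int,
    window_overlaps: int | None = None,
    window_dmrs: int | None = None,
) -> pd.DataFrame:
    """Recompute every derived percentage/ratio from integer count tables.

    Inputs use the published table layouts (one row per comparison):
    ``de_table`` down_count/up_count, ``dm_cpg_table`` hypo/hyper,
    ``dm_promoter_table`` hypo/hyper, ``overlap_table`` overlap_count;
    ``window_overlaps``/``window_dmrs`` optionally give the genome-wide
    fixed-size-window overlap and DMR totals.  Rounding follows the printed
    conventions: transcript percentages to 2 decimals, DEG/DMR overlap
    percentages to 1 decimal, up/hypo shares to the nearest integer, and
    fold ratios to 1 decimal.  Zero denominators yield NA.
    """
    if total_transcripts <= 0:
        raise ValueError("total_transcripts must be positive")

    def safe(num, den, digits):
        if den == 0:
            return np.nan
        return round(num / den, digits)

    rows = []
    for _, r in de_table.iterrows():
        comp = r["comparison"]
        down, up = int(r["down_count"]), int(r["up_count"])
        deg_total = down + up
        row = {
            "comparison": comp,
            "down_pct_of_transcripts": safe(100.0 * down, total_transcripts, 2),
            "up_pct_of_transcripts": safe(100.0 * up, total_transcripts, 2),
            "combined_pct_of_transcripts": safe(100.0 * deg_total, total_transcripts, 2),
            "up_pct_of_degs": safe(100.0 * up, deg_total, 0),
            "down_pct_of_degs": safe(100.0 * down, deg_total, 0),
        }
        cpg = dm_cpg_table[dm_cpg_table["comparison"] == comp]
        if len(cpg):
            hypo, hyper = int(cpg["hypo"].iloc[0]), int(cpg["hyper"].iloc[0])
            row["cpg_total"] = hypo + hyper
            row["hyper_over_hypo"] = safe(hyper, hypo, 1)
            row["hypo_over_hyper"] = safe(hypo, hyper, 1)
            row["hypo_pct_of_cpgs"] = safe(100.0 * hypo, hypo + hyper, 0)
            row["hyper_pct_of_cpgs"] = safe(100.0 * hyper, hypo + hyper, 0)
        prom = dm_promoter_table[dm_promoter_table["comparison"] == comp]
        ov = overlap_table[overlap_table["comparison"] == comp]
        if len(prom) and len(ov):
            p_hypo, p_hyper = int(prom["hypo"].iloc[0]), int(prom["hyper"].iloc[0])
            n_ov = int(ov["overlap_count"].iloc[0])
            row["promoter_dmr_total"] = p_hypo + p_hyper
            row["overlap_pct_of_degs"] = safe(100.0 * n_ov, deg_total, 1)
            row["overlap_pct_of_dmrs"] = safe(100.0 * n_ov, p_hypo + p_hyper, 0)
        rows.append(row)
    out = pd.DataFrame(rows)
    if window_overlaps is not None and window_dmrs is not None:
        out.attrs["window_overlap_pct_of_dmrs"] = safe(100.0 * window_overlaps, window_dmrs, 1)
    return out
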