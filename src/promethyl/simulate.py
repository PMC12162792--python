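"""Joint WGBS + RNA-seq simulator for a 2-genotype x 3-time-point design.

The generator emulates the statistical structure the downstream analysis
assumes: CpG methylation whose mean follows a TSS-anchored profile (high
plateau upstream, trough just downstream of the TSS), beta-binomial
overdispersion across pooled biological replicates, negative-binomial
expression counts, and a configurable subset of genes whose promoter
methylation is inversely coupled to expression.  Truth tables record exactly
which genes were perturbed so recovery can be scored without leakage.

Randomness: every stage draws from ``numpy.random.default_rng([seed, k])``
with a fixed stage constant ``k``, so each stage is independently
reproducible and the whole dataset is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GENOTYPES,
    TIMEPOINTS,
    AnnotationSet,
    CpGCountTable,
    ExpressionMatrix,
    PoolLabel,
)

__all__ = ["SimConfig", "MethylationTruth", "ExpressionTruth", "mean_meth_profile",
           "simulate_annotation", "simulate_methylation", "simulate_expression",
           "simulate_dataset", "default_pools"]

_STAGE_ANNOT = 11
_STAGE_METH = 22
_STAGE_EXPR = 33


@dataclass
class SimConfig:
    """All knobs of the generator; the defaults are the study conditions.

    ``coupling_slope`` is the change in log2 expression per percentage point
    of promoter methylation (negative = repressive), ``dm_effect`` a
    treatment shift in percentage points applied to a ``dm_region_width`` bp
    stretch of the promoter, ``biol_dispersion_meth`` the beta-binomial
    correlation rho across pools.
    """

    seed: int = 0
    n_genes: int = 2000
    intergenic_spacing: int = 15000
    cpg_spacing_mean: float = 30.0
    background_spacing_mean: float = 500.0
    mean_coverage: float = 15.0
    plateau_meth: float = 0.80
    trough_meth: float = 0.15
    trough_offset: float = 200.0
    profile_width: float = 400.0
    gene_jitter_sd: float = 0.15  # between-gene spread of promoter methylation level
    biol_dispersion_meth: float = 0.02
    expr_dispersion: float = 0.1
    coupling_fraction: float = 0.10
    coupling_slope: float = -0.04
    dm_fraction: float = 0.05
    dm_effect: float = 30.0
    dm_region_width: float = 100.0
    dm_region_start: float | None = None  # fix all DM regions at this rel start
    de_fraction: float = 0.05
    de_log2fc: float = 2.0
    pools_per_cell: int = 2
    baseline_log2_mean: float = 7.5
    baseline_log2_sd: float = 2.0
    depth_jitter: float = 0.2
    pool_noise_inflation: float = 0.0  # optional extra per-pool noise, default off
    promoter_upstream: int = 2000
    promoter_downstream: int = 200
    metaplot_upstream: int = 5000
    metaplot_downstream: int = 1000

    def validate(self) -> None:
        if not (0 <= self.trough_meth <= self.plateau_meth <= 1):
            raise ValueError("need 0 <= trough_meth <= plateau_meth <= 1")
        for name in ("coupling_fraction", "dm_fraction", "de_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if not 0 <= self.biol_dispersion_meth < 1:
            raise ValueError("biol_dispersion_meth must be in [0,1)")
        if self.expr_dispersion < 0:
            raise ValueError("expr_dispersion must be >= 0")
        span = self.metaplot_upstream + self.metaplot_downstream
        if self.n_genes > 0 and self.intergenic_spacing < span:
            raise ValueError(
                f"intergenic_spacing {self.intergenic_spacing} smaller than the "
                f"metaplot span {span}; gene spans would overlap"
            )


@dataclass
class MethylationTruth:
    """Ground truth from the methylation stage.

    ``promoter_meth`` is the population (noise-free) promoter-mean
    methylation percent per gene per pool; ``dm_genes`` lists the perturbed
    genes with the promoter-local region and shift sign.
    """

    promoter_meth: pd.DataFrame  # genes x pool names, percent
    dm_genes: pd.DataFrame  # gene_id, rel_start, rel_end, sign


@dataclass
class ExpressionTruth:
    coupled_genes: list[str]
    de_genes: pd.DataFrame  # gene_id, sign (log2fc sign at later time points)


def default_pools(pools_per_cell: int = 2) -> list[PoolLabel]:
    return [
        PoolLabel(g, t, r)
        for g in GENOTYPES
        for t in TIMEPOINTS
        for r in range(1, pools_per_cell + 1)
    ]


def mean_meth_profile(rel_pos, cfg: SimConfig):
    """Mean methylation fraction as a function of signed bp from the TSS.

    Approaches ``plateau_meth`` far upstream, decreases monotonically to a
    minimum of ``trough_meth`` exactly at ``trough_offset`` bp downstream of
    the TSS, and recovers partially into the gene body (to 70% of the
    plateau-trough range above the trough).
    """
    rel = np.asarray(rel_pos, dtype=float)
    amp = cfg.plateau_meth - cfg.trough_meth
    body = cfg.trough_meth + 0.7 * amp
    x = (cfg.trough_offset - rel) / cfg.profile_width  # >0 upstream of trough
    up = cfg.trough_meth + amp * (1.0 - np.exp(-np.square(x)))
    down = cfg.trough_meth + (body - cfg.trough_meth) * (1.0 - np.exp(-np.square(x)))
    out = np.where(rel <= cfg.trough_offset, up, down)
    return out if out.ndim else float(out)


def simulate_annotation(cfg: SimConfig) -> AnnotationSet | None:
    """Place ``n_genes`` genes on one synthetic chromosome.

    TSSs sit every ``intergenic_spacing`` bp (offset so the first metaplot
    span fits on the chromosome) with random strand, so the -5000..+1000
    metaplot spans of adjacent genes never overlap.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, _STAGE_ANNOT])
    n = cfg.n_genes
    offset = cfg.metaplot_upstream + cfg.metaplot_downstream
    tss = offset + np.arange(n, dtype=np.int64) * cfg.intergenic_spacing
    strand = rng.choice(["+", "-"], size=n)
    width = int(np.ceil(np.log10(max(n, 1) + 1)))
    df = pd.DataFrame(
        {
            "gene_id": [f"gene{str(i).zfill(width)}" for i in range(n)],
            "chrom": "chrSim",
            "tss": tss,
            "strand": strand,
        }
    )
    return AnnotationSet(df) if n > 0 else AnnotationSet(
        pd.DataFrame({"gene_id": pd.Series(dtype=str), "chrom": pd.Series(dtype=str),
                      "tss": pd.Series(dtype=np.int64), "strand": pd.Series(dtype=str)})
    )


def _beta_binomial_fraction(rng, mu, rho):
    """Draw pool-level methylation fractions: Beta with mean mu, correlation rho."""
    if rho <= 0:
        return mu
    a = mu * (1.0 - rho) / rho
    b = (1.0 - mu) * (1.0 - rho) / rho
    return rng.beta(np.maximum(a, 1e-8), np.maximum(b, 1e-8))


def simulate_methylation(
    annotation: AnnotationSet, cfg: SimConfig
) -> tuple[CpGCountTable, MethylationTruth]:
    """Simulate per-CpG counts for every pool of the full design.

    CpGs are laid down with exponential spacing across each gene's metaplot
    span plus a sparse intergenic background.  Per site and pool the read
    coverage is Poisson(``mean_coverage``), the methylation fraction is
    beta-binomial around the TSS-distance profile (with a per-gene baseline
    jitter), and ``dm_fraction`` of genes get a +/- ``dm_effect`` point shift
    over one promoter-local region in all Day28/Day41 pools.
    """
    cfg.validate()
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    rng = np.random.default_rng([cfg.seed, _STAGE_METH])
    pools = default_pools(cfg.pools_per_cell)
    n_pools = len(pools)
    later = np.array([p.timepoint != "Day0" for p in pools])

    recs = annotation.records
    genes = recs["gene_id"].to_numpy()
    n_genes = len(genes)

    # CpG positions: exponential gaps within each gene span, background between
    span_lo, span_hi = -cfg.metaplot_upstream, cfg.metaplot_downstream
    span_len = span_hi - span_lo
    pos_list, rel_list, gene_idx_list = [], [], []
    for gi, rec in enumerate(recs.itertuples()):
        n_draw = int(span_len / cfg.cpg_spacing_mean * 1.5) + 8
        gaps = rng.exponential(cfg.cpg_spacing_mean, size=n_draw)
        rel = span_lo + np.cumsum(gaps)
        rel = np.unique(np.round(rel[rel < span_hi]).astype(np.int64))
        rel = rel[(rel >= span_lo) & (rel < span_hi)]
        pos = rec.tss + rel if rec.strand == "+" else rec.tss - rel
        pos_list.append(pos)
        rel_list.append(rel)
        gene_idx_list.append(np.full(rel.size, gi))
    gene_pos = np.concatenate(pos_list) if pos_list else np.array([], dtype=np.int64)
    gene_rel = np.concatenate(rel_list) if rel_list else np.array([], dtype=np.int64)
    gene_gi = np.concatenate(gene_idx_list) if gene_idx_list else np.array([], dtype=np.int64)
    # gene spans are disjoint by construction but guard against duplicates anyway
    _, uniq = np.unique(gene_pos, return_index=True)
    gene_pos, gene_rel, gene_gi = gene_pos[uniq], gene_rel[uniq], gene_gi[uniq]

    # sparse intergenic background (no gene, flat plateau methylation),
    # excluded from every gene's metaplot span
    chrom_len = int(recs["tss"].max()) + cfg.metaplot_downstream + cfg.intergenic_spacing
    n_bg = int(chrom_len / cfg.background_spacing_mean)
    bg_pos = np.unique(rng.integers(0, chrom_len, size=n_bg))
    span_starts = np.sort(np.where(
        recs["strand"].to_numpy() == "+",
        recs["tss"].to_numpy() - cfg.metaplot_upstream,
        recs["tss"].to_numpy() - cfg.metaplot_downstream,
    ))
    full_span = cfg.metaplot_upstream + cfg.metaplot_downstream
    nearest = np.searchsorted(span_starts, bg_pos, side="right") - 1
    in_span = (nearest >= 0) & (bg_pos < span_starts[np.maximum(nearest, 0)] + full_span)
    bg_pos = bg_pos[~in_span]
    bg_pos = bg_pos[~np.isin(bg_pos, gene_pos)]

    pos = np.concatenate([gene_pos, bg_pos])
    rel = np.concatenate([gene_rel, np.zeros(bg_pos.size, dtype=np.int64)])
    gene_idx = np.concatenate([gene_gi, np.full(bg_pos.size, -1)])
    order = np.argsort(pos, kind="stable")
    pos, rel, gene_idx = pos[order], rel[order], gene_idx[order]

    n_sites = pos.size
    is_bg = gene_idx == -1

    # per-gene baseline jitter and DM truth
    jitter = rng.normal(0.0, cfg.gene_jitter_sd, size=n_genes)
    n_dm = int(round(cfg.dm_fraction * n_genes))
    dm_gene_idx = rng.choice(n_genes, size=n_dm, replace=False) if n_dm else np.array([], int)
    dm_sign = rng.choice([-1.0, 1.0], size=n_dm)
    prom_lo, prom_hi = -cfg.promoter_upstream, cfg.promoter_downstream
    if cfg.dm_region_start is not None:
        starts = np.full(n_dm, float(cfg.dm_region_start))
    else:
        starts = rng.uniform(prom_lo, prom_hi - cfg.dm_region_width, size=n_dm) if n_dm else np.array([])
    dm_rel_start = np.floor(starts).astype(np.int64) if n_dm else np.array([], int)
    dm_rel_end = dm_rel_start + int(cfg.dm_region_width)
    dm_genes = pd.DataFrame(
        {
            "gene_id": genes[dm_gene_idx],
            "rel_start": dm_rel_start,
            "rel_end": dm_rel_end,
            "sign": dm_sign.astype(int) if n_dm else np.array([], int),
        }
    )

    # population mean methylation per site (baseline) and the DM shift mask
    base_mu = np.where(is_bg, cfg.plateau_meth, mean_meth_profile(np.where(is_bg, 0, rel), cfg))
    base_mu = base_mu + np.where(is_bg, 0.0, jitter[np.maximum(gene_idx, 0)])
    base_mu = np.clip(base_mu, 1e-3, 1 - 1e-3)
    shift = np.zeros(n_sites)
    for k in range(n_dm):
        m = (gene_idx == dm_gene_idx[k]) & (rel >= dm_rel_start[k]) & (rel < dm_rel_end[k])
        shift[m] = dm_sign[k] * cfg.dm_effect / 100.0

    meth = np.empty((n_sites, n_pools), dtype=np.int64)
    unmeth = np.empty_like(meth)
    rho = cfg.biol_dispersion_meth
    for j, pool in enumerate(pools):
        mu_j = base_mu + (shift if later[j] else 0.0)
        mu_j = np.clip(mu_j, 1e-3, 1 - 1e-3)
        frac = _beta_binomial_fraction(rng, mu_j, rho)
        if cfg.pool_noise_inflation > 0:
            frac = np.clip(frac + rng.normal(0, cfg.pool_noise_inflation, n_sites), 0, 1)
        cov = rng.poisson(cfg.mean_coverage, size=n_sites)
        m = rng.binomial(cov, frac)
        meth[:, j] = m
        unmeth[:, j] = cov - m

    sites = pd.DataFrame({"chrom": "chrSim", "pos": pos})
    table = CpGCountTable(sites, meth, unmeth, pools)

    # noise-free promoter-mean methylation percent per gene per pool
    in_prom = (~is_bg) & (rel >= prom_lo) & (rel < prom_hi)
    prom_pct = np.zeros((n_genes, n_pools))
    for j in range(n_pools):
        mu_j = np.clip(base_mu + (shift if later[j] else 0.0), 1e-3, 1 - 1e-3)
        sums = np.bincount(gene_idx[in_prom], weights=mu_j[in_prom], minlength=n_genes)
        cnts = np.bincount(gene_idx[in_prom], minlength=n_genes)
        prom_pct[:, j] = 100.0 * sums / np.maximum(cnts, 1)
    promoter_meth = pd.DataFrame(prom_pct, index=genes, columns=[p.name for p in pools])
    return table, MethylationTruth(promoter_meth, dm_genes)


def simulate_expression(
    annotation: AnnotationSet,
    promoter_meth_truth: "pd.DataFrame | MethylationTruth",
    cfg: SimConfig,
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Simulate NB expression counts coupled to promoter methylation.

    For a ``coupling_fraction`` subset of genes the log2 mean is
    ``baseline_g + coupling_slope * promoter_meth_percent``; a disjoint
    ``de_fraction`` subset of the remaining genes receives an independent
    ``+/- de_log2fc`` shift at Day28/Day41.  Counts are NB with per-pool
    depth factors and dispersion ``expr_dispersion``.

    When the full :class:`MethylationTruth` is supplied, a coupled gene that
    also carries a treatment methylation shift additionally responds to that
    shift at full strength (``coupling_slope * dm_effect`` log2 units at the
    shifted time points), modelling a regulatory element that sits inside
    the shifted region rather than being diluted over the whole promoter.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, _STAGE_EXPR])
    pools = default_pools(cfg.pools_per_cell)
    later = np.array([p.timepoint != "Day0" for p in pools])
    genes = annotation.records["gene_id"].to_numpy()
    n_genes = len(genes)
    n_pools = len(pools)
    dm_genes = None
    if isinstance(promoter_meth_truth, MethylationTruth):
        dm_genes = promoter_meth_truth.dm_genes
        promoter_meth_truth = promoter_meth_truth.promoter_meth
    meth_pct = promoter_meth_truth.loc[genes, [p.name for p in pools]].to_numpy()

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n_genes)
    n_coupled = int(round(cfg.coupling_fraction * n_genes))
    perm = rng.permutation(n_genes)
    coupled_idx = perm[:n_coupled]
    rest = perm[n_coupled:]
    n_de = int(round(cfg.de_fraction * n_genes))
    n_de = min(n_de, rest.size)
    de_idx = rest[:n_de]
    de_sign = rng.choice([-1.0, 1.0], size=n_de)

    log2_mu = np.tile(baseline[:, None], (1, n_pools))
    coupled_mask = np.zeros(n_genes, dtype=bool)
    coupled_mask[coupled_idx] = True
    # coupled genes: centre the methylation term so the baseline keeps its scale
    log2_mu[coupled_mask] += cfg.coupling_slope * (meth_pct[coupled_mask] - 50.0)
    if dm_genes is not None and len(dm_genes):
        gene_row = {g: i for i, g in enumerate(genes)}
        for rec in dm_genes.itertuples():
            gi = gene_row[rec.gene_id]
            if coupled_mask[gi]:
                log2_mu[gi, later] += cfg.coupling_slope * rec.sign * cfg.dm_effect
    for k, gi in enumerate(de_idx):
        log2_mu[gi, later] += de_sign[k] * cfg.de_log2fc

    depth = rng.uniform(1 - cfg.depth_jitter, 1 + cfg.depth_jitter, size=n_pools)
    mu = depth[None, :] * np.exp2(log2_mu)  # baseline_log2_mean sets the count scale
    phi = cfg.expr_dispersion
    if phi < 1e-8:
        counts = rng.poisson(mu)
    else:
        counts = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))
    df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                      columns=[p.name for p in pools])
    truth = ExpressionTruth(
        coupled_genes=list(genes[np.sort(coupled_idx)]),
        de_genes=pd.DataFrame({"gene_id": genes[de_idx], "sign": de_sign.astype(int)}),
    )
    return ExpressionMatrix(df, pools), truth


def simulate_dataset(cfg: SimConfig):
    """Run all three stages; returns (annotation, cpg_table, expr, meth_truth, expr_truth)."""
    annotation = simulate_annotation(cfg)
    cpg, meth_truth = simulate_methylation(annotation, cfg)
    expr, expr_truth = simulate_expression(annotation, meth_truth, cfg)
    return annotation, cpg, expr, meth_truth, expr_truth
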