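"""Expression filtering, TMM normalization, log2-CPM and NB differential
expression.

This is an original implementation of the standard count-based RNA-seq
workflow: CPM filtering, trimmed-mean-of-M-values (TMM) between-sample
factors, prior-count log2-CPM, negative-binomial dispersion estimation by
grid-profiled likelihood with shrinkage toward the common value, and a
per-gene NB likelihood-ratio test for a two-group contrast with BH-FDR
calling.  It targets statistical agreement (calibration and parameter
recovery), not bit-compatibility with any particular reference tool.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io_formats import Comparison, ExpressionMatrix
from .methylation import adjust_pvalues

__all__ = [
    "filter_expressed",
    "tmm_factors",
    "log_cpm",
    "estimate_dispersion",
    "de_test",
    "summarize_de",
]


def filter_expressed(
    matrix: ExpressionMatrix, min_cpm: float = 1.0, min_pools: int | None = None
) -> ExpressionMatrix:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_pools`` pools.

    ``min_pools`` defaults to the smallest genotype-by-time group size.
    """
    if min_pools is None:
        labels = [(p.genotype, p.timepoint) for p in matrix.pools]
        min_pools = min(labels.count(l) for l in set(labels))
    cpm = matrix.counts.to_numpy() / matrix.lib_sizes[None, :] * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_pools
    return matrix.subset_genes(keep)


def tmm_factors(
    matrix: ExpressionMatrix,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors.

    The reference pool is the one whose 75th count percentile (as a fraction
    of library size) is closest to the mean across pools (smallest index on
    ties).  For each other pool, per-gene log2 rate ratios M and average
    log2 abundances A are computed over genes positive in both pools, the
    30% M tails and 5% A tails are trimmed, and the factor is 2 to the
    inverse-asymptotic-variance weighted mean of the surviving M.  Factors
    are rescaled to geometric mean 1.
    """
    y = matrix.counts.to_numpy(dtype=float)
    if y.shape[1] < 2:
        raise ValueError("TMM needs at least two pools")
    lib = matrix.lib_sizes
    uq = np.array([np.quantile(y[:, j][y[:, j] > 0], 0.75) if (y[:, j] > 0).any() else 0.0
                   for j in range(y.shape[1])]) / lib
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        factors[j] = _tmm_pair(y[:, j], lib[j], y[:, ref], lib[ref], logratio_trim, abs_trim)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def _tmm_pair(y, n, yr, nr, logratio_trim, abs_trim):
    pos = (y > 0) & (yr > 0)
    if pos.sum() == 0:
        return 1.0
    y, yr = y[pos], yr[pos]
    r, rr = y / n, yr / nr
    m = np.log2(r / rr)
    a = 0.5 * np.log2(r * rr)
    w = (n - y) / (n * y) + (nr - yr) / (nr * yr)  # asymptotic var of M

    k = m.size
    lo_m, hi_m = np.quantile(m, logratio_trim), np.quantile(m, 1 - logratio_trim)
    lo_a, hi_a = np.quantile(a, abs_trim), np.quantile(a, 1 - abs_trim)
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if keep.sum() < 20:
        warnings.warn("fewer than 20 genes survive TMM trimming; using untrimmed mean",
                      stacklevel=2)
        keep = np.ones(k, dtype=bool)
    mw = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0**mw)


def log_cpm(matrix: ExpressionMatrix, prior: float = 2.0) -> pd.DataFrame:
    """log2 counts-per-million with a library-size-scaled prior count.

    log2((count + prior*L_i/Lbar) / (L_i + 2*prior*L_i/Lbar) * 1e6) with
    L_i the TMM-effective library size.
    """
    if prior <= 0:
        raise ValueError("prior must be > 0")
    lib = matrix.effective_lib_sizes
    scaled_prior = prior * lib / lib.mean()
    y = matrix.counts.to_numpy(dtype=float)
    vals = np.log2((y + scaled_prior[None, :]) / (lib + 2 * scaled_prior)[None, :] * 1e6)
    return pd.DataFrame(vals, index=matrix.counts.index, columns=matrix.counts.columns)


# ---------------------------------------------------------------------------
# negative-binomial machinery


def _nb_loglik(y, mu, phi):
    """NB log-likelihood, elementwise then summed over the last axis.

    phi -> 0 reduces to Poisson.  Shapes broadcast; zero-mean cells with
    zero counts contribute 0.
    """
    mu = np.maximum(mu, 1e-12)
    if phi < 1e-10:
        return np.sum(y * np.log(mu) - mu - gammaln(y + 1), axis=-1)
    inv = 1.0 / phi
    return np.sum(
        gammaln(y + inv) - gammaln(inv) - gammaln(y + 1)
        + y * np.log(phi * mu / (1 + phi * mu))
        - inv * np.log1p(phi * mu),
        axis=-1,
    )


def _nb_fit_onegroup(y, offsets, phi, n_iter=25, tol=1e-10):
    """MLE of a single NB mean rate with known offsets, vectorized over genes.

    Model mu_gj = m_g * offset_j; Fisher-scoring on log m_g starting from
    the rate estimate sum(y)/sum(offset).  Genes with all-zero counts get
    rate 0 (their likelihood contribution is exactly 0 for y = 0).
    """
    y = np.atleast_2d(y)
    tot = y.sum(axis=1)
    off_tot = np.sum(offsets)
    rate = tot / off_tot
    zero = tot == 0
    b = np.log(np.where(zero, 1.0, rate))
    if phi >= 1e-10:
        for _ in range(n_iter):
            mu = np.exp(b)[:, None] * offsets[None, :]
            denom = 1.0 + phi * mu
            score = np.sum((y - mu) / denom, axis=1)
            info = np.sum(mu / denom, axis=1)
            step = score / np.maximum(info, 1e-12)
            step = np.clip(step, -5, 5)
            b = b + step
            if np.max(np.abs(step[~zero]), initial=0.0) < tol:
                break
    rate = np.where(zero, 0.0, np.exp(b))
    mu = rate[:, None] * offsets[None, :]
    ll = _nb_loglik(y, np.where(mu > 0, mu, 1e-300), phi)
    ll = np.where(zero, _nb_loglik(y, np.full_like(y, 1e-300, dtype=float), phi), ll)
    return rate, ll


def _group_indices(matrix: ExpressionMatrix):
    """Pools grouped by genotype x timepoint (the design cells)."""
    groups: dict[tuple[str, str], list[int]] = {}
    for j, p in enumerate(matrix.pools):
        groups.setdefault((p.genotype, p.timepoint), []).append(j)
    return list(groups.values())


def _profile_loglik_per_gene(y, offsets, groups, phi):
    """Cox-Reid adjusted profile log-likelihood summed over design cells.

    The adjustment (-0.5 log of the Fisher information of the fitted mean)
    removes most of the downward bias of the plain profile likelihood when
    group sizes are small.
    """
    total = np.zeros(y.shape[0])
    for idx in groups:
        rate, ll = _nb_fit_onegroup(y[:, idx], offsets[idx], phi)
        mu = rate[:, None] * offsets[idx][None, :]
        info = np.sum(mu / (1.0 + phi * mu), axis=1)
        adj = np.where(info > 0, 0.5 * np.log(np.maximum(info, 1e-300)), 0.0)
        total += ll - adj
    return total


def estimate_dispersion(
    matrix: ExpressionMatrix,
    groups: list[list[int]] | None = None,
    prior_df: float = 10.0,
    default_phi: float = 0.1,
) -> tuple[float, np.ndarray]:
    """Common and tagwise NB dispersions by grid-profiled likelihood.

    The common dispersion maximizes the profile log-likelihood summed over
    genes on a 61-point log grid from 1e-4 to 10, refined by golden-section
    search.  Tagwise values shrink each gene's grid MLE toward the common
    value with a prior weight equivalent to ``prior_df`` residual degrees of
    freedom.  If every design cell has a single pool there is no replication
    to estimate from and the configured default is returned with a warning.
    """
    y = matrix.counts.to_numpy(dtype=float)
    offsets = matrix.effective_lib_sizes / np.mean(matrix.effective_lib_sizes)
    if groups is None:
        groups = _group_indices(matrix)
    resid_df = y.shape[1] - len(groups)
    if resid_df <= 0:
        warnings.warn("no replication in any group; using default dispersion", stacklevel=2)
        return default_phi, np.full(y.shape[0], default_phi)

    grid = np.logspace(-4, 1, 61)
    ll_grid = np.empty((y.shape[0], grid.size))
    for k, phi in enumerate(grid):
        ll_grid[:, k] = _profile_loglik_per_gene(y, offsets, groups, phi)
    total = ll_grid.sum(axis=0)
    best = int(np.argmax(total))

    # golden-section refinement of the common value around the grid optimum
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid.size - 1)]
    common = _golden_max(
        lambda p: _profile_loglik_per_gene(y, offsets, groups, p).sum(), lo, hi
    )

    tag_mle = grid[np.argmax(ll_grid, axis=1)]
    tagwise = (resid_df * tag_mle + prior_df * common) / (resid_df + prior_df)
    return float(common), tagwise


def _golden_max(f, lo, hi, n_iter=30):
    g = (np.sqrt(5) - 1) / 2
    a, b = np.log(lo), np.log(hi)
    c, d = b - g * (b - a), a + g * (b - a)
    fc, fd = f(np.exp(c)), f(np.exp(d))
    for _ in range(n_iter):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - g * (b - a)
            fc = f(np.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + g * (b - a)
            fd = f(np.exp(d))
    return float(np.exp((a + b) / 2))


def de_test(
    matrix: ExpressionMatrix,
    comparison: Comparison,
    tagwise_phi: np.ndarray | None = None,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Two-group NB likelihood-ratio test per gene with BH-FDR calling.

    Fits a one-rate null and a two-rate (group) alternative with library
    offsets and the gene's tagwise dispersion; log2_fc is B over A from the
    fitted rates with a half-count continuity floor; calls are up/down at
    ``fdr < fdr_cut``.  Genes with zero counts in every pool of both groups
    are skipped (the expression filter should have removed them).
    """
    ia, ib = list(comparison.pools_a), list(comparison.pools_b)
    if len(ia) + len(ib) < 3:
        raise ValueError("need at least three pools across the two groups")
    y = matrix.counts.to_numpy(dtype=float)
    offsets = matrix.effective_lib_sizes / np.mean(matrix.effective_lib_sizes)
    if tagwise_phi is None:
        _, tagwise_phi = estimate_dispersion(matrix)
    tagwise_phi = np.asarray(tagwise_phi, dtype=float)

    ya, yb = y[:, ia], y[:, ib]
    oa, ob = offsets[ia], offsets[ib]
    yab = y[:, ia + ib]
    oab = offsets[ia + ib]

    n_genes = y.shape[0]
    lrt = np.zeros(n_genes)
    rate_a = np.zeros(n_genes)
    rate_b = np.zeros(n_genes)
    # group genes by (rounded) dispersion to keep the fits vectorized
    for phi in np.unique(np.round(tagwise_phi, 6)):
        sel = np.round(tagwise_phi, 6) == phi
        ra, ll_a = _nb_fit_onegroup(ya[sel], oa, phi)
        rb, ll_b = _nb_fit_onegroup(yb[sel], ob, phi)
        _, ll_0 = _nb_fit_onegroup(yab[sel], oab, phi)
        lrt[sel] = np.maximum(2.0 * (ll_a + ll_b - ll_0), 0.0)
        rate_a[sel], rate_b[sel] = ra, rb

    skipped = (ya.sum(axis=1) == 0) & (yb.sum(axis=1) == 0)
    p = stats.chi2.sf(lrt, df=1)
    p[skipped] = np.nan

    # continuity-floored fold change for reporting
    fa = np.maximum(rate_a, 0.5 / oa.sum())
    fb = np.maximum(rate_b, 0.5 / ob.sum())
    log2_fc = np.log2(fb / fa)
    log2_fc[skipped] = np.nan

    fdr = adjust_pvalues(p)
    lcpm = log_cpm(matrix)
    out = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "log2_fc": log2_fc,
            "log2_cpm_mean": lcpm.to_numpy()[:, ia + ib].mean(axis=1),
            "p_value": p,
            "fdr": fdr,
        }
    )
    sig = (out["fdr"] < fdr_cut).fillna(False)
    out["call"] = np.where(
        sig & (out["log2_fc"] > 0), "up", np.where(sig & (out["log2_fc"] < 0), "down", "ns")
    )
    return out


def summarize_de(results: pd.DataFrame, total_transcripts: int) -> dict:
    """Up/down counts with percentages of the assayed transcript universe."""
    if total_transcripts == 0:
        raise ValueError("total_transcripts must be positive")
    down = int((results["call"] == "down").sum())
    up = int((results["call"] == "up").sum())
    return {
        "down_count": down,
        "up_count": up,
        "down_pct": round(100.0 * down / total_transcripts, 2),
        "up_pct": round(100.0 * up / total_transcripts, 2),
    }
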