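"""CpG-level filtering, coverage normalization and differential methylation.

The differential test is a two-group binomial logistic regression fitted per
unit (CpG site or promoter window) over the pools' (methylated, coverage)
observations, with a likelihood-ratio test for the group coefficient and a
Pearson-X^2/df overdispersion scaling of the statistic (floored at 1).  With
a single group covariate the binomial logistic MLE is available in closed
form — the fitted probability of each group is its coverage-pooled
methylation proportion — which lets the whole genome be tested with array
arithmetic; tests cross-check this against an iterative GLM fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import Comparison, CpGCountTable

__all__ = [
    "filter_coverage",
    "normalize_coverage",
    "dm_test",
    "dm_test_table",
    "adjust_pvalues",
    "call_dm",
    "summarize_dm_calls",
]

_BETA_CLIP = 20.0  # cap on |group log-odds difference| under separation
_P_FLOOR = 1e-12


def filter_coverage(table: CpGCountTable, min_cov: int = 10) -> CpGCountTable:
    """Keep only sites with coverage >= ``min_cov`` in *every* pool."""
    keep = (table.coverage >= min_cov).all(axis=1)
    return table.subset(keep)


def normalize_coverage(table: CpGCountTable) -> CpGCountTable:
    """Scale each pool's counts so median coverages line up across pools.

    Pool ``i`` is scaled by ``median(pool medians) / median(pool i)``; both
    counts are multiplied and rounded half-up independently, which preserves
    the methylation fraction to within one read.
    """
    cov = table.coverage
    medians = np.median(cov, axis=0)
    if (medians == 0).any():
        j = int(np.argmax(medians == 0))
        raise ValueError(f"pool {table.pools[j].name} has zero median coverage")
    target = np.median(medians)
    s = target / medians
    meth = np.floor(table.meth * s[None, :] + 0.5).astype(np.int64)
    unmeth = np.floor(table.unmeth * s[None, :] + 0.5).astype(np.int64)
    return CpGCountTable(table.sites.copy(), meth, unmeth, list(table.pools))


def _group_loglik(meth, cov, p):
    """Binomial log-likelihood (without the constant) summed over pools."""
    p = np.clip(p, _P_FLOOR, 1 - _P_FLOOR)
    if p.ndim == 1:
        p = p[:, None]
    return (meth * np.log(p) + (cov - meth) * np.log1p(-p)).sum(axis=1)


def dm_test(meth_a, unmeth_a, meth_b, unmeth_b, return_details: bool = False):
    """Differential methylation test for stacked units.

    Parameters are (n_units, n_pools_in_group) arrays (1-D input is treated
    as a single unit).  Returns ``(meth_diff, statistic, p_value, ok)``
    where ``meth_diff`` is percentage points (B - A) of the coverage-pooled
    group methylation, ``statistic`` the overdispersion-corrected LRT, and
    ``ok`` flags units testable in both groups (others get NaN and are meant
    to be skipped by the caller).  With ``return_details`` the uncorrected
    LRT and the dispersion estimate phi are appended to the tuple.
    """
    meth_a, unmeth_a = np.atleast_2d(meth_a), np.atleast_2d(unmeth_a)
    meth_b, unmeth_b = np.atleast_2d(meth_b), np.atleast_2d(unmeth_b)
    cov_a, cov_b = meth_a + unmeth_a, meth_b + unmeth_b

    tot_ma, tot_ca = meth_a.sum(axis=1), cov_a.sum(axis=1)
    tot_mb, tot_cb = meth_b.sum(axis=1), cov_b.sum(axis=1)
    ok = (tot_ca > 0) & (tot_cb > 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        p_a = tot_ma / np.maximum(tot_ca, 1)
        p_b = tot_mb / np.maximum(tot_cb, 1)
        p_0 = (tot_ma + tot_mb) / np.maximum(tot_ca + tot_cb, 1)

    # separation guard: clip each group's fitted logit to +/- BETA_CLIP/2,
    # which caps the group coefficient |beta1| at BETA_CLIP and keeps the
    # test symmetric under relabeling A <-> B
    p_lo = 1.0 / (1.0 + np.exp(_BETA_CLIP / 2))
    p_a_fit = np.clip(p_a, p_lo, 1 - p_lo)
    p_b_fit = np.clip(p_b, p_lo, 1 - p_lo)

    ll_full = _group_loglik(meth_a, cov_a, p_a_fit) + _group_loglik(meth_b, cov_b, p_b_fit)
    ll_null = _group_loglik(meth_a, cov_a, p_0) + _group_loglik(meth_b, cov_b, p_0)
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)

    # Pearson X^2 of the full model over pools with coverage, df = n_obs - 2
    def _pearson(meth, cov, p):
        p = np.clip(p, _P_FLOOR, 1 - _P_FLOOR)[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = np.square(meth - cov * p) / (cov * p * (1 - p))
        return np.where(cov > 0, contrib, 0.0).sum(axis=1)

    x2 = _pearson(meth_a, cov_a, p_a_fit) + _pearson(meth_b, cov_b, p_b_fit)
    n_obs = (cov_a > 0).sum(axis=1) + (cov_b > 0).sum(axis=1)
    df = n_obs - 2
    phi = np.where(df > 0, x2 / np.maximum(df, 1), 1.0)
    phi = np.maximum(phi, 1.0)

    statistic = lrt / phi
    p_value = stats.chi2.sf(statistic, df=1)
    meth_diff = 100.0 * (p_b - p_a)

    bad = ~ok
    for arr in (meth_diff, statistic, p_value):
        arr[bad] = np.nan
    if return_details:
        return meth_diff, statistic, p_value, ok, lrt, phi
    return meth_diff, statistic, p_value, ok


def dm_test_table(table: CpGCountTable, comparison: Comparison) -> pd.DataFrame:
    """Run :func:`dm_test` on every CpG site for one comparison.

    Units untestable in a group (all-zero coverage) are skipped with the
    reason recorded in the ``skip_reason`` column.
    """
    ia, ib = list(comparison.pools_a), list(comparison.pools_b)
    meth_diff, statistic, p, ok = dm_test(
        table.meth[:, ia], table.unmeth[:, ia], table.meth[:, ib], table.unmeth[:, ib]
    )
    cov_a = table.coverage[:, ia].sum(axis=1)
    cov_b = table.coverage[:, ib].sum(axis=1)
    pct_a = 100.0 * table.meth[:, ia].sum(axis=1) / np.maximum(cov_a, 1)
    pct_b = 100.0 * table.meth[:, ib].sum(axis=1) / np.maximum(cov_b, 1)
    out = pd.DataFrame(
        {
            "chrom": table.sites["chrom"].to_numpy(),
            "pos": table.sites["pos"].to_numpy(),
            "meth_percent_A": pct_a,
            "meth_percent_B": pct_b,
            "meth_diff": meth_diff,
            "statistic": statistic,
            "p_value": p,
            "skip_reason": np.where(ok, "", "zero coverage in a group"),
        }
    )
    return out


def adjust_pvalues(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    finite = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if finite.any():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def call_dm(
    results: pd.DataFrame,
    q_cut: float = 0.01,
    diff_cut: float = 25.0,
    mode: str = "promoter",
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Attach q-values and hyper/hypo/ns calls to a DM result table.

    ``promoter`` mode requires q < ``q_cut`` and |meth_diff| >= ``diff_cut``;
    ``window`` mode requires only p < ``p_cut`` (no q, no effect-size filter).
    """
    out = results.copy()
    out["q_value"] = adjust_pvalues(out["p_value"].to_numpy())
    if mode == "promoter":
        sig = (out["q_value"] < q_cut) & (out["meth_diff"].abs() >= diff_cut)
    elif mode == "window":
        sig = out["p_value"] < p_cut
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sig = sig.fillna(False)
    out["call"] = np.where(
        sig & (out["meth_diff"] > 0), "hyper", np.where(sig & (out["meth_diff"] < 0), "hypo", "ns")
    )
    return out


def summarize_dm_calls(called: pd.DataFrame) -> dict:
    """(total, hypo, hyper) counts in the published table layout."""
    hypo = int((called["call"] == "hypo").sum())
    hyper = int((called["call"] == "hyper").sum())
    return {"total": hypo + hyper, "hypo": hypo, "hyper": hyper}
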