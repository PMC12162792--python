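"""CPM filtering, TMM factors, log-CPM, dispersion estimation and the NB
likelihood-ratio test, with brute-force and external oracles."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from promethyl.expression import (
    de_test,
    estimate_dispersion,
    filter_expressed,
    log_cpm,
    summarize_de,
    tmm_factors,
)
from promethyl.io_formats import Comparison, ExpressionMatrix, PoolLabel
from promethyl.simulate import default_pools


def make_matrix(counts, n_pools=None):
    counts = np.asarray(counts)
    pools = default_pools()[: counts.shape[1]]
    df = pd.DataFrame(
        counts,
        index=pd.Index([f"g{i}" for i in range(counts.shape[0])], name="gene_id"),
        columns=[p.name for p in pools],
    )
    return ExpressionMatrix(df, pools)


class TestFilterExpressed:
    def test_all_zero_gene_removed(self):
        m = make_matrix([[0, 0], [100, 100]])
        assert filter_expressed(m, min_pools=1).gene_ids == ["g1"]

    def test_cpm_threshold_in_enough_pools(self):
        # lib sizes ~2e6: g0 has CPM (1.5, 0) -> removed at min_pools=2
        base = np.full((1000, 2), 2000)
        g0 = np.array([[3, 0]])
        m = make_matrix(np.vstack([g0, base]))
        kept = filter_expressed(m, min_cpm=1.0, min_pools=2)
        assert "g0" not in kept.gene_ids

    def test_zero_threshold_is_identity(self):
        m = make_matrix([[0, 5], [3, 0]])
        assert filter_expressed(m, min_cpm=0.0, min_pools=1).gene_ids == m.gene_ids


def _tmm_oracle(y, lib, j, ref):
    """Straightforward re-implementation of the trimmed weighted mean."""
    yj, yr = y[:, j].astype(float), y[:, ref].astype(float)
    pos = (yj > 0) & (yr > 0)
    yj, yr = yj[pos], yr[pos]
    n, nr = lib[j], lib[ref]
    m = np.log2((yj / n) / (yr / nr))
    a = 0.5 * np.log2((yj / n) * (yr / nr))
    w = (n - yj) / (n * yj) + (nr - yr) / (nr * yr)
    keep = (
        (m >= np.quantile(m, 0.3)) & (m <= np.quantile(m, 0.7))
        & (a >= np.quantile(a, 0.05)) & (a <= np.quantile(a, 0.95))
    )
    return 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep]))


class TestTMM:
    def test_identical_columns_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 500, size=300)
        m = make_matrix(np.column_stack([col, col]))
        assert np.allclose(tmm_factors(m), 1.0)

    def test_pure_depth_absorbed_by_lib_sizes(self):
        rng = np.random.default_rng(1)
        col = rng.integers(10, 500, size=400)
        m = make_matrix(np.column_stack([col, 2 * col]))
        assert np.allclose(tmm_factors(m), 1.0, atol=1e-12)

    def test_composition_shift_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        base = rng.integers(50, 500, size=1000)
        shifted = base.copy()
        shifted[:100] *= 8  # 10% of genes 8-fold up in pool 2
        y = np.column_stack([base, shifted])
        m = make_matrix(y)
        factors = tmm_factors(m)
        lib = m.lib_sizes
        uq = np.array([np.quantile(y[:, j][y[:, j] > 0], 0.75) for j in range(2)]) / lib
        ref = int(np.argmin(np.abs(uq - uq.mean())))
        j = 1 - ref
        raw = _tmm_oracle(y, lib, j, ref)
        expected = np.ones(2)
        expected[j] = raw
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(factors, expected, atol=1e-6)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
    def test_factors_agree_with_edger(self, tmp_path):
        """Loose cross-check against the Bioconductor TMM implementation."""
        rng = np.random.default_rng(7)
        y = rng.negative_binomial(10, 10 / (10 + 300), size=(500, 4))
        y[:50, 2] *= 5
        m = make_matrix(y)
        ours = tmm_factors(m)
        counts_file = tmp_path / "counts.tsv"
        np.savetxt(counts_file, y, fmt="%d", delimiter="\t")
        script = tmp_path / "tmm.R"
        script.write_text(textwrap.dedent("""
            suppressMessages(library(edgeR))
            y <- as.matrix(read.table(commandArgs(TRUE)[1]))
            f <- calcNormFactors(y, method="TMM")
            cat(sprintf("%.8f\\n", f))
        """))
        out = subprocess.run(["Rscript", str(script), str(counts_file)],
                             capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        theirs = np.array([float(x) for x in out.stdout.split()])
        assert np.allclose(ours, theirs, rtol=0.05, atol=0.02)


class TestLogCpm:
    def test_zero_counts_equal_libs_constant(self):
        m = make_matrix(np.vstack([[0, 0], np.full((50, 2), 100)]))
        vals = log_cpm(m).iloc[0]
        assert vals.iloc[0] == pytest.approx(vals.iloc[1])

    def test_doubling_large_counts_adds_one(self):
        filler = np.full((10000, 2), 1000)  # dominate the library size
        m = make_matrix(np.vstack([[40000, 80000], filler]))
        vals = log_cpm(m).iloc[0]
        assert vals.iloc[1] - vals.iloc[0] == pytest.approx(1.0, abs=0.02)

    def test_zero_prior_rejected(self):
        m = make_matrix([[1, 1]])
        with pytest.raises(ValueError, match="prior"):
            log_cpm(m, prior=0.0)

    def test_monotone_in_count(self):
        filler = np.full((100, 4), 500)
        m = make_matrix(np.vstack([[1, 10, 100, 1000], filler]))
        vals = log_cpm(m).iloc[0].to_numpy()
        # equal library sizes up to the gene itself; ordering must hold
        assert np.all(np.diff(vals) > 0)


def _nb_counts(rng, mean, phi, shape):
    if phi == 0:
        return rng.poisson(mean, size=shape)
    return rng.negative_binomial(1 / phi, 1 / (1 + phi * mean), size=shape)


class TestDispersion:
    def test_poisson_counts_give_near_zero(self):
        rng = np.random.default_rng(10)
        m = make_matrix(_nb_counts(rng, 200, 0.0, (2000, 12)))
        common, _ = estimate_dispersion(m)
        assert common <= 0.01

    def test_recovers_true_dispersion(self):
        rng = np.random.default_rng(11)
        m = make_matrix(_nb_counts(rng, 300, 0.1, (2000, 12)))
        common, tag = estimate_dispersion(m)
        assert 0.07 <= common <= 0.13
        assert np.all(tag >= 0)

    def test_more_replication_does_not_inflate(self):
        rng = np.random.default_rng(12)
        y = _nb_counts(rng, 300, 0.1, (800, 6))
        pools6 = default_pools(1)  # 6 pools, one per cell
        m1 = ExpressionMatrix(
            pd.DataFrame(y, index=[f"g{i}" for i in range(800)],
                         columns=[p.name for p in pools6]), pools6)
        y2 = np.hstack([y, _nb_counts(rng, 300, 0.1, (800, 6))])
        pools12 = default_pools(2)
        m2 = ExpressionMatrix(
            pd.DataFrame(y2, index=[f"g{i}" for i in range(800)],
                         columns=[p.name for p in pools12]), pools12)
        c1, _ = estimate_dispersion(m1, groups=[[0, 1, 2], [3, 4, 5]])
        c2, _ = estimate_dispersion(m2, groups=[[0, 1, 2, 6, 7, 8], [3, 4, 5, 9, 10, 11]])
        # doubling replication of the same process: estimate stays in range
        assert abs(c2 - 0.1) <= abs(c1 - 0.1) + 0.03

    def test_no_replication_falls_back_with_warning(self):
        m = make_matrix(np.random.default_rng(1).integers(1, 100, (50, 6)))
        groups = [[j] for j in range(6)]
        with pytest.warns(UserWarning, match="replication"):
            common, tag = estimate_dispersion(m, groups=groups)
        assert common == 0.1


class TestDETest:
    def _comp(self):
        return Comparison("A_vs_B", (0, 1), (2, 3))

    def test_label_swap_negates_lfc(self):
        rng = np.random.default_rng(13)
        m = make_matrix(_nb_counts(rng, 200, 0.05, (300, 4)))
        fwd = de_test(m, Comparison("f", (0, 1), (2, 3)), tagwise_phi=np.full(300, 0.05))
        rev = de_test(m, Comparison("r", (2, 3), (0, 1)), tagwise_phi=np.full(300, 0.05))
        assert np.allclose(fwd["log2_fc"], -rev["log2_fc"], atol=1e-6)
        assert np.allclose(fwd["p_value"], rev["p_value"], atol=1e-8)

    def test_recovers_known_fold_change(self):
        rng = np.random.default_rng(14)
        y = _nb_counts(rng, 5000, 0.05, (400, 4)).astype(np.int64)
        y[:40, 2:] = _nb_counts(rng, 20000, 0.05, (40, 2))  # true log2 fc = 2
        m = make_matrix(y)
        m.norm_factors = tmm_factors(m)  # absorb the composition shift
        res = de_test(m, self._comp(), tagwise_phi=np.full(400, 0.05))
        est = res["log2_fc"][:40]
        assert np.median(np.abs(est - 2.0)) < 0.3
        assert (res["call"][:40] == "up").mean() > 0.9

    def test_gene_and_pool_order_invariance(self):
        rng = np.random.default_rng(15)
        y = _nb_counts(rng, 300, 0.05, (100, 4))
        m = make_matrix(y)
        res = de_test(m, self._comp(), tagwise_phi=np.full(100, 0.05))
        perm = rng.permutation(100)
        m2 = make_matrix(y[perm])
        m2.counts.index = pd.Index([f"g{i}" for i in perm], name="gene_id")
        res2 = de_test(m2, self._comp(), tagwise_phi=np.full(100, 0.05))
        merged = res.set_index("gene_id").join(res2.set_index("gene_id"), rsuffix="_p")
        assert np.allclose(merged["p_value"], merged["p_value_p"], atol=1e-9)


class TestSummarizeDE:
    def test_published_style_percentages(self):
        res = pd.DataFrame({"call": ["down"] * 253 + ["up"] * 652 + ["ns"] * 10})
        s = summarize_de(res, 27856)
        assert (s["down_pct"], s["up_pct"]) == (0.91, 2.34)

    def test_zero_counts(self):
        s = summarize_de(pd.DataFrame({"call": ["ns"]}), 100)
        assert s == {"down_count": 0, "up_count": 0, "down_pct": 0.0, "up_pct": 0.0}

    def test_combined_percentage(self):
        res = pd.DataFrame({"call": ["down"] * 829 + ["up"] * 1508})
        s = summarize_de(res, 27856)
        assert round(100 * (829 + 1508) / 27856, 2) == 8.39
        assert s["down_count"] + s["up_count"] == 2337

    def test_zero_universe_rejected(self):
        with pytest.raises(ValueError):
            summarize_de(pd.DataFrame({"call": []}), 0)
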