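"""Generator structure: determinism, the TSS profile, truth-table hygiene,
and closed-form marginals."""

import numpy as np
import pandas as pd
import pytest

from promethyl.io_formats import TIMEPOINTS
from promethyl.simulate import (
    SimConfig,
    default_pools,
    mean_meth_profile,
    simulate_annotation,
    simulate_dataset,
    simulate_expression,
    simulate_methylation,
)
from promethyl.windows import tss_relative_position


class TestProfile:
    def test_trough_value_at_offset(self):
        cfg = SimConfig()
        assert mean_meth_profile(200, cfg) == pytest.approx(0.15)

    def test_far_upstream_reaches_plateau(self):
        cfg = SimConfig()
        assert mean_meth_profile(-5000, cfg) == pytest.approx(0.80, abs=0.01)

    def test_degenerate_flat_profile(self):
        cfg = SimConfig(plateau_meth=0.5, trough_meth=0.5)
        rel = np.arange(-5000, 1000, 37)
        assert np.allclose(mean_meth_profile(rel, cfg), 0.5)

    def test_monotone_decreasing_into_trough(self):
        cfg = SimConfig()
        rel = np.arange(-5000, 201)
        vals = mean_meth_profile(rel, cfg)
        assert np.all(np.diff(vals) <= 1e-12)


class TestAnnotation:
    def test_metaplot_spans_disjoint(self):
        cfg = SimConfig(n_genes=2, intergenic_spacing=20000)
        ann = simulate_annotation(cfg)
        spans = [(t - 5000, t + 1000) for t in ann.records["tss"]]
        assert spans[0][1] <= spans[1][0]

    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=5, n_genes=30)
        assert simulate_annotation(cfg).records.equals(simulate_annotation(cfg).records)

    def test_zero_genes_allowed(self):
        assert len(simulate_annotation(SimConfig(n_genes=0))) == 0

    def test_too_small_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            simulate_annotation(SimConfig(intergenic_spacing=3000))


class TestMethylation:
    def test_deterministic_under_seed(self, small_cfg, small_dataset):
        _, cpg, *_ = small_dataset
        ann = simulate_annotation(small_cfg)
        cpg2, _ = simulate_methylation(ann, small_cfg)
        assert np.array_equal(cpg.meth, cpg2.meth)
        assert np.array_equal(cpg.unmeth, cpg2.unmeth)

    def test_empty_truth_table_without_dm(self):
        cfg = SimConfig(seed=2, n_genes=20, dm_fraction=0.0)
        ann = simulate_annotation(cfg)
        _, truth = simulate_methylation(ann, cfg)
        assert truth.dm_genes.empty

    def test_observed_fraction_matches_binomial_error(self):
        """At rho=0 and deep coverage the trough sites hit ~15% within 2 s.e."""
        cfg = SimConfig(seed=9, n_genes=20, mean_coverage=1000,
                        biol_dispersion_meth=0.0, gene_jitter_sd=0.0, dm_fraction=0.0)
        ann = simulate_annotation(cfg)
        cpg, _ = simulate_methylation(ann, cfg)
        # collect CpGs within a few bp of the trough offset
        recs = ann.records.set_index("gene_id")
        pos = cpg.sites["pos"].to_numpy()
        sel = np.zeros(len(pos), dtype=bool)
        for rec in recs.itertuples():
            rel = tss_relative_position(pos, rec.tss, rec.strand)
            sel |= np.abs(rel - 200) <= 10  # profile is flat to <1e-3 here
        assert sel.any()
        m = cpg.meth[sel].sum()
        n = cpg.coverage[sel].sum()
        p_exp = mean_meth_profile(200, cfg)
        se = np.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(m / n - p_exp) < 2 * se + 0.003  # small slack for +/-2 bp window

    def test_truth_tables_have_no_leakage(self, small_dataset):
        """The DM truth table is exactly the perturbed genes: sites outside
        listed regions have identical expected methylation across times."""
        _, cpg, _, meth_truth, _ = small_dataset
        listed = set(meth_truth.dm_genes["gene_id"])
        prom = meth_truth.promoter_meth
        day0 = [c for c in prom.columns if "Day0" in c]
        day28 = [c for c in prom.columns if "Day28" in c]
        moved = prom[day28].mean(axis=1) - prom[day0].mean(axis=1)
        moved_set = set(prom.index[moved.abs() > 1e-9])
        # no unlisted gene ever moves; a listed gene may fail to move only if
        # its shifted region happens to contain no CpG (rare but legitimate)
        assert moved_set <= listed
        assert len(moved_set) >= 0.8 * len(listed)

    def test_empirical_profile_matches_mean_curve(self):
        cfg = SimConfig(seed=11, n_genes=250, dm_fraction=0.0)
        ann = simulate_annotation(cfg)
        cpg, _ = simulate_methylation(ann, cfg)
        recs = ann.records
        pos = cpg.sites["pos"].to_numpy()
        # pool all sites of all genes into 250 bp bins of relative position
        rel_all = np.full(len(pos), np.nan)
        for rec in recs.itertuples():
            rel = tss_relative_position(pos, rec.tss, rec.strand)
            in_span = (rel >= -5000) & (rel < 1000)
            rel_all[in_span] = rel[in_span]
        ok = ~np.isnan(rel_all)
        frac = cpg.meth[ok].sum(axis=1) / cpg.coverage[ok].sum(axis=1)
        bins = np.arange(-5000, 1001, 250)
        idx = np.digitize(rel_all[ok], bins) - 1
        rel_ok = rel_all[ok]
        for b in range(len(bins) - 1):
            sel = idx == b
            if sel.sum() < 50:
                continue
            expected = mean_meth_profile(rel_ok[sel], cfg).mean()
            assert abs(frac[sel].mean() - expected) < 0.05


class TestExpression:
    def test_coupling_closed_form(self):
        """Coupled gene at 80% vs 15% methylation: log2 ratio = -0.05*65."""
        cfg = SimConfig(seed=4, n_genes=400, coupling_fraction=1.0,
                        coupling_slope=-0.05, de_fraction=0.0,
                        expr_dispersion=1e-14, depth_jitter=0.0,
                        baseline_log2_mean=14.0, baseline_log2_sd=0.0)
        ann = simulate_annotation(cfg)
        pools = default_pools(cfg.pools_per_cell)
        truth = pd.DataFrame(
            {p.name: (80.0 if p.timepoint == "Day0" else 15.0) for p in pools},
            index=ann.records["gene_id"],
        )
        expr, _ = simulate_expression(ann, truth, cfg)
        day0 = [p.name for p in pools if p.timepoint == "Day0"]
        later = [p.name for p in pools if p.timepoint != "Day0"]
        ratio = np.log2(expr.counts[later].mean(axis=1).mean()
                        / expr.counts[day0].mean(axis=1).mean())
        assert ratio == pytest.approx(-0.05 * (15 - 80), abs=0.05)

    def test_no_effect_without_coupling_or_de(self):
        cfg = SimConfig(seed=4, n_genes=50, coupling_fraction=0.0, de_fraction=0.0,
                        expr_dispersion=1e-14, depth_jitter=0.0,
                        baseline_log2_mean=15.0, baseline_log2_sd=0.0)
        ann = simulate_annotation(cfg)
        pools = default_pools(cfg.pools_per_cell)
        truth = pd.DataFrame(
            {p.name: (80.0 if p.timepoint == "Day0" else 15.0) for p in pools},
            index=ann.records["gene_id"],
        )
        expr, t = simulate_expression(ann, truth, cfg)
        assert t.de_genes.empty and not t.coupled_genes
        # near-Poisson at mean 2^15: all pools within a fraction of a percent
        cv = expr.counts.std(axis=1) / expr.counts.mean(axis=1)
        assert (cv < 0.02).all()

    def test_dataset_deterministic_under_seed(self, small_cfg, small_dataset):
        expr = small_dataset[2]
        expr2 = simulate_dataset(small_cfg)[2]
        pd.testing.assert_frame_equal(expr.counts, expr2.counts)
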