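"""Generate a joint WGBS + RNA-seq dataset and look at its structure.

The generator emulates a 2-genotype x 3-time-point feeding study with two
replicate pools per cell: CpG methylation follows a TSS-anchored profile
(high plateau upstream, ~15% trough just downstream of the TSS), expression
counts are negative-binomial, and truth tables record which genes were
perturbed.
"""

from promethyl import SimConfig, simulate_dataset

cfg = SimConfig(seed=1, n_genes=200)
annotation, cpg, expr, meth_truth, expr_truth = simulate_dataset(cfg)

print(f"genes: {len(annotation)} on one synthetic chromosome")
print(f"CpG sites: {len(cpg.sites)} across {len(cpg.pools)} pools")
print(f"mean coverage: {cpg.coverage.mean():.1f}x (configured {cfg.mean_coverage}x)")
print(f"expression matrix: {expr.counts.shape[0]} genes x {expr.counts.shape[1]} pools, "
      f"median count {expr.counts.median().median():.0f}")
print(f"truth: {len(meth_truth.dm_genes)} genes with a methylation shift, "
      f"{len(expr_truth.de_genes)} independent DE genes, "
      f"{len(expr_truth.coupled_genes)} methylation-coupled genes")
print("\nfirst shifted genes (region in bp relative to the TSS):")
print(meth_truth.dm_genes.head(3).to_string(index=False))
# Each row is a promoter stretch whose methylation moves by +/-30 points at
# the Day28/Day41 time points; the analysis should rediscover these.
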