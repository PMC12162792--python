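"""End-to-end orchestration: simulate -> filter/normalize -> DM -> DE ->
windows -> association -> report, as one reproducible run directory.

Every stage writes its outputs as TSV into the run directory; the run is a
pure function of the configuration (including the seed), so re-running with
the same config reproduces byte-identical tables.  A ``run.log`` records the
seed, thresholds and SHA-256 digests of the inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, expression, methylation, windows
from .io_formats import Design, default_design, write_annotation_bed, write_cpg_counts, write_expression, write_table
from .simulate import SimConfig, simulate_dataset

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("promethyl")


@dataclass
class RunConfig:
    """Configuration of one pipeline run over synthetic data."""

    out_dir: str
    sim: SimConfig = field(default_factory=SimConfig)
    window_sizes: tuple[float, ...] = (100.0, 50.0, 25.0, 12.5)
    min_coverage: int = 10
    q_cut_promoter: float = 0.01
    diff_cut: float = 25.0
    p_cut_window: float = 0.05
    fdr_cut_de: float = 0.05
    write_inputs: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage in dependency order; returns the run directory.

    A stage failure leaves the completed stages' outputs in place and an
    ``error_manifest.json`` naming the failed stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({"sim": asdict(config.sim),
                        **{k: v for k, v in asdict(config).items() if k != "sim"}}, fh)

    stage = "simulate"
    try:
        annotation, cpg, expr, meth_truth, expr_truth = simulate_dataset(config.sim)
        design = default_design(cpg.pools)
        design.min_coverage = config.min_coverage
        design.q_cut_promoter = config.q_cut_promoter
        design.diff_cut = config.diff_cut
        design.p_cut_window = config.p_cut_window
        design.fdr_cut_de = config.fdr_cut_de
        if config.write_inputs:
            write_annotation_bed(annotation, out / "annotation.bed")
            write_cpg_counts(cpg, out / "cpg_counts")
            write_expression(expr, out / "expression.tsv")
            write_table(meth_truth.dm_genes, out / "truth_dm_genes.tsv")
            write_table(expr_truth.de_genes, out / "truth_de_genes.tsv")
            pd.DataFrame({"gene_id": expr_truth.coupled_genes}).to_csv(
                out / "truth_coupled_genes.tsv", sep="\t", index=False)

        stage = "filter_normalize"
        filtered = methylation.filter_coverage(cpg, config.min_coverage)
        normalized = methylation.normalize_coverage(filtered)

        stage = "dm"
        dm_summaries = []
        for comp in design.comparisons:
            res = methylation.dm_test_table(normalized, comp)
            called = methylation.call_dm(res, q_cut=config.q_cut_promoter,
                                         diff_cut=config.diff_cut, mode="promoter")
            write_table(called, out / f"dm_cpg_{comp.label}.tsv")
            s = methylation.summarize_dm_calls(called)
            dm_summaries.append({"comparison": comp.label, **s})
        write_table(pd.DataFrame(dm_summaries), out / "dm_cpg_summary.tsv")

        stage = "de"
        total_transcripts = len(expr.gene_ids)
        kept = expression.filter_expressed(expr)
        kept.norm_factors = expression.tmm_factors(kept)
        _, tagwise = expression.estimate_dispersion(kept)
        de_by_comp = {}
        de_summaries = []
        for comp in design.comparisons:
            res = expression.de_test(kept, comp, tagwise_phi=tagwise,
                                     fdr_cut=config.fdr_cut_de)
            de_by_comp[comp.label] = res
            write_table(res, out / f"de_{comp.label}.tsv")
            s = expression.summarize_de(res, total_transcripts)
            de_summaries.append({"comparison": comp.label, **s})
        write_table(pd.DataFrame(de_summaries), out / "de_summary.tsv")

        stage = "windows"
        prom_agg = windows.aggregate_window_counts(normalized, annotation, "promoter")
        agg_by_size = {s: windows.aggregate_window_counts(normalized, annotation, s)
                       for s in config.window_sizes}
        prom_summaries, window_summaries = [], []
        window_dm_by = {}
        prom_dm_by = {}
        for comp in design.comparisons:
            called = windows.window_dm(prom_agg, comp, normalized.pools, mode="promoter",
                                       q_cut=config.q_cut_promoter, diff_cut=config.diff_cut)
            prom_dm_by[comp.label] = called
            write_table(called, out / f"dm_promoter_{comp.label}.tsv")
            prom_summaries.append({"comparison": comp.label,
                                   **methylation.summarize_dm_calls(called)})
            for size in config.window_sizes:
                wres = windows.window_dm(agg_by_size[size], comp, normalized.pools,
                                         mode="window", p_cut=config.p_cut_window)
                window_dm_by[(comp.label, size)] = wres
                write_table(wres, out / f"dm_windows_{size:g}_{comp.label}.tsv")
                profile = windows.positional_dmr_profile(wres)
                write_table(profile, out / f"dmr_profile_{size:g}_{comp.label}.tsv")
                window_summaries.append({"comparison": comp.label, "size": size,
                                         **methylation.summarize_dm_calls(wres)})
        write_table(pd.DataFrame(prom_summaries), out / "dm_promoter_summary.tsv")
        write_table(pd.DataFrame(window_summaries), out / "dm_windows_summary.tsv")

        stage = "associate"
        fed_nt = [i for i, p in enumerate(normalized.pools)
                  if p.genotype == "non_transgenic" and p.timepoint == "Day0"]
        curve = association.metaplot(normalized, annotation, pool_indices=fed_nt, smooth=True)
        write_table(curve, out / "metaplot.tsv")

        lcpm = expression.log_cpm(kept)
        prom_pct = _promoter_percent(prom_agg, normalized, fed_nt)
        static = association.static_association(
            prom_pct, lcpm.iloc[:, fed_nt].mean(axis=1))
        write_table(static["density"], out / "static_association_density.tsv")
        static_row = {k: v for k, v in static.items() if k != "density"}
        write_table(pd.DataFrame([static_row]), out / "static_association.tsv")

        overlap_rows = []
        delta_frames = []
        for comp in design.comparisons:
            ov = association.overlap_deg_dmr(de_by_comp[comp.label], prom_dm_by[comp.label])
            overlap_rows.append({"comparison": comp.label,
                                 "overlap_count": ov["overlap_count"],
                                 "deg_count": ov["deg_count"],
                                 "dmr_gene_count": ov["dmr_gene_count"]})
            w100 = window_dm_by[(comp.label, config.window_sizes[0])]
            delta = association.delta_association(
                w100[["gene_id", "rel_start", "meth_diff"]], de_by_comp[comp.label])
            delta["comparison"] = comp.label
            delta_frames.append(delta)
        write_table(pd.DataFrame(overlap_rows), out / "overlap_summary.tsv")
        write_table(pd.concat(delta_frames, ignore_index=True), out / "delta_association.tsv")

        stage = "report"
        _write_report(out, dm_summaries, de_summaries, prom_summaries, overlap_rows,
                      static_row, total_transcripts)
    except Exception as exc:
        with open(out / "error_manifest.json", "w") as fh:
            json.dump({"stage": stage, "error": str(exc)}, fh, indent=2)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    digests = {p.name: _digest(p) for p in sorted(out.glob("*.tsv"))}
    with open(out / "run.log", "w") as fh:
        fh.write(f"seed\t{config.sim.seed}\n")
        fh.write(f"min_coverage\t{config.min_coverage}\n")
        fh.write(f"q_cut_promoter\t{config.q_cut_promoter}\n")
        fh.write(f"diff_cut\t{config.diff_cut}\n")
        fh.write(f"p_cut_window\t{config.p_cut_window}\n")
        fh.write(f"fdr_cut_de\t{config.fdr_cut_de}\n")
        fh.write(f"elapsed_s\t{time.time() - t0:.1f}\n")
        for name, d in digests.items():
            fh.write(f"sha256:{name}\t{d}\n")
    logger.info("pipeline finished in %.1fs -> %s", time.time() - t0, out)
    return out


def _promoter_percent(prom_agg: pd.DataFrame, table, pool_indices) -> pd.Series:
    """Coverage-pooled promoter methylation percent per gene over given pools."""
    names = [table.pools[i].name for i in pool_indices]
    meth = sum(prom_agg[f"meth_{n}"] for n in names)
    cov = meth + sum(prom_agg[f"unmeth_{n}"] for n in names)
    pct = 100.0 * meth / cov.where(cov > 0)
    return pd.Series(pct.to_numpy(), index=prom_agg["gene_id"].to_numpy())


def _write_report(out: Path, dm_sum, de_sum, prom_sum, overlap_rows, static_row,
                  total_transcripts) -> None:
    ratios = association.derived_ratios(
        pd.DataFrame(de_sum), pd.DataFrame(dm_sum), pd.DataFrame(prom_sum),
        pd.DataFrame(overlap_rows), total_transcripts)
    write_table(ratios, out / "derived_ratios.tsv")
    lines = ["# Run report", "",
             f"Transcripts assayed: {total_transcripts}", "",
             "## Differential expression (down, up, % of transcripts)", ""]
    for r in de_sum:
        lines.append(f"- {r['comparison']}: {r['down_count']} ({r['down_pct']}%), "
                     f"{r['up_count']} ({r['up_pct']}%)")
    lines += ["", "## Differentially methylated CpGs (total, hypo, hyper)", ""]
    for r in dm_sum:
        lines.append(f"- {r['comparison']}: {r['total']}, {r['hypo']}, {r['hyper']}")
    lines += ["", "## Differentially methylated promoters (hypo, hyper)", ""]
    for r in prom_sum:
        lines.append(f"- {r['comparison']}: {r['hypo']}, {r['hyper']}")
    lines += ["", "## DEG-DMR overlap (promoter mode)", ""]
    for r in overlap_rows:
        lines.append(f"- {r['comparison']}: {r['overlap_count']} of {r['deg_count']} DEGs")
    lines += ["", "## Static association",
              "",
              f"slope={static_row['slope']:.4f} log2CPM per methylation point, "
              f"p={static_row['p_value']:.3g}, n={static_row['n']}"]
    (out / "report.md").write_text("\n".join(lines) + "\n")
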