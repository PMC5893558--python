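"""End-to-end conjunction-FDR pipeline: read -> harmonize -> inflation ->
enrichment -> cFDR/conjunction -> clump -> annotate -> plot.

Stage order is fixed; every stage logs its SNP attrition and all artifacts
land in one run directory together with a metadata JSON sufficient to
reproduce the run (config, seed, lambda estimates, SNP counts).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cfdr import CfdrConfig, build_lookup_grid, run_conjunction
from .enrichment import fold_enrichment, plot_conjunction_manhattan, plot_enrichment
from .inflation import correct_panel
from .loci import assign_blocks, lead_report, lead_snps, read_gene_annotation
from .sumstats import harmonize, read_sumstats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    trait_files: list = field(default_factory=list)     # [(path, trait_name), ...]
    column_maps: list | None = None
    out_dir: str = "conjfdr_run"
    strata: tuple = (1.0, 0.1, 0.01, 0.001)
    grid_size: int = 101
    fdr_threshold: float = 0.05
    min_stratum_size: int = 100
    inflation_correction: bool = True
    inflation_subset_file: str | None = None
    block_method: str = "window"
    window_bp: int = 250_000
    r2_threshold: float = 0.2
    ld_table_file: str | None = None
    gene_annotation_file: str | None = None
    enrichment_strata_neglog: tuple = (0.0, 1.0, 2.0)
    pruning_r: int = 0
    seed: int = 0

    def validate(self):
        if len(self.trait_files) < 2:
            raise ValueError("need >= 2 trait files")
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must be in (0, 1]")
        return self

    def cfdr_config(self) -> CfdrConfig:
        return CfdrConfig(strata=tuple(self.strata), grid_size=self.grid_size,
                          fdr_threshold=self.fdr_threshold,
                          min_stratum_size=self.min_stratum_size,
                          pruning_r=self.pruning_r, pruning_seed=self.seed)


def _stage(name):
    logger.info("=== stage: %s ===", name)


def cmd_run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a dict of artifact paths."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"version": __version__, "seed": config.seed,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config).items()}}
    meta["config_hash"] = hashlib.sha256(
        json.dumps(meta["config"], sort_keys=True).encode()).hexdigest()[:16]
    artifacts = {}

    _stage("read")
    tables = []
    for i, (path, name) in enumerate(config.trait_files):
        cmap = config.column_maps[i] if config.column_maps else None
        t = read_sumstats(path, column_map=cmap, trait_name=name)
        logger.info("trait %s: %d SNPs (%d dropped)", name, len(t), t.n_dropped)
        tables.append(t)
    meta["n_snps_per_trait"] = {t.trait_name: len(t) for t in tables}

    _stage("harmonize")
    try:
        panel = harmonize(tables)
    except ValueError as e:
        raise RuntimeError(f"stage harmonize: {e}") from e
    meta["harmonize"] = panel.log

    _stage("inflation")
    if config.inflation_correction:
        mask = None
        if config.inflation_subset_file:
            keep = set(Path(config.inflation_subset_file).read_text().split())
            mask = np.array([s in keep for s in panel.snp_ids])
        ests = correct_panel(panel, mask)
        meta["lambda_gc"] = {n: e.lambda_gc for n, e in zip(panel.trait_names, ests)}
    panel_path = out / "harmonized_panel.tsv"
    panel.write_tsv(panel_path)
    artifacts["panel"] = str(panel_path)

    ta, tb = panel.trait_names[0], panel.trait_names[1]
    pa = panel.p[:, 0]
    pb = panel.p[:, 1]

    _stage("enrichment")
    curve = fold_enrichment(pa, pb, strata=config.enrichment_strata_neglog)
    curve_path = out / f"enrichment_{ta}_given_{tb}.tsv"
    curve.to_frame().to_csv(curve_path, sep="\t", index=False, float_format="%.6g")
    artifacts["enrichment_tsv"] = str(curve_path)
    for ext in ("png", "svg"):
        p = out / f"enrichment_{ta}_given_{tb}.{ext}"
        plot_enrichment(curve, p)
        artifacts[f"enrichment_{ext}"] = str(p)

    _stage("cfdr/conjunction")
    cconf = config.cfdr_config()
    blocks = None
    if config.pruning_r > 0 or config.block_method == "r2_graph":
        ld = None
        if config.ld_table_file:
            import pandas as pd
            ld = pd.read_csv(config.ld_table_file, sep="\t")
        blocks = assign_blocks(panel.snp_ids, panel.chrom, panel.pos, ld_table=ld,
                               method=config.block_method, window_bp=config.window_bp,
                               r2_threshold=config.r2_threshold)
    results = run_conjunction(panel, ta, tb, cconf, blocks=blocks)
    grid = build_lookup_grid(pa, pb, cconf)
    grid.to_frame().to_csv(out / "cfdr_lookup_grid.tsv", sep="\t", index=False,
                           float_format="%.6g")
    meta["n_significant"] = int(results["significant"].sum())

    _stage("clump")
    if blocks is None:
        blocks = assign_blocks(panel.snp_ids, panel.chrom, panel.pos,
                               method=config.block_method, window_bp=config.window_bp)
    leads = lead_snps(results, blocks)
    results["lead"] = leads
    res_path = out / f"conjunction_{ta}_{tb}.tsv"
    results.to_csv(res_path, sep="\t", index=False, float_format="%.6g")
    artifacts["conjunction_tsv"] = str(res_path)
    meta["n_leads"] = int(leads.sum())

    _stage("annotate")
    genes = read_gene_annotation(config.gene_annotation_file) \
        if config.gene_annotation_file else None
    report = lead_report(results, leads, genes, panel)
    report_path = out / "lead_snps.tsv"
    report.to_csv(report_path, sep="\t", index=False, float_format="%.6g")
    artifacts["lead_snps"] = str(report_path)

    _stage("plot")
    ann = {r["rsid"]: r["gene"] for _, r in report.iterrows()} if len(report) else None
    for ext in ("png", "svg"):
        p = out / f"manhattan_{ta}_{tb}.{ext}"
        plot_conjunction_manhattan(results, leads, ann, p, config.fdr_threshold)
        artifacts[f"manhattan_{ext}"] = str(p)

    meta_path = out / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    artifacts["metadata"] = str(meta_path)
    return artifacts
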