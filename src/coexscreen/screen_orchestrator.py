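"""End-to-end screen: which co-expression modules are simultaneously
associated with differential expression, unique CpG methylation, and
chromosomal instability.

The pipeline runs gene filtering, network construction (soft threshold,
TOM, tree cut, module merging, eigengenes, kME), cell-composition
deconvolution, differential methylation, the covariate-adjusted
eigengene-CpG screen, the chromosomal-instability index and its eigengene
regression, and GSEA of each module's gene set against the tumor/normal
ranking. A module is *selected* when all three criteria hold:

1. its gene set is enriched in the configured direction of the
   tumor/normal ranking at ``gsea_fdr_max`` (default: enriched among
   tumor-down genes),
2. at least ``min_unique_dm_cpgs`` differentially methylated CpGs are
   uniquely assigned to it by the screen, and
3. its eigengene predicts the instability index at ``cin_fdr_max``.

Given a seed the run is deterministic; every written table carries the
configuration hash in a provenance header line.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import coexpression as cx
from . import cnv_instability as cnv
from . import deconvolution as dc
from . import enrichment as enr
from . import methylation_screen as ms
from .io_formats import (
    BetaMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    GenomeModel,
    SampleTable,
    SegmentTable,
)

logger = logging.getLogger("coexscreen")

__all__ = ["ScreenParams", "ScreenReport", "run_screen", "report_hubs",
           "match_modules"]


@dataclass
class ScreenParams:
    """Tunable thresholds of every stage plus the selection rule."""

    # network
    min_module_size: int = 30
    cut_height: float = 0.995
    deep_split: int = 2
    merge_cut: float = 0.25
    scale_free_target_r2: float = 0.8
    # methylation
    dm_delta_beta: float = 0.2
    dm_fdr: float = 0.05
    screen_alpha: float = 0.05
    adjust_composition: bool = True
    # cnv
    cnv_threshold: float = 0.3
    # gsea
    gsea_weight_p: float = 1.0
    gsea_n_perm: int = 1000
    # selection rule
    gsea_fdr_max: float = 0.05
    gsea_direction: str = "down"  # down | up | either
    min_unique_dm_cpgs: int = 10
    cin_fdr_max: float = 0.05
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ScreenReport:
    per_cluster: pd.DataFrame      # one row per module with all three criteria
    selected: list[int]
    modules: cx.ModuleAssignment
    eigengenes: cx.EigengeneMatrix
    kme: pd.DataFrame
    proportions: dc.ProportionTable
    dm: pd.DataFrame
    cpg_assocs: pd.DataFrame
    cin: pd.Series
    cin_assocs: pd.DataFrame
    gsea_results: list[enr.GseaResult]
    ranking: enr.RankedList
    config_hash: str
    seed: int
    warnings: list[str] = field(default_factory=list)


def _stage(name: str):
    logger.info("stage=%s", name)
    return time.perf_counter()


def run_screen(expr: ExpressionMatrix, betas: BetaMatrix, segments: SegmentTable,
               samples: SampleTable, reference: ExpressionMatrix,
               reference_labels: pd.Series, genome: GenomeModel,
               params: ScreenParams | None = None) -> ScreenReport:
    """Run the full screen on aligned input layers.

    All layers are matched by sample id; at least 20 samples must be
    shared between expression, methylation and the sample table.
    """
    params = params or ScreenParams()
    t0 = time.perf_counter()
    shared = [s for s in samples.sample_ids
              if s in expr.data.columns and s in betas.data.columns]
    if len(shared) < 20:
        raise ValueError(f"only {len(shared)} samples shared across layers; need >= 20")
    warnings_log: list[str] = []

    t = _stage("filter_genes")
    filtered = cx.filter_genes(expr, samples)
    logger.info("filter_genes kept %d/%d genes (%.2fs)",
                len(filtered.gene_ids), len(expr.gene_ids), time.perf_counter() - t)

    t = _stage("network")
    logx = cx.log_transform(filtered)
    sft = cx.pick_soft_threshold(logx, target_r2=params.scale_free_target_r2)
    adj = cx.adjacency_from_expression(logx, sft.chosen_power)
    tom = cx.compute_tom(adj)
    modules = cx.cut_modules(tom, filtered.gene_ids,
                             min_module_size=params.min_module_size,
                             cut_height=params.cut_height,
                             deep_split=params.deep_split)
    if len(modules.module_ids) < 2:
        warnings_log.append("fewer than 2 modules found; selection skipped")
        logger.warning("fewer than 2 modules found; selection skipped")
        empty = pd.DataFrame()
        return ScreenReport(empty, [], modules,
                            cx.EigengeneMatrix(pd.DataFrame(index=filtered.sample_ids)),
                            pd.DataFrame(), _uniform_proportions(samples), pd.DataFrame(),
                            pd.DataFrame(), pd.Series(dtype=float), pd.DataFrame(), [],
                            enr.RankedList(pd.DataFrame(columns=["gene_id", "stat"])),
                            params.config_hash(), params.seed, warnings_log)
    eigengenes = cx.compute_eigengenes(filtered, modules)
    modules, eigengenes = cx.merge_close_modules(filtered, modules, eigengenes,
                                                 merge_cut=params.merge_cut)
    kme = cx.module_membership(filtered, eigengenes)
    logger.info("network: power=%g, %d modules (%.2fs)", sft.chosen_power,
                len(modules.module_ids), time.perf_counter() - t)

    t = _stage("deconvolution")
    signature = dc.build_signature(reference, reference_labels,
                                   bulk_genes=expr.gene_ids)
    proportions = dc.estimate_proportions(expr, signature)
    logger.info("deconvolution done (%.2fs)", time.perf_counter() - t)

    t = _stage("methylation_screen")
    dm = ms.differential_methylation(betas, samples)
    dm_cpgs = list(dm.cpg_id[dm.passes])
    if dm_cpgs:
        dm_betas = BetaMatrix(betas.data.loc[dm_cpgs])
        assocs = ms.associate_cpgs(
            eigengenes, dm_betas,
            proportions if params.adjust_composition else None,
            alpha=params.screen_alpha)
        assocs = ms.attach_direction(assocs, dm) if len(assocs) else assocs
    else:
        assocs = pd.DataFrame(columns=["cpg_id", "cluster", "b", "p", "fdr", "direction"])
    logger.info("methylation: %d DM CpGs, %d assigned (%.2fs)",
                len(dm_cpgs), len(assocs), time.perf_counter() - t)

    t = _stage("cnv_instability")
    altered = cnv.call_altered(segments, threshold=params.cnv_threshold)
    cin = cnv.cin_index(altered, genome, sample_ids=eigengenes.data.index.tolist())
    cin_assocs = cnv.associate_cin(cin, eigengenes, proportions)
    logger.info("cin computed for %d samples (%.2fs)", len(cin), time.perf_counter() - t)

    t = _stage("gsea")
    ranking = enr.rank_genes(expr, samples)
    cluster_sets = GeneSetCollection(modules.as_sets())
    gsea_results = enr.gsea(ranking, cluster_sets, weight_p=params.gsea_weight_p,
                            n_perm=params.gsea_n_perm, seed=params.seed)
    logger.info("gsea on %d sets (%.2fs)", len(gsea_results), time.perf_counter() - t)

    rows = []
    gsea_by_module = {int(r.set_name.split("_")[1]): r for r in gsea_results}
    sizes = modules.sizes()
    for m in modules.module_ids:
        g = gsea_by_module[m]
        sub = assocs[assocs.cluster == m] if len(assocs) else assocs
        n_cpg = len(sub)
        hyper = float((sub.direction > 0).mean()) if n_cpg else np.nan
        cin_row = cin_assocs[cin_assocs.cluster == m].iloc[0]
        if params.gsea_direction == "down":
            direction_ok = g.es < 0
        elif params.gsea_direction == "up":
            direction_ok = g.es > 0
        else:
            direction_ok = True
        crit_gsea = bool(g.fdr < params.gsea_fdr_max and direction_ok)
        crit_cpg = bool(n_cpg >= params.min_unique_dm_cpgs)
        crit_cin = bool(cin_row.fdr < params.cin_fdr_max)
        rows.append({
            "cluster": m, "size": sizes[m],
            "gsea_es": g.es, "gsea_nes": g.nes, "gsea_fdr": g.fdr,
            "n_unique_dm_cpgs": n_cpg, "hypermethylated_fraction": hyper,
            "cin_slope": cin_row.slope, "cin_p": cin_row.p, "cin_fdr": cin_row.fdr,
            "crit_gsea": crit_gsea, "crit_cpg": crit_cpg, "crit_cin": crit_cin,
            "selected": crit_gsea and crit_cpg and crit_cin,
        })
    per_cluster = pd.DataFrame(rows)
    selected = [int(r.cluster) for r in per_cluster.itertuples() if r.selected]
    logger.info("screen complete: %d/%d modules selected (%.2fs total)",
                len(selected), len(per_cluster), time.perf_counter() - t0)
    return ScreenReport(per_cluster, selected, modules, eigengenes, kme, proportions,
                        dm, assocs, cin, cin_assocs, gsea_results, ranking,
                        params.config_hash(), params.seed, warnings_log)


def _uniform_proportions(samples: SampleTable) -> dc.ProportionTable:
    n = len(samples.sample_ids)
    data = pd.DataFrame(np.full((n, 3), 1 / 3),
                        index=pd.Index(samples.sample_ids, name="sample_id"),
                        columns=["basal", "luminal", "stromal"])
    return dc.ProportionTable(data)


def report_hubs(report: ScreenReport, k: int = 5) -> dict[int, pd.DataFrame]:
    """Top-k hub genes (by kME, ties lexicographic) per selected module."""
    return {m: cx.hub_genes(report.kme, report.modules, m, k=k)
            for m in report.selected}


def match_modules(detected: cx.ModuleAssignment, truth: pd.Series) -> dict[int, int]:
    """Map each detected module to the planted module with maximal Jaccard overlap."""
    mapping = {}
    for m in detected.module_ids:
        genes = set(detected.genes_in(m))
        best, best_j = 0, 0.0
        for t in sorted(set(truth) - {0}):
            tgenes = set(truth.index[truth == t])
            j = len(genes & tgenes) / len(genes | tgenes)
            if j > best_j:
                best, best_j = t, j
        mapping[m] = best
    return mapping


def write_report(report: ScreenReport, outdir: str | Path) -> None:
    """Write the per-cluster report and all intermediate tables as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# coexscreen config_hash={report.config_hash} seed={report.seed}\n"

    def _write(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=index)

    _write(report.per_cluster, "screen_report.tsv")
    _write(report.modules.labels.to_frame(), "modules.tsv", index=True)
    _write(report.eigengenes.data, "eigengenes.tsv", index=True)
    _write(report.kme, "kme.tsv", index=True)
    _write(report.proportions.data, "proportions.tsv", index=True)
    _write(report.dm, "differential_methylation.tsv")
    _write(report.cpg_assocs, "cpg_associations.tsv")
    _write(report.cin.to_frame(), "cin.tsv", index=True)
    _write(report.cin_assocs, "cin_associations.tsv")
    gsea_df = pd.DataFrame([{
        "set": r.set_name, "es": r.es, "nes": r.nes, "p": r.p, "fdr": r.fdr,
        "size": r.size, "leading_edge": ",".join(r.leading_edge),
    } for r in report.gsea_results])
    _write(gsea_df, "gsea.tsv")
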