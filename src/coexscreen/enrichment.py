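"""Gene-set and genomic-interval enrichment layers.

* ``rank_genes`` — Welch t ranking of genes tumor vs normal on
  log2(TPM+1), with logFC and BH FDR so the conventional differential-
  expression gate (|logFC| > 0.5, FDR < 0.05) can be applied by callers.
* ``gsea`` — weighted Kolmogorov-Smirnov running-sum enrichment score
  with a seeded gene-label permutation null, NES and BH FDR.
* ``fisher_overlap`` — two-sided Fisher exact test of two sets within a
  universe, with a Haldane 0.5 correction applied to the odds ratio only
  when a cell is zero.
* ``overlap_cpgs`` / ``classify_context`` — half-open point-in-interval
  overlap of CpGs against interval sets, and promoter/distal labelling by
  distance to the nearest TSS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CpGMap, ExpressionMatrix, GeneSetCollection, IntervalSet, SampleTable

__all__ = [
    "RankedList",
    "GseaResult",
    "FisherResult",
    "rank_genes",
    "enrichment_score",
    "gsea",
    "fisher_overlap",
    "overlap_cpgs",
    "classify_context",
]


@dataclass
class RankedList:
    """Genes sorted by a signed statistic, descending; ties broken by gene id."""

    table: pd.DataFrame  # columns gene_id, stat [, log_fc, p, fdr]; sorted

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.gene_id)

    @property
    def stats(self) -> np.ndarray:
        return self.table.stat.to_numpy(dtype=float)


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p: float
    fdr: float
    leading_edge: list[str] = field(default_factory=list)
    size: int = 0


@dataclass
class FisherResult:
    a: int  # |A ∩ B|
    b: int  # |A \ B|
    c: int  # |B \ A|
    d: int  # |universe \ (A ∪ B)|
    odds_ratio: float
    p: float
    or_corrected: bool = False

    @property
    def table(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def rank_genes(expr: ExpressionMatrix, samples: SampleTable) -> RankedList:
    """Welch t statistic of log2(TPM+1), tumor vs normal, sorted descending."""
    tumor_ids = [s for s in samples.ids_for("tumor") if s in expr.data.columns]
    normal_ids = [s for s in samples.ids_for("normal") if s in expr.data.columns]
    if len(tumor_ids) < 2 or len(normal_ids) < 2:
        raise ValueError("need >= 2 samples per condition to rank genes")
    logx = np.log2(expr.data + 1.0)
    t_vals = logx[tumor_ids].to_numpy(dtype=float)
    n_vals = logx[normal_ids].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p = stats.ttest_ind(t_vals, n_vals, axis=1, equal_var=False)
    t_stat = np.nan_to_num(t_stat, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    log_fc = t_vals.mean(axis=1) - n_vals.mean(axis=1)
    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({
        "gene_id": expr.gene_ids, "stat": t_stat, "log_fc": log_fc, "p": p, "fdr": fdr,
    })
    table = table.sort_values(["stat", "gene_id"], ascending=[False, True],
                              kind="stable").reset_index(drop=True)
    return RankedList(table)


def _es_from_hits(hit: np.ndarray, weights: np.ndarray) -> tuple[float, int]:
    N = len(hit)
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == N:
        raise ValueError("gene set must hit some but not all of the ranking")
    w_hit = np.where(hit, weights, 0.0)
    total = w_hit.sum()
    if total == 0:  # all hit weights zero: fall back to equal steps
        w_hit = hit.astype(float)
        total = float(n_hit)
    steps = np.where(hit, w_hit / total, -1.0 / (N - n_hit))
    running = np.cumsum(steps)
    pos = int(np.argmax(np.abs(running)))
    return float(running[pos]), pos


def enrichment_score(ranked_ids: list[str], ranked_stats: np.ndarray,
                     members: set[str], weight_p: float = 1.0) -> tuple[float, int]:
    """Weighted KS running-sum enrichment score of a set in a ranking.

    Hits increment by |stat|^weight_p normalised to sum 1 over hits (equal
    steps when all hit weights are 0), misses decrement by 1/(N - Nh);
    returns (maximum deviation from zero, position of the extremum).
    """
    N = len(ranked_ids)
    hit = np.fromiter((g in members for g in ranked_ids), dtype=bool, count=N)
    w = np.abs(np.asarray(ranked_stats, dtype=float)) ** weight_p
    return _es_from_hits(hit, w)


def gsea(ranking: RankedList, sets: GeneSetCollection, weight_p: float = 1.0,
         n_perm: int = 1000, seed: int = 0) -> list[GseaResult]:
    """Permutation GSEA of each gene set against the ranking.

    The null redraws each set's positions uniformly from the ranking
    (gene-label permutation). NES = ES / mean |null ES| of the matching
    sign; the nominal p is the add-one-corrected fraction of same-sign
    null scores at least as extreme. FDR is BH across sets.
    """
    rng = np.random.default_rng(seed)
    ids = ranking.gene_ids
    universe = set(ids)
    stats_vec = ranking.stats
    N = len(ids)
    results = []
    for name in sets:
        members = set(sets[name])
        missing = sorted(members - universe)
        if missing:
            raise ValueError(f"gene set {name!r} has members outside the ranking: "
                             f"{missing[:10]}")
        es, pos = enrichment_score(ids, stats_vec, members, weight_p)
        n_hit = len(members)
        weights = np.abs(stats_vec) ** weight_p
        null_es = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.choice(N, size=n_hit, replace=False)
            null_hit = np.zeros(N, dtype=bool)
            null_hit[perm] = True
            null_es[b], _ = _es_from_hits(null_hit, weights)
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        if len(same_sign) == 0:
            p = 1.0 / (n_perm + 1)
            nes = 0.0
        else:
            p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + len(same_sign))
            denom = np.abs(same_sign).mean()
            nes = es / denom if denom > 0 else 0.0
        hit_positions = [i for i, g in enumerate(ids) if g in members]
        if es >= 0:
            leading = [ids[i] for i in hit_positions if i <= pos]
        else:
            leading = [ids[i] for i in hit_positions if i >= pos]
        results.append(GseaResult(name, es, nes, p, np.nan, leading, n_hit))
    fdrs = multipletests([r.p for r in results], method="fdr_bh")[1]
    for r, f in zip(results, fdrs):
        r.fdr = float(f)
    return results


def fisher_overlap(set_a, set_b, universe) -> FisherResult:
    """Two-sided Fisher exact test of the overlap of two sets in a universe."""
    A, B, U = set(set_a), set(set_b), set(universe)
    outside = (A | B) - U
    if outside:
        raise ValueError(f"elements outside the universe: {sorted(outside)[:10]}")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(U - (A | B))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = min(a, b, c, d) == 0
    if corrected:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return FisherResult(a, b, c, d, float(odds), float(p), corrected)


def overlap_cpgs(cpgs: CpGMap, intervals: IntervalSet,
                 foreground: list[str] | None = None,
                 background: list[str] | None = None
                 ) -> tuple[pd.Series, FisherResult | None]:
    """Half-open overlap of CpG positions with an interval set.

    A CpG at position p overlaps [s, e) iff s <= p < e. When a foreground
    subset and a background universe of CpG ids are supplied, also returns
    the Fisher enrichment of overlapping foreground CpGs against the
    background.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in intervals.data.itertuples():
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    starts_ends = {
        c: (np.array([s for s, _ in ivs]), np.array([e for _, e in ivs]))
        for c, ivs in by_chrom.items()
    }
    flags = {}
    warned = False
    for r in cpgs.data.itertuples():
        if r.chrom not in starts_ends:
            if not warned and r.chrom not in by_chrom:
                warnings.warn(f"CpG chromosome {r.chrom!r} absent from interval set; "
                              "counting as non-overlapping", stacklevel=2)
                warned = True
            flags[r.cpg_id] = False
            continue
        s, e = starts_ends[r.chrom]
        flags[r.cpg_id] = bool(np.any((s <= r.pos) & (r.pos < e)))
    overlap = pd.Series(flags, name="overlaps")
    fisher = None
    if foreground is not None:
        bg = background if background is not None else cpgs.cpg_ids
        overlapping = [c for c in bg if overlap.get(c, False)]
        fisher = fisher_overlap(overlapping, foreground, bg)
    return overlap, fisher


def classify_context(cpgs: CpGMap, tss: IntervalSet,
                     promoter_window: int = 2000) -> pd.Series:
    """Label each CpG promoter/distal by distance to the nearest TSS.

    TSS are supplied as 1-bp intervals; a CpG is ``promoter`` when
    |pos - tss| <= promoter_window for some TSS on the same chromosome,
    ``distal`` otherwise (including CpGs on TSS-free chromosomes).
    """
    if len(tss) == 0:
        raise ValueError("empty TSS set")
    tss_by_chrom: dict[str, np.ndarray] = {}
    for r in tss.data.itertuples():
        tss_by_chrom.setdefault(r.chrom, []).append(r.start)
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}
    labels = {}
    for r in cpgs.data.itertuples():
        positions = tss_by_chrom.get(r.chrom)
        if positions is None:
            labels[r.cpg_id] = "distal"
            continue
        dist = np.min(np.abs(positions - r.pos))
        labels[r.cpg_id] = "promoter" if dist <= promoter_window else "distal"
    return pd.Series(labels, name="context")
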