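"""Chromosomal instability index from copy-number segments, and its
association with module eigengenes.

A region counts as copy-number altered when |log2 intensity ratio| strictly
exceeds a threshold (default 0.3). The per-sample chromosomal instability
index (CIN) is the fraction of each chromosome covered by the union of that
sample's altered segments, averaged with equal weight over every chromosome
in the genome model; chromosomes without altered segments contribute 0, so
CIN lies in [0, 1]. Overlapping altered segments are unioned before length
summation — raw length sums could exceed the chromosome with re-segmented
input.

Each module eigengene is then tested against CIN with ordinary least
squares, CIN ~ EG_i + composition covariates, with a two-sided t test on
the eigengene slope and Benjamini-Hochberg correction across modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coexpression import EigengeneMatrix
from .deconvolution import ProportionTable
from .io_formats import GenomeModel, SegmentTable

__all__ = ["CINAssociation", "call_altered", "cin_index", "union_length", "associate_cin"]


@dataclass
class CINAssociation:
    cluster: int
    slope: float
    p: float
    fdr: float = np.nan


def call_altered(segments: SegmentTable, threshold: float = 0.3) -> SegmentTable:
    """Keep segments whose |log2ratio| strictly exceeds ``threshold``."""
    mask = segments.data.log2ratio.abs() > threshold
    return SegmentTable(segments.data[mask].reset_index(drop=True))


def union_length(starts: np.ndarray, ends: np.ndarray) -> int:
    """Total bp covered by the union of half-open intervals."""
    if len(starts) == 0:
        return 0
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    total, cur_s, cur_e = 0, s[0], e[0]
    for i in range(1, len(s)):
        if s[i] > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s[i], e[i]
        else:
            cur_e = max(cur_e, e[i])
    total += cur_e - cur_s
    return int(total)


def cin_index(altered: SegmentTable, genome: GenomeModel,
              sample_ids: list[str] | None = None) -> pd.Series:
    """Per-sample chromosomal instability index.

    ``sample_ids`` optionally fixes the output index (samples without
    segments get CIN 0); otherwise samples present in the table are used.
    """
    altered.validate_against(genome)
    chroms = genome.chroms
    if sample_ids is None:
        sample_ids = sorted(set(altered.data.sample_id))
    cin = pd.Series(0.0, index=pd.Index(sample_ids, name="sample_id"), name="cin")
    grouped = altered.data.groupby(["sample_id", "chrom"], sort=False)
    fractions: dict[str, dict[str, float]] = {s: {} for s in sample_ids}
    for (sample, chrom), grp in grouped:
        if sample not in fractions:
            continue
        covered = union_length(grp.start.to_numpy(), grp.end.to_numpy())
        fractions[sample][chrom] = covered / genome[chrom]
    for sample in sample_ids:
        per_chrom = [fractions[sample].get(c, 0.0) for c in chroms]
        cin[sample] = float(np.mean(per_chrom))
    return cin


def associate_cin(cin: pd.Series, eigengenes: EigengeneMatrix,
                  proportions: ProportionTable) -> pd.DataFrame:
    """OLS of CIN on each eigengene with composition covariates.

    Model per module i: CIN = a_i + b_i*EG_i + composition + error, with
    the first T-1 of T proportion columns as composition covariates.
    Returns one row per module with slope, two-sided t p-value on the
    slope, and BH FDR across modules.
    """
    samples = list(eigengenes.data.index)
    missing = [s for s in samples if s not in cin.index or s not in proportions.data.index]
    if missing:
        raise ValueError(f"samples missing from CIN or proportions: {missing[:5]}")
    y = cin.loc[samples].to_numpy(dtype=float)
    comp = proportions.design_columns().loc[samples].to_numpy(dtype=float)
    n = len(samples)
    rows = []
    for m in eigengenes.module_ids:
        eg = eigengenes.eigengene(m).to_numpy(dtype=float)
        X = np.column_stack([np.ones(n), eg, comp])
        if n <= X.shape[1] + 2:
            raise ValueError("too few samples for the CIN regression design")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient CIN design for module {m}")
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        df = n - X.shape[1]
        sigma2 = resid @ resid / df
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(sigma2 * xtx_inv[1, 1])
        if se == 0:
            t_stat = np.inf if coef[1] != 0 else 0.0
            p = 0.0 if coef[1] != 0 else 1.0
        else:
            t_stat = coef[1] / se
            p = 2.0 * stats.t.sf(abs(t_stat), df)
        rows.append({"cluster": m, "slope": coef[1], "t": t_stat, "p": p})
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out.p, method="fdr_bh")[1]
    return out
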