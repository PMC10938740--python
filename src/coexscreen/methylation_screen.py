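"""Differential methylation and the eigengene-CpG association screen.

Differential methylation between tumor and normal samples is called on
beta values with a moderated two-sample t test: the per-CpG pooled
variance is shrunk toward the cross-CpG mean variance with a fixed prior
strength (posterior variance (d0*s0^2 + d*s^2)/(d0 + d), d0 = 4), and a
CpG passes when |delta beta| > 0.2 and BH FDR < 0.05.

The screen then regresses each module eigengene on each differentially
methylated CpG,

    EG_i = a_i + b_i * CpG_j + Cov + err,

where Cov holds the cell-composition proportions (first T-1 of T types)
and the eigengenes of every other module. Adjusting for the remaining
eigengenes makes a surviving association unique to its module; adjusting
for composition removes CpGs that merely track the tissue's cell-type
mix. p-values on b_i are BH-corrected within each module's family and a
CpG is assigned to the module with the smallest FDR among those below
alpha (ties: larger |b_i|, then smaller module id), so no CpG is reported
under two modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coexpression import EigengeneMatrix
from .deconvolution import ProportionTable
from .io_formats import BetaMatrix, SampleTable

__all__ = [
    "differential_methylation",
    "associate_cpgs",
    "hypermethylation_fraction",
    "DELTA_BETA_THRESHOLD",
    "DM_FDR_THRESHOLD",
]

DELTA_BETA_THRESHOLD = 0.2
DM_FDR_THRESHOLD = 0.05
MODERATION_PRIOR_DF = 4.0  # fixed prior strength of the variance shrinkage


def differential_methylation(betas: BetaMatrix, samples: SampleTable) -> pd.DataFrame:
    """Tumor-vs-normal moderated t test per CpG on beta values.

    Returns a frame with delta_beta (mean tumor - mean normal), p, fdr
    and the boolean ``passes`` gate (|delta_beta| > 0.2 and fdr < 0.05).
    """
    tumor_ids = [s for s in samples.ids_for("tumor") if s in betas.data.columns]
    normal_ids = [s for s in samples.ids_for("normal") if s in betas.data.columns]
    if len(tumor_ids) < 2 or len(normal_ids) < 2:
        raise ValueError(
            f"need >= 2 samples per condition, got {len(tumor_ids)} tumor / "
            f"{len(normal_ids)} normal"
        )
    t_vals = betas.data[tumor_ids].to_numpy(dtype=float)
    n_vals = betas.data[normal_ids].to_numpy(dtype=float)
    n1, n2 = t_vals.shape[1], n_vals.shape[1]
    delta = t_vals.mean(axis=1) - n_vals.mean(axis=1)
    # pooled two-sample variance, then empirical-Bayes shrinkage toward the
    # cross-CpG mean variance with fixed prior df d0
    ss = t_vals.var(axis=1, ddof=1) * (n1 - 1) + n_vals.var(axis=1, ddof=1) * (n2 - 1)
    d = n1 + n2 - 2
    s2 = ss / d
    d0 = MODERATION_PRIOR_DF
    s0_sq = float(s2.mean())
    s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t_stat), d0 + d)
    fdr = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({
        "cpg_id": betas.cpg_ids,
        "delta_beta": delta,
        "t": t_stat,
        "p": p,
        "fdr": fdr,
    })
    out["passes"] = (out.delta_beta.abs() > DELTA_BETA_THRESHOLD) & (out.fdr < DM_FDR_THRESHOLD)
    return out


def _screen_design(eigengenes: EigengeneMatrix, proportions: ProportionTable | None,
                   focal: int, samples: list[str]) -> np.ndarray:
    """Covariate block for module ``focal``: intercept, T-1 proportions, other eigengenes.

    ``proportions=None`` drops the composition covariates (used to
    demonstrate the confounding they are there to remove).
    """
    if proportions is None:
        comp = np.empty((len(samples), 0))
    else:
        comp = proportions.design_columns().loc[samples].to_numpy(dtype=float)
    others = [m for m in eigengenes.module_ids if m != focal]
    eg_others = eigengenes.data.loc[samples, [f"EG{m}" for m in others]].to_numpy(dtype=float)
    n = len(samples)
    Z = np.column_stack([np.ones(n), comp, eg_others])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        comp_cols = [] if proportions is None else list(proportions.design_columns().columns)
        cols = ["intercept", *comp_cols, *(f"EG{m}" for m in others)]
        raise ValueError(f"rank-deficient covariate design for module {focal}: {cols}")
    return Z


def associate_cpgs(eigengenes: EigengeneMatrix, betas: BetaMatrix,
                   proportions: ProportionTable | None, alpha: float = 0.05,
                   use_m_values: bool = False) -> pd.DataFrame:
    """Assign each CpG to at most one module via the covariate-adjusted screen.

    For every (module i, CpG j) pair fits OLS of EG_i on [beta_j,
    composition, other eigengenes], takes the two-sided t p-value of the
    CpG slope, BH-corrects within module i's family, and assigns CpG j to
    the module with the smallest FDR among those with fdr < alpha.

    ``use_m_values`` regresses on M-values log2(beta/(1-beta)) instead of
    beta (beta clipped to [1e-6, 1-1e-6] first).
    """
    samples = [s for s in eigengenes.data.index if s in betas.data.columns]
    cpgs = betas.cpg_ids
    module_ids = eigengenes.module_ids
    n = len(samples)
    n_comp = 0 if proportions is None else proportions.design_columns().shape[1]
    min_n = (len(module_ids) - 1) + n_comp + 3
    if n < min_n + 1:
        raise ValueError(f"{n} shared samples is too few for the screen design")
    B = betas.data[samples].to_numpy(dtype=float).T  # samples x cpgs
    if use_m_values:
        Bc = np.clip(B, 1e-6, 1 - 1e-6)
        B = np.log2(Bc / (1 - Bc))
    per_module: list[pd.DataFrame] = []
    for m in module_ids:
        y = eigengenes.eigengene(m).loc[samples].to_numpy(dtype=float)
        Z = _screen_design(eigengenes, proportions, m, samples)
        # Frisch-Waugh: residualise y and every CpG column against Z once,
        # then each b_i and its t statistic come from a single regression of
        # residual on residual with df = n - (covariates + 2).
        Q, _ = np.linalg.qr(Z)
        y_res = y - Q @ (Q.T @ y)
        B_res = B - Q @ (Q.T @ B)
        xx = (B_res * B_res).sum(axis=0)
        xy = B_res.T @ y_res
        df = n - Z.shape[1] - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.where(xx > 0, xy / np.where(xx > 0, xx, 1.0), 0.0)
        rss = (y_res * y_res).sum() - b * xy
        rss = np.maximum(rss, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(rss / df / np.where(xx > 0, xx, np.inf))
        t_stat = np.where(se > 0, b / np.where(se > 0, se, 1.0),
                          np.where(b != 0, np.inf, 0.0))
        p = 2.0 * stats.t.sf(np.abs(t_stat), df)
        fdr = multipletests(p, method="fdr_bh")[1]
        per_module.append(pd.DataFrame({
            "cpg_id": cpgs, "cluster": m, "b": b, "p": p, "fdr": fdr,
        }))
    table = pd.concat(per_module, ignore_index=True)
    sig = table[table.fdr < alpha].copy()
    if sig.empty:
        return pd.DataFrame(columns=["cpg_id", "cluster", "b", "p", "fdr"])
    # unique assignment: smallest FDR, then largest |b|, then smallest module id
    sig["abs_b"] = sig.b.abs()
    sig = sig.sort_values(["cpg_id", "fdr", "abs_b", "cluster"],
                          ascending=[True, True, False, True], kind="stable")
    best = sig.drop_duplicates("cpg_id", keep="first").drop(columns="abs_b")
    return best.reset_index(drop=True)


def attach_direction(assocs: pd.DataFrame, dm: pd.DataFrame) -> pd.DataFrame:
    """Add the differential-methylation direction (sign of delta beta) per CpG."""
    delta = dm.set_index("cpg_id").delta_beta
    out = assocs.copy()
    out["direction"] = np.sign(delta.loc[out.cpg_id].to_numpy())
    return out


def hypermethylation_fraction(assocs: pd.DataFrame, cluster: int) -> float:
    """Fraction of a module's assigned CpGs that are hypermethylated in tumors."""
    sub = assocs[assocs.cluster == cluster]
    if sub.empty:
        raise ValueError(f"no CpG associations for cluster {cluster}")
    if "direction" not in sub.columns:
        raise ValueError("associations lack a direction column; attach_direction first")
    return float((sub.direction > 0).mean())
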