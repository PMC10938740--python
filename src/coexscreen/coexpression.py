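"""Weighted co-expression network construction and module extraction.

The network is unsigned: adjacency a_ij = |cor(x_i, x_j)|^beta on
log2(TPM+1) profiles, with beta chosen by the scale-free topology
criterion. Topological overlap

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    L_ij   = sum_{u != i,j} a_iu * a_uj,

measures shared-neighbourhood similarity; modules are branches of the
average-linkage tree of 1 - TOM, extracted by a simplified hybrid tree
cut (static cut, size filter, then nearest-module reassignment by mean
TOM). Each module is summarised by its eigengene: the first principal
component of the module's standardised expression, scaled to unit
variance and oriented to correlate positively with the module's mean
standardised profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_formats import ExpressionMatrix, SampleTable

__all__ = [
    "SoftThresholdResult",
    "ModuleAssignment",
    "EigengeneMatrix",
    "log_transform",
    "filter_genes",
    "pick_soft_threshold",
    "adjacency_from_expression",
    "compute_tom",
    "cut_modules",
    "compute_eigengenes",
    "merge_close_modules",
    "module_membership",
]


def log_transform(expr: ExpressionMatrix) -> pd.DataFrame:
    """log2(TPM + 1), genes x samples."""
    return np.log2(expr.data + 1.0)


@dataclass
class SoftThresholdResult:
    """Scale-free fit over candidate soft-thresholding powers."""

    powers: np.ndarray
    signed_r2: np.ndarray          # sign(log-log slope) * R^2
    mean_connectivity: np.ndarray
    chosen_power: float
    target_r2: float = 0.8

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "power": self.powers,
            "signed_r2": self.signed_r2,
            "mean_connectivity": self.mean_connectivity,
            "chosen": self.powers == self.chosen_power,
        })


@dataclass
class ModuleAssignment:
    """Gene -> integer module label; 0 means unassigned ("grey")."""

    labels: pd.Series  # index = gene ids, values = int

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(int)

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    def genes_in(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def sizes(self) -> dict[int, int]:
        return {m: int((self.labels == m).sum()) for m in self.module_ids}

    def as_sets(self) -> dict[str, list[str]]:
        return {f"module_{m}": self.genes_in(m) for m in self.module_ids}


@dataclass
class EigengeneMatrix:
    """Samples x modules eigengene matrix, unit sample variance per column."""

    data: pd.DataFrame  # index = sample ids, columns = "EG<module>"
    variance_explained: dict[int, float] = field(default_factory=dict)

    @property
    def module_ids(self) -> list[int]:
        return [int(c[2:]) for c in self.data.columns]

    def eigengene(self, module: int) -> pd.Series:
        return self.data[f"EG{module}"]


def filter_genes(expr: ExpressionMatrix, samples: SampleTable) -> ExpressionMatrix:
    """Expression filter applied before network construction.

    Keeps genes with TPM > 1 in strictly more than half of the tumor
    samples, then among those keeps genes whose log2(TPM+1) variance lies
    strictly above the 25th percentile (linear-interpolation quantile) of
    the surviving genes' variances.
    """
    tumor_ids = [s for s in samples.ids_for("tumor") if s in expr.data.columns]
    if not tumor_ids:
        raise ValueError("no tumor samples present in the expression matrix")
    tumor = expr.data[tumor_ids]
    frac_expressed = (tumor > 1.0).mean(axis=1)
    expressed = expr.data.index[frac_expressed > 0.5]
    if len(expressed) == 0:
        raise ValueError(
            "no genes expressed (> 1 TPM) in over 50% of tumor samples; "
            "review expression filtering thresholds"
        )
    logx = np.log2(expr.data.loc[expressed] + 1.0)
    variances = logx.var(axis=1, ddof=1)
    cutoff = np.percentile(variances.to_numpy(), 25.0)  # linear interpolation
    keep = variances.index[variances > cutoff]
    if len(keep) == 0:
        raise ValueError(
            "no genes with variance above the 25th percentile; "
            "review expression filtering thresholds"
        )
    return ExpressionMatrix(expr.data.loc[keep])


def _correlation(logx: pd.DataFrame) -> np.ndarray:
    x = logx.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    if (sd == 0).any():
        gene = logx.index[int(np.argmax(sd == 0))]
        raise ValueError(f"constant expression for gene {gene!r}: correlation undefined")
    c = np.corrcoef(x)
    return np.clip(c, -1.0, 1.0)


def adjacency_from_expression(logx: pd.DataFrame, power: float) -> np.ndarray:
    """Unsigned adjacency |cor|^power with unit diagonal."""
    adj = np.abs(_correlation(logx)) ** power
    np.fill_diagonal(adj, 1.0)
    return adj


def _scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Scale-free fit index: -sign(slope) * R^2 of log10 p(k) ~ log10 k.

    Computed over equal-width connectivity bins; positive when the degree
    distribution decays (the scale-free direction), so a good power gives
    an index near 1.
    """
    k = connectivity[connectivity > 0]
    if len(k) < 2 or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mask = (counts > 0) & (centers > 0)
    if mask.sum() < 2:
        return 0.0
    logk = np.log10(centers[mask])
    logp = np.log10(counts[mask] / counts.sum())
    if np.ptp(logk) == 0:
        return 0.0
    slope, _ = np.polyfit(logk, logp, 1)
    r = np.corrcoef(logk, logp)[0, 1]
    return float(-np.sign(slope) * r * r)


def pick_soft_threshold(expr_log: pd.DataFrame,
                        powers: np.ndarray | None = None,
                        target_r2: float = 0.8,
                        n_bins: int = 10) -> SoftThresholdResult:
    """Evaluate candidate powers and choose one by the scale-free criterion.

    Chooses the smallest power whose signed scale-free R^2 reaches
    ``target_r2``; if none does, the power maximising signed R^2.
    """
    if powers is None:
        powers = np.arange(1, 21, dtype=float)
    powers = np.asarray(powers, dtype=float)
    n_genes, n_samples = expr_log.shape
    if n_genes < 30 or n_samples < 20:
        warnings.warn(
            f"soft-threshold selection on {n_genes} genes x {n_samples} samples; "
            "fewer than 30 genes or 20 samples gives an unstable scale-free fit",
            stacklevel=2,
        )
    abs_cor = np.abs(_correlation(expr_log))
    r2 = np.empty(len(powers))
    mean_k = np.empty(len(powers))
    for i, p in enumerate(powers):
        adj = abs_cor ** p
        np.fill_diagonal(adj, 1.0)
        k = adj.sum(axis=1) - 1.0
        mean_k[i] = k.mean()
        r2[i] = _scale_free_fit(k, n_bins=n_bins)
    hits = np.nonzero(r2 >= target_r2)[0]
    chosen = powers[hits[0]] if len(hits) else powers[int(np.argmax(r2))]
    return SoftThresholdResult(powers, r2, mean_k, float(chosen), target_r2)


def compute_tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency matrix; diagonal 1.

    Isolated perfectly-linked pairs (denominator 0) are defined as overlap 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be square and symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    # L_ij = sum_u a_iu a_uj over u != i,j; the matrix product includes no
    # i or j diagonal terms because diag(a) = 0.
    L = a @ a
    num = L + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 1.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 1..M by decreasing size (ties by old label); 0 stays 0."""
    out = np.zeros_like(labels)
    nonzero = [l for l in np.unique(labels) if l != 0]
    sizes = {l: (labels == l).sum() for l in nonzero}
    order = sorted(nonzero, key=lambda l: (-sizes[l], l))
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


def cut_modules(tom: np.ndarray, gene_ids: list[str],
                min_module_size: int = 30,
                cut_height: float = 0.995,
                deep_split: int = 2) -> ModuleAssignment:
    """Extract modules from a TOM by a simplified hybrid dynamic tree cut.

    Average-linkage clustering of 1 - TOM, cut at the most informative
    height at or below ``cut_height``: among all merge heights, the one
    yielding the largest number of clusters of at least
    ``min_module_size`` genes (a single fixed height cannot separate
    tight modules from the diffuse background, which coalesces just
    below the tree's root). Ties between heights are broken toward the
    higher height (most inclusive module membership) for
    ``deep_split`` <= 2 and toward the lower height (finer splits) above.
    Branches below ``min_module_size`` are unassigned (label 0);
    unassigned genes are then re-admitted to the module with the highest
    mean TOM, provided that mean exceeds the module's median
    within-module TOM (the PAM-like stage).
    """
    n = tom.shape[0]
    if n != len(gene_ids):
        raise ValueError("gene_ids length does not match TOM dimension")
    if n < min_module_size:
        raise ValueError(
            f"{n} genes is fewer than min_module_size={min_module_size}; "
            "reduce min_module_size"
        )
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    merge_heights = np.unique(linkage[:, 2])
    candidates = np.append(merge_heights[merge_heights <= cut_height], cut_height)
    # small step above each merge height so fcluster includes that merge
    eps = 1e-9
    best_height, best_count = cut_height, -1
    prefer_high = deep_split <= 2
    order = candidates if prefer_high else candidates[::-1]
    for h in order:
        raw = hierarchy.fcluster(linkage, t=h + eps, criterion="distance")
        count = int(np.sum(np.bincount(raw) >= min_module_size))
        if count > best_count or (count == best_count and prefer_high and h > best_height):
            best_height, best_count = h, count
    raw = hierarchy.fcluster(linkage, t=best_height + eps, criterion="distance")
    labels = np.asarray(raw, dtype=int)
    # drop undersized branches
    for l in np.unique(labels):
        if (labels == l).sum() < min_module_size:
            labels[labels == l] = 0
    labels = _relabel_by_size(labels)
    modules = [l for l in np.unique(labels) if l != 0]
    if modules:
        # PAM-like stage: mean TOM to each module vs module's median within-TOM
        med_within = {}
        for m in modules:
            idx = np.nonzero(labels == m)[0]
            sub = tom[np.ix_(idx, idx)]
            off = sub[~np.eye(len(idx), dtype=bool)]
            med_within[m] = np.median(off) if len(off) else 0.0
        unassigned = np.nonzero(labels == 0)[0]
        for g in unassigned:
            best_m, best_mean = 0, -np.inf
            for m in modules:
                idx = np.nonzero(labels == m)[0]
                mean_tom = tom[g, idx].mean()
                if mean_tom > best_mean:
                    best_m, best_mean = m, mean_tom
            if best_m != 0 and best_mean > med_within[best_m]:
                labels[g] = best_m
        labels = _relabel_by_size(labels)
    return ModuleAssignment(pd.Series(labels, index=pd.Index(gene_ids), name="module"))


def compute_eigengenes(expr: ExpressionMatrix,
                       modules: ModuleAssignment) -> EigengeneMatrix:
    """First-principal-component eigengene per module.

    Per module: standardise each gene's log2(TPM+1) profile to mean 0,
    sd 1 across samples; the eigengene is the first right singular vector
    of the standardised genes x samples block, rescaled to unit sample
    variance and sign-oriented so that it correlates non-negatively with
    the module's mean standardised profile.
    """
    logx = log_transform(expr)
    samples = expr.sample_ids
    cols, var_explained = {}, {}
    for m in modules.module_ids:
        genes = modules.genes_in(m)
        if len(genes) < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")
        block = logx.loc[genes].to_numpy(dtype=float)
        sd = block.std(axis=1, ddof=1)
        if (sd == 0).any():
            gene = genes[int(np.argmax(sd == 0))]
            raise ValueError(f"zero-variance gene {gene!r} in module {m}")
        z = (block - block.mean(axis=1, keepdims=True)) / sd[:, None]
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        eg = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(eg, mean_profile) < 0:
            eg = -eg
        eg_sd = eg.std(ddof=1)
        if eg_sd == 0:
            raise ValueError(f"degenerate eigengene for module {m}")
        cols[f"EG{m}"] = eg / eg_sd
        var_explained[m] = float(s[0] ** 2 / (s ** 2).sum())
    data = pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"))
    return EigengeneMatrix(data, var_explained)


def merge_close_modules(expr: ExpressionMatrix,
                        modules: ModuleAssignment,
                        eigengenes: EigengeneMatrix | None = None,
                        merge_cut: float = 0.25) -> tuple[ModuleAssignment, EigengeneMatrix]:
    """Merge module pairs whose eigengene dissimilarity 1 - cor < merge_cut.

    Greedy agglomeration: repeatedly merge the closest eligible pair,
    recompute eigengenes, and stop at a fixpoint.
    """
    labels = modules.labels.copy()
    if eigengenes is None:
        eigengenes = compute_eigengenes(expr, ModuleAssignment(labels))
    while True:
        assignment = ModuleAssignment(labels)
        ids = assignment.module_ids
        if len(ids) < 2:
            break
        eg = eigengenes.data[[f"EG{m}" for m in ids]].to_numpy()
        cor = np.corrcoef(eg.T)
        dissim = 1.0 - cor
        np.fill_diagonal(dissim, np.inf)
        i, j = np.unravel_index(np.argmin(dissim), dissim.shape)
        if dissim[i, j] >= merge_cut:
            break
        keep, drop = sorted((ids[i], ids[j]))
        labels[labels == drop] = keep
        labels = pd.Series(
            _relabel_by_size(labels.to_numpy()), index=labels.index, name="module"
        )
        eigengenes = compute_eigengenes(expr, ModuleAssignment(labels))
    assignment = ModuleAssignment(labels)
    return assignment, compute_eigengenes(expr, assignment)


def module_membership(expr: ExpressionMatrix,
                      eigengenes: EigengeneMatrix) -> pd.DataFrame:
    """kME matrix: Pearson correlation of each gene's log2(TPM+1) with each eigengene."""
    logx = log_transform(expr).to_numpy(dtype=float)
    sd = logx.std(axis=1, ddof=1)
    if (sd == 0).any():
        gene = expr.gene_ids[int(np.argmax(sd == 0))]
        raise ValueError(f"zero-variance gene {gene!r}: kME undefined")
    eg = eigengenes.data.to_numpy(dtype=float)
    zrow = logx - logx.mean(axis=1, keepdims=True)
    zrow /= np.linalg.norm(zrow, axis=1, keepdims=True)
    egc = eg - eg.mean(axis=0)
    egc /= np.linalg.norm(egc, axis=0)
    kme = zrow @ egc
    return pd.DataFrame(np.clip(kme, -1, 1), index=expr.data.index,
                        columns=eigengenes.data.columns)


def hub_genes(kme: pd.DataFrame, modules: ModuleAssignment,
              module: int, k: int = 5) -> pd.DataFrame:
    """Top-k member genes of a module ranked by kME (ties by gene id)."""
    genes = modules.genes_in(module)
    col = f"EG{module}"
    sub = kme.loc[genes, col]
    order = sorted(genes, key=lambda g: (-sub[g], g))
    top = order[:k]
    tied = len(set(np.round(sub[order[: min(k + 1, len(order))]], 12))) < min(k + 1, len(order))
    return pd.DataFrame({
        "gene_id": top,
        "kME": [sub[g] for g in top],
        "rank": np.arange(1, len(top) + 1),
        "tied": tied,
    })
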