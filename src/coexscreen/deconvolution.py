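"""Bulk cell-composition estimation by signature non-negative least squares.

A signature matrix of per-cell-type mean expression (linear TPM scale) is
built from a labelled reference; each bulk sample is then decomposed as a
non-negative combination of the signatures and the weights are renormalised
to the simplex. Mixing is modelled on the linear scale because transcript
abundance mixes linearly in molecule counts. The resulting proportions serve
as composition covariates in the downstream eigengene regressions;
cross-subject variance weighting of full deconvolution frameworks is reduced
to an optional inverse-variance row weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io_formats import ExpressionMatrix

__all__ = ["SignatureMatrix", "ProportionTable", "build_signature", "estimate_proportions"]


@dataclass
class SignatureMatrix:
    """Genes x cell-types reference mean expression (linear scale)."""

    data: pd.DataFrame  # index = gene ids, columns = cell types

    def __post_init__(self) -> None:
        if self.data.shape[1] < 2:
            raise ValueError("signature requires at least 2 cell types")
        vals = self.data.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("negative reference expression in signature")
        if (vals.sum(axis=1) == 0).any():
            gene = self.data.index[int(np.argmax(vals.sum(axis=1) == 0))]
            raise ValueError(f"all-zero signature row for gene {gene!r}")

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ProportionTable:
    """Samples x cell-types mixing proportions; each row on the simplex."""

    data: pd.DataFrame
    residual_norm: pd.Series | None = None
    identifiable: bool = True

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if (vals < -1e-12).any():
            raise ValueError("negative proportion")
        if not np.allclose(vals.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("proportion rows must sum to 1")

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)

    def design_columns(self) -> pd.DataFrame:
        """First T-1 of T proportion columns (drops one to avoid simplex collinearity)."""
        return self.data.iloc[:, :-1]


def build_signature(reference: ExpressionMatrix, labels: pd.Series,
                    marker_selection: str = "all_common",
                    bulk_genes: list[str] | None = None,
                    top_k: int = 50) -> SignatureMatrix:
    """Per-cell-type mean reference profiles, optionally restricted to markers.

    ``labels`` maps reference column (cell/profile) id -> cell-type name.
    ``marker_selection="top_k_fold"`` keeps, per type, the ``top_k`` genes
    with the largest fold change of that type's mean over the mean of the
    other types (pseudocount 1).
    """
    labels = labels.astype(str)
    types = sorted(set(labels))
    if len(types) < 2:
        raise ValueError("reference must contain at least 2 cell types")
    data = reference.data
    means = {}
    for t in types:
        ids = labels.index[labels == t]
        ids = [i for i in ids if i in data.columns]
        if not ids:
            raise ValueError(f"cell type {t!r} has no reference profiles")
        means[t] = data[ids].mean(axis=1)
    sig = pd.DataFrame(means)
    if bulk_genes is not None:
        shared = [g for g in sig.index if g in set(bulk_genes)]
        sig = sig.loc[shared]
    sig = sig[sig.sum(axis=1) > 0]
    if marker_selection == "top_k_fold":
        keep: set[str] = set()
        arr = sig.to_numpy(dtype=float)
        for j, t in enumerate(sig.columns):
            rest = np.delete(arr, j, axis=1).mean(axis=1)
            fold = (arr[:, j] + 1.0) / (rest + 1.0)
            order = np.argsort(-fold, kind="stable")
            keep.update(sig.index[order[:top_k]])
        sig = sig.loc[[g for g in sig.index if g in keep]]
    elif marker_selection != "all_common":
        raise ValueError(f"unknown marker_selection {marker_selection!r}")
    return SignatureMatrix(sig)


def estimate_proportions(bulk: ExpressionMatrix, sig: SignatureMatrix,
                         weighting: str = "none") -> ProportionTable:
    """Per-sample NNLS decomposition of bulk expression onto the signature.

    Solves min_{p >= 0} || W (bulk_g - sum_t sig_gt p_t) || per sample and
    renormalises p to sum 1. ``weighting="inverse_variance"`` downweights
    genes with high variance across the signature's cell types.
    """
    if weighting not in ("none", "inverse_variance"):
        raise ValueError(f"unknown weighting {weighting!r}")
    shared = [g for g in sig.data.index if g in set(bulk.gene_ids)]
    if len(shared) < 2 * sig.data.shape[1]:
        raise ValueError(
            f"only {len(shared)} genes shared between bulk and signature; "
            f"need at least 2 per cell type"
        )
    S = sig.data.loc[shared].to_numpy(dtype=float)
    B = bulk.data.loc[shared].to_numpy(dtype=float)
    identifiable = np.linalg.matrix_rank(S) == S.shape[1]
    if not identifiable:
        warnings.warn("signature columns are collinear; proportions are not identifiable",
                      stacklevel=2)
    if weighting == "inverse_variance":
        w = 1.0 / np.sqrt(S.var(axis=1, ddof=1) + 1e-8)
        S = S * w[:, None]
        B = B * w[:, None]
    rows, resids = [], []
    for j, sample in enumerate(bulk.sample_ids):
        y = B[:, j]
        if np.all(bulk.data[sample].to_numpy() == 0):
            raise ValueError(f"bulk sample {sample!r} is all zero")
        p, resid = nnls(S, y)
        total = p.sum()
        if total == 0:
            p = np.full(S.shape[1], 1.0 / S.shape[1])
        else:
            p = p / total
        rows.append(p)
        resids.append(resid)
    data = pd.DataFrame(rows, index=pd.Index(bulk.sample_ids, name="sample_id"),
                        columns=sig.cell_types)
    return ProportionTable(data, residual_norm=pd.Series(resids, index=data.index),
                           identifiable=identifiable)
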