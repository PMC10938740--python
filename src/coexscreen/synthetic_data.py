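"""Synthetic multi-omics cohort with planted ground truth.

The generator emits the full input stack of the screen — bulk expression,
CpG beta values, copy-number segments, sample metadata, a labelled
reference for deconvolution, and a CpG coordinate map — built from an
explicit latent structure that is returned alongside as ``SyntheticTruth``:

* per-module eigengene truths: independent standard normal sample scores;
  module genes load on them on the log2(TPM+1) scale, optionally shifted
  in tumors (the differential-expression plant);
* cell-type proportions drawn from a Dirichlet; a designated block of
  type-exclusive marker genes mixes the reference profiles linearly, so
  deconvolution is well-posed;
* CpGs generated on the logit scale (mapped through the sigmoid, so betas
  live in [0,1] without truncation): module-linked CpGs carry an
  eigengene slope and a tumor shift, and every CpG carries a cell-
  composition term — the confound the screen's covariates must remove;
* per-sample chromosomal-instability targets, optionally tied to one
  module's eigengene, realised as non-overlapping altered segments whose
  recomputed index matches the target to within +-0.01.

All randomness flows from the config's single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    BetaMatrix,
    CpGMap,
    ExpressionMatrix,
    GenomeModel,
    SampleTable,
    SegmentTable,
)

__all__ = ["ModuleSpec", "CohortConfig", "SyntheticTruth", "SyntheticCohort",
           "generate_cohort", "generate_reference", "default_genome"]

CELL_TYPES = ("basal", "luminal", "stromal")


def default_genome() -> GenomeModel:
    """Five synthetic 10-Mb chromosomes; desk-scale stand-in for a karyotype."""
    return GenomeModel({f"chr{i}": 10_000_000 for i in range(1, 6)})


@dataclass
class ModuleSpec:
    """One planted co-expression module."""

    size: int
    eigengene_effect_sd: float = 1.0   # scale of gene loadings on the eigengene
    within_noise_sd: float = 0.6       # residual sd of log2(TPM+1) within the module
    de_shift: float = 0.0              # tumor shift of log2(TPM+1); <0 = down in tumor


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Defaults give the desk-scale default cohort: 2,000 genes in 5 modules
    of 50-150 genes plus background, 200 samples (150 tumor / 50 normal),
    1,000 CpGs with 10 module-linked CpGs per module, 3 cell types, and
    the chromosomal-instability index tied to module 1, whose genes are
    also shifted down in tumors.
    """

    n_tumor: int = 150
    n_normal: int = 50
    modules: list[ModuleSpec] = field(default_factory=lambda: [
        ModuleSpec(150, de_shift=-1.0),
        ModuleSpec(120),
        ModuleSpec(90),
        ModuleSpec(70),
        ModuleSpec(50),
    ])
    n_background_genes: int = 1520
    n_cpgs: int = 1000
    n_linked_cpgs_per_module: int = 10
    cpg_effect: float = 1.0               # logit-beta slope on the linked eigengene
    cpg_tumor_shift: float = 1.5          # logit-beta tumor shift of linked CpGs
    cpg_noise_sd: float = 0.5             # residual sd on the logit scale
    composition: tuple[float, ...] = (3.0, 3.0, 3.0)  # Dirichlet concentration
    composition_confound_strength: float = 2.0
    module_composition_sd: float = 0.5    # scale of module-gene loadings on composition
    cin_linked_module: int | None = 1     # 1-based module index, or None
    cin_noise_sd: float = 0.05
    genome: GenomeModel = field(default_factory=default_genome)
    seed: int = 0
    n_markers_per_type: int = 30
    n_reference_profiles_per_type: int = 3

    def __post_init__(self) -> None:
        if self.n_tumor <= 0 or self.n_normal <= 0:
            raise ValueError("sample counts must be positive")
        if any(c <= 0 for c in self.composition):
            raise ValueError("Dirichlet concentrations must be positive")
        if len(self.composition) != len(CELL_TYPES):
            raise ValueError(f"expected {len(CELL_TYPES)} composition concentrations")
        if self.n_linked_cpgs_per_module * len(self.modules) > self.n_cpgs:
            raise ValueError("more linked CpGs requested than CpGs available")
        n_markers = self.n_markers_per_type * len(CELL_TYPES)
        if n_markers > self.n_background_genes:
            raise ValueError("marker genes exceed the background gene budget")
        if self.cin_linked_module is not None and not (
            1 <= self.cin_linked_module <= len(self.modules)
        ):
            raise ValueError("cin_linked_module out of range")


@dataclass
class SyntheticTruth:
    """Planted parameters against which recovery is scored."""

    gene_modules: pd.Series          # gene -> module label, 0 = background
    eigengenes: pd.DataFrame         # samples x modules true eigengene scores
    proportions: pd.DataFrame        # samples x cell types, rows sum to 1
    cpg_links: pd.Series             # cpg -> linked module, 0 = none
    cpg_slope_sign: pd.Series        # cpg -> sign of the planted logit slope
    cin: pd.Series                   # sample -> true CIN target
    de_status: pd.Series             # gene -> planted differential expression


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    betas: BetaMatrix
    segments: SegmentTable
    samples: SampleTable
    reference: ExpressionMatrix
    reference_labels: pd.Series      # reference profile id -> cell type
    cpg_map: CpGMap
    truth: SyntheticTruth


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_reference(config: CohortConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[ExpressionMatrix, pd.Series, pd.DataFrame]:
    """Reference expression profiles with type-exclusive marker genes.

    Returns (reference matrix genes x profiles, profile -> cell-type labels,
    true per-type mean profiles genes x types). Marker gene g of type t has
    mean TPM ~ Uniform(50, 150) in t and 0 in every other type; each type
    contributes ``n_reference_profiles_per_type`` noisy profiles around its
    mean.
    """
    if len(CELL_TYPES) < 2:  # pragma: no cover - fixed constant
        raise ValueError("need at least 2 cell types")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    k = config.n_markers_per_type
    marker_ids = [f"marker_{t}_{i:03d}" for t in CELL_TYPES for i in range(k)]
    means = pd.DataFrame(0.0, index=pd.Index(marker_ids), columns=list(CELL_TYPES))
    for ti, t in enumerate(CELL_TYPES):
        block = [f"marker_{t}_{i:03d}" for i in range(k)]
        means.loc[block, t] = rng.uniform(50.0, 150.0, size=k)
    profiles, labels = {}, {}
    for t in CELL_TYPES:
        for r in range(config.n_reference_profiles_per_type):
            pid = f"ref_{t}_{r}"
            noise = rng.normal(1.0, 0.05, size=len(marker_ids))
            profiles[pid] = np.maximum(means[t].to_numpy() * noise, 0.0)
            labels[pid] = t
    ref = pd.DataFrame(profiles, index=means.index)
    return ExpressionMatrix(ref), pd.Series(labels, name="cell_type"), means


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort; deterministic under the config seed."""
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_tumor + config.n_normal
    sample_ids = [f"T{i + 1:03d}" for i in range(config.n_tumor)] + \
                 [f"N{i + 1:03d}" for i in range(config.n_normal)]
    is_tumor = np.array([1.0] * config.n_tumor + [0.0] * config.n_normal)
    samples = SampleTable(pd.DataFrame({
        "sample_id": sample_ids,
        "condition": ["tumor"] * config.n_tumor + ["normal"] * config.n_normal,
    }))

    # --- latent structure -------------------------------------------------
    n_modules = len(config.modules)
    eigen_true = rng.standard_normal((n_samples, n_modules))
    eigen_df = pd.DataFrame(eigen_true, index=pd.Index(sample_ids, name="sample_id"),
                            columns=[f"EG{m + 1}" for m in range(n_modules)])
    props = rng.dirichlet(np.asarray(config.composition, dtype=float), size=n_samples)
    props_df = pd.DataFrame(props, index=pd.Index(sample_ids, name="sample_id"),
                            columns=list(CELL_TYPES))

    # --- expression -------------------------------------------------------
    reference, ref_labels, ref_means = generate_reference(config, rng)
    marker_ids = list(ref_means.index)
    n_module_genes = sum(m.size for m in config.modules)
    n_plain_bg = config.n_background_genes - len(marker_ids)
    if n_plain_bg < 0:
        raise ValueError("marker genes exceed the background gene budget")
    gene_ids, gene_module = [], []
    for mi, mod in enumerate(config.modules, start=1):
        gene_ids += [f"mod{mi}_g{j:04d}" for j in range(mod.size)]
        gene_module += [mi] * mod.size
    bg_ids = [f"bg_g{j:05d}" for j in range(n_plain_bg)]
    gene_ids += bg_ids + marker_ids
    gene_module += [0] * (n_plain_bg + len(marker_ids))

    log_expr = np.empty((len(gene_ids), n_samples))
    row = 0
    de_status = {}
    centered_props_expr = props - props.mean(axis=0)
    for mi, mod in enumerate(config.modules, start=1):
        mu = rng.uniform(3.0, 7.0, size=mod.size)
        w = mod.eigengene_effect_sd * rng.uniform(0.6, 1.4, size=mod.size)
        # shared per-module composition direction: bulk module expression
        # partially tracks the cell-type mix, the confound the screen adjusts for
        u = rng.normal(0.0, config.module_composition_sd, size=props.shape[1])
        comp_factor = centered_props_expr @ u
        c = rng.uniform(0.5, 1.5, size=mod.size)
        noise = rng.normal(0.0, mod.within_noise_sd, size=(mod.size, n_samples))
        block = (mu[:, None] + np.outer(w, eigen_true[:, mi - 1])
                 + np.outer(c, comp_factor)
                 + mod.de_shift * is_tumor[None, :] + noise)
        log_expr[row:row + mod.size] = block
        for j in range(mod.size):
            de_status[gene_ids[row + j]] = abs(mod.de_shift) > 0
        row += mod.size
    mu_bg = rng.uniform(2.0, 7.0, size=n_plain_bg)
    sd_bg = rng.uniform(0.3, 1.2, size=n_plain_bg)
    log_expr[row:row + n_plain_bg] = (
        mu_bg[:, None] + rng.normal(0.0, 1.0, size=(n_plain_bg, n_samples)) * sd_bg[:, None]
    )
    for g in bg_ids:
        de_status[g] = False
    row += n_plain_bg
    # marker genes mix the reference means linearly in the proportions
    mix = ref_means.to_numpy() @ props.T  # markers x samples, linear TPM
    mix *= rng.normal(1.0, 0.05, size=mix.shape)
    marker_tpm = np.maximum(mix, 0.0)
    for g in marker_ids:
        de_status[g] = False

    tpm = np.empty_like(log_expr)
    tpm[:row] = np.maximum(np.exp2(log_expr[:row]) - 1.0, 0.0)
    tpm[row:] = marker_tpm
    expr = ExpressionMatrix(pd.DataFrame(tpm, index=pd.Index(gene_ids),
                                         columns=sample_ids))

    # --- methylation ------------------------------------------------------
    cpg_ids = [f"cg{j:07d}" for j in range(config.n_cpgs)]
    links = np.zeros(config.n_cpgs, dtype=int)
    k = config.n_linked_cpgs_per_module
    for mi in range(n_modules):
        links[mi * k:(mi + 1) * k] = mi + 1
    b0 = rng.uniform(-1.5, 1.5, size=config.n_cpgs)
    b0[links > 0] = rng.uniform(-1.4, -0.8, size=(links > 0).sum())  # room to shift up
    conf = rng.normal(0.0, config.composition_confound_strength,
                      size=(config.n_cpgs, len(CELL_TYPES)))
    centered_props = props - props.mean(axis=0)
    logit = (b0[:, None]
             + conf @ centered_props.T
             + rng.normal(0.0, config.cpg_noise_sd, size=(config.n_cpgs, n_samples)))
    slope_sign = np.zeros(config.n_cpgs)
    for j in np.nonzero(links)[0]:
        m = links[j]
        logit[j] += config.cpg_effect * eigen_true[:, m - 1]
        logit[j] += config.cpg_tumor_shift * is_tumor
        slope_sign[j] = np.sign(config.cpg_effect) if config.cpg_effect else 0.0
    # a tenth of the unlinked CpGs are differentially methylated without any
    # module link: they must pass the DM gate yet fail the screen
    unlinked = np.nonzero(links == 0)[0]
    dm_only = unlinked[rng.random(len(unlinked)) < 0.1]
    logit[dm_only] += config.cpg_tumor_shift * is_tumor
    betas = BetaMatrix(pd.DataFrame(_sigmoid(logit), index=pd.Index(cpg_ids),
                                    columns=sample_ids))

    # --- CpG coordinates --------------------------------------------------
    chroms = config.genome.chroms
    cpg_chrom = [chroms[c] for c in rng.integers(0, len(chroms), size=config.n_cpgs)]
    cpg_pos = [int(rng.integers(0, config.genome[c])) for c in cpg_chrom]
    cpg_map = CpGMap(pd.DataFrame({"cpg_id": cpg_ids, "chrom": cpg_chrom,
                                   "pos": cpg_pos}))

    # --- CIN and segments -------------------------------------------------
    if config.cin_linked_module is not None:
        e = eigen_true[:, config.cin_linked_module - 1]
        e_std = (e - e.mean()) / e.std(ddof=0)
        cin_true = np.clip(0.05 + 0.4 * e_std
                           + rng.normal(0.0, config.cin_noise_sd, size=n_samples),
                           0.0, 1.0)
    else:
        cin_true = np.clip(rng.normal(0.1, 0.05, size=n_samples), 0.0, 1.0)
    seg_rows = []
    for si, sample in enumerate(sample_ids):
        c = cin_true[si]
        if c <= 0:
            continue
        # per-chromosome altered fractions averaging exactly to c
        d = rng.uniform(0.5, 1.5, size=len(chroms))
        fracs = c * d / d.mean()
        if fracs.max() > 1.0:  # keep the exact mean rather than clipping
            fracs = np.full(len(chroms), c)
        for chrom, frac in zip(chroms, fracs):
            length = config.genome[chrom]
            altered_bp = int(round(frac * length))
            if altered_bp <= 0:
                continue
            altered_bp = min(altered_bp, length)
            n_pieces = int(rng.integers(1, 4)) if altered_bp >= 3 else 1
            cuts = np.sort(rng.integers(1, altered_bp, size=n_pieces - 1)) \
                if n_pieces > 1 else np.array([], dtype=int)
            piece_lens = np.diff(np.concatenate([[0], cuts, [altered_bp]]))
            piece_lens = piece_lens[piece_lens > 0]
            free = length - altered_bp
            gaps = rng.multinomial(free, np.ones(len(piece_lens) + 1) / (len(piece_lens) + 1))
            pos = 0
            for piece, gap in zip(piece_lens, gaps[:-1]):
                start = pos + int(gap)
                end = start + int(piece)
                amp = (0.35 + rng.exponential(0.3)) * (1 if rng.random() < 0.5 else -1)
                seg_rows.append((sample, chrom, start, end, amp))
                pos = end
    segments = SegmentTable(pd.DataFrame(
        seg_rows, columns=["sample_id", "chrom", "start", "end", "log2ratio"]
    )).validate_against(config.genome)

    truth = SyntheticTruth(
        gene_modules=pd.Series(gene_module, index=pd.Index(gene_ids), name="module"),
        eigengenes=eigen_df,
        proportions=props_df,
        cpg_links=pd.Series(links, index=pd.Index(cpg_ids), name="module"),
        cpg_slope_sign=pd.Series(slope_sign, index=pd.Index(cpg_ids), name="sign"),
        cin=pd.Series(cin_true, index=pd.Index(sample_ids, name="sample_id"), name="cin"),
        de_status=pd.Series(de_status, name="de").loc[gene_ids],
    )
    return SyntheticCohort(expr, betas, segments, samples, reference, ref_labels,
                           cpg_map, truth)
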