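"""Readers, writers and validated containers for the pipeline's external formats.

All genomic coordinates are normalised internally to 0-based, half-open
intervals. SEG-like copy-number tables may arrive 1-based closed
(``seg1_closed``, the common SEG convention) and are converted on read;
BED is consumed natively. Sample alignment across molecular layers is by
sample-id string equality, never by column order. Missing values in the
matrices are a hard error: no NA policy is defined for this pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "BetaMatrix",
    "SegmentTable",
    "GenomeModel",
    "IntervalSet",
    "GeneSetCollection",
    "SampleTable",
    "CpGMap",
    "read_matrix",
    "write_matrix",
    "read_segments",
    "write_segments",
    "read_bed",
    "write_bed",
    "read_gmt",
    "write_gmt",
    "read_genome",
    "write_genome",
    "read_samples",
    "write_samples",
    "read_cpg_map",
    "write_cpg_map",
]

SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "log2ratio"]


class FormatError(ValueError):
    """Raised when an input file violates a format or type invariant."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM matrix (non-negative, finite)."""

    data: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise FormatError(
                f"non-finite expression value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative TPM at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class BetaMatrix:
    """CpGs x samples methylation beta values, each in [0, 1]."""

    data: pd.DataFrame  # index = cpg ids, columns = sample ids

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "cpg")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise FormatError(
                f"non-finite beta at cpg {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        out = (vals < 0) | (vals > 1)
        if out.any():
            bad = np.argwhere(out)[0]
            raise FormatError(
                f"beta value outside [0,1] at cpg {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}: {vals[bad[0], bad[1]]}"
            )

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class GenomeModel:
    """Chromosome name -> length in bp."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if int(length) <= 0:
                raise FormatError(f"chromosome {chrom!r} has non-positive length {length}")
        self.lengths = {c: int(v) for c, v in self.lengths.items()}

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]


@dataclass
class SegmentTable:
    """Copy-number segments: (sample_id, chrom, start, end, log2ratio).

    Coordinates are internal 0-based half-open. Validation against a
    GenomeModel (bounds, known chromosome) happens at read/construction
    time when a genome is supplied.
    """

    data: pd.DataFrame  # columns SEGMENT_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in SEGMENT_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"segment table missing columns: {missing}")
        self.data = self.data[SEGMENT_COLUMNS].reset_index(drop=True)
        if len(self.data):
            self.data = self.data.astype(
                {"sample_id": str, "chrom": str, "start": np.int64,
                 "end": np.int64, "log2ratio": float}
            )
            bad = self.data[self.data.start >= self.data.end]
            if len(bad):
                r = bad.iloc[0]
                raise FormatError(
                    f"segment with end <= start: {r.sample_id} {r.chrom}:{r.start}-{r.end}"
                )
            if (self.data.start < 0).any():
                raise FormatError("segment with negative start")

    def validate_against(self, genome: GenomeModel) -> "SegmentTable":
        for r in self.data.itertuples():
            if r.chrom not in genome:
                raise FormatError(f"segment chromosome {r.chrom!r} absent from genome model")
            if r.end > genome[r.chrom]:
                raise FormatError(
                    f"segment {r.sample_id} {r.chrom}:{r.start}-{r.end} exceeds "
                    f"chromosome length {genome[r.chrom]}"
                )
        return self

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class IntervalSet:
    """Genomic intervals (chrom, start, end, name), 0-based half-open; may overlap."""

    data: pd.DataFrame  # columns chrom, start, end, name

    def __post_init__(self) -> None:
        cols = ["chrom", "start", "end", "name"]
        if "name" not in self.data.columns:
            self.data = self.data.assign(name="")
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise FormatError(f"interval set missing columns: {missing}")
        self.data = self.data[cols].reset_index(drop=True)
        if len(self.data):
            self.data = self.data.astype(
                {"chrom": str, "start": np.int64, "end": np.int64, "name": str}
            )
            bad = self.data[self.data.start >= self.data.end]
            if len(bad):
                r = bad.iloc[0]
                raise FormatError(f"interval with start >= end: {r.chrom}:{r.start}-{r.end}")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class SampleTable:
    """Per-sample metadata; requires unique sample_id and a tumor/normal condition."""

    data: pd.DataFrame  # columns sample_id, condition, optional numeric covariates

    def __post_init__(self) -> None:
        for col in ("sample_id", "condition"):
            if col not in self.data.columns:
                raise FormatError(f"sample table missing column {col!r}")
        self.data = self.data.reset_index(drop=True)
        _check_unique(self.data.sample_id, "sample")
        bad = set(self.data.condition) - {"tumor", "normal"}
        if bad:
            raise FormatError(f"unknown condition values: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.sample_id)

    def ids_for(self, condition: str) -> list[str]:
        return list(self.data.sample_id[self.data.condition == condition])


@dataclass
class CpGMap:
    """CpG id -> genomic anchor (chrom, single-base 0-based pos) plus optional gene context."""

    data: pd.DataFrame  # columns cpg_id, chrom, pos [, nearest_gene, distance_to_tss]

    def __post_init__(self) -> None:
        for col in ("cpg_id", "chrom", "pos"):
            if col not in self.data.columns:
                raise FormatError(f"cpg map missing column {col!r}")
        self.data = self.data.reset_index(drop=True)
        _check_unique(self.data.cpg_id, "cpg")
        if (self.data.pos.astype(np.int64) < 0).any():
            raise FormatError("cpg map contains negative position")
        self.data = self.data.assign(
            pos=self.data.pos.astype(np.int64), chrom=self.data.chrom.astype(str)
        )

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.data.cpg_id)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, kind: str) -> ExpressionMatrix | BetaMatrix:
    """Read a feature x sample TSV matrix.

    First column = feature ids, header row = sample ids. ``kind`` selects
    validation: ``"expression"`` (TPM, non-negative) or ``"beta"`` ([0,1]).
    Row and column order are preserved.
    """
    if kind not in ("expression", "beta"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        raise FormatError(f"missing values in matrix {path}")
    return ExpressionMatrix(df) if kind == "expression" else BetaMatrix(df)


def write_matrix(matrix: ExpressionMatrix | BetaMatrix, path: str | Path,
                 feature_label: str = "feature_id") -> None:
    matrix.data.to_csv(path, sep="\t", index_label=feature_label)


def read_segments(path: str | Path, genome: GenomeModel,
                  dialect: str = "seg1_closed") -> SegmentTable:
    """Read a SEG-like TSV and normalise coordinates to 0-based half-open.

    ``seg1_closed`` input (1-based, closed) is converted via start-1 with the
    end left unchanged; ``bed0_halfopen`` is taken as-is.
    """
    if dialect not in ("seg1_closed", "bed0_halfopen"):
        raise ValueError(f"unknown segment dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    rename = {"sample": "sample_id", "chromosome": "chrom",
              "loc.start": "start", "loc.end": "end", "seg.mean": "log2ratio"}
    df = df.rename(columns=rename)
    return segments_from_frame(df, genome, dialect=dialect)


def segments_from_frame(df: pd.DataFrame, genome: GenomeModel,
                        dialect: str = "bed0_halfopen") -> SegmentTable:
    df = df.copy()
    if dialect == "seg1_closed":
        df["start"] = df["start"].astype(np.int64) - 1
    table = SegmentTable(df)
    return table.validate_against(genome)


def write_segments(table: SegmentTable, path: str | Path,
                   dialect: str = "seg1_closed") -> None:
    df = table.data.copy()
    if dialect == "seg1_closed":
        df["start"] = df["start"] + 1
    df.to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> IntervalSet:
    """Read BED3/BED4 (0-based half-open, whitespace- or tab-separated)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line with < 3 fields")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = parts[3] if len(parts) > 3 else ""
            rows.append((chrom, start, end, name))
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    intervals.data.to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name, members = parts[0], [g for g in parts[2:] if g]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = members
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            fh.write("\t".join([name, "na", *sets[name]]) + "\n")


def read_genome(path: str | Path) -> GenomeModel:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={0: str})
    _check_unique(df.chrom, "chromosome")
    return GenomeModel(dict(zip(df.chrom, df.length)))


def write_genome(genome: GenomeModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def read_samples(path: str | Path) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def write_samples(samples: SampleTable, path: str | Path) -> None:
    samples.data.to_csv(path, sep="\t", index=False)


def read_cpg_map(path: str | Path) -> CpGMap:
    return CpGMap(pd.read_csv(path, sep="\t", dtype={"cpg_id": str, "chrom": str}))


def write_cpg_map(cpg_map: CpGMap, path: str | Path) -> None:
    cpg_map.data.to_csv(path, sep="\t", index=False)
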