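"""Domain types, file readers/writers and interval indexing.

Coordinate convention: everything internal is 0-based, half-open ``[start, end)``
(BED convention). CpG manifests that follow the Illumina 1-based convention are
converted on read (``one_based=True``, the default). Chromosome names are
normalised to the ``chr``-prefixed dialect on read.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalIndex",
    "TFBSCollection",
    "CpGManifest",
    "SampleMatrix",
    "CohortBundle",
    "GeneAnnotation",
    "RegulatoryMap",
    "normalize_chrom",
    "read_bed",
    "write_bed",
    "read_tfbs_bed",
    "read_matrix",
    "read_manifest",
    "align_cohort",
]


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line/cell."""


def normalize_chrom(chrom: str) -> str:
    """Normalise chromosome dialects ("1" vs "chr1") to the chr-prefixed form."""
    return chrom if chrom.startswith("chr") else "chr" + chrom


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def distance_to(self, pos: int) -> int:
        """Distance from a point to the interval: 0 inside ``[start, end)``,
        otherwise the gap to the nearest included base."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - (self.end - 1)
        return 0


class IntervalIndex:
    """Merged-interval overlap index for one set of intervals.

    Intervals are merged per chromosome into disjoint sorted runs, so any
    point/region overlap question reduces to one binary search. Used both for
    CpG-to-TFBS proximity mapping and region-level TFBS support counting.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            merged: list[list[int]] = []
            for s, e in pairs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            arr = np.asarray(merged, dtype=np.int64)
            self._starts[chrom] = arr[:, 0]
            self._ends[chrom] = arr[:, 1]

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def overlaps_points(self, chrom: str, pos: np.ndarray, window: int = 0) -> np.ndarray:
        """Boolean mask: which points lie within ``window`` bp of an interval
        (0 inside, gap-to-nearest-base otherwise)."""
        pos = np.asarray(pos, dtype=np.int64)
        if chrom not in self._starts:
            return np.zeros(pos.shape, dtype=bool)
        starts, ends = self._starts[chrom], self._ends[chrom]
        # candidate: the rightmost merged interval with start <= pos + window
        idx = np.searchsorted(starts, pos + window, side="right") - 1
        hit = idx >= 0
        safe = np.where(hit, idx, 0)
        # point q overlaps iff end - 1 + window >= q, i.e. end > q - window
        hit &= ends[safe] > pos - window
        return hit

    def overlaps_regions(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Boolean mask: which regions ``[start, end)`` share >= 1 bp with an interval."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if chrom not in self._starts:
            return np.zeros(starts.shape, dtype=bool)
        ms, me = self._starts[chrom], self._ends[chrom]
        idx = np.searchsorted(ms, ends, side="left") - 1
        hit = idx >= 0
        safe = np.where(hit, idx, 0)
        hit &= me[safe] > starts
        return hit


class TFBSCollection:
    """Per-TF genomic interval sets with a lazy overlap index per TF."""

    def __init__(self, sites: Mapping[str, Sequence[GenomicInterval]]):
        self._sites: dict[str, list[GenomicInterval]] = {
            tf: list(ivs) for tf, ivs in sites.items()
        }
        self._index: dict[str, IntervalIndex] = {}

    @property
    def tf_names(self) -> list[str]:
        return sorted(self._sites)

    def sites(self, tf: str) -> list[GenomicInterval]:
        return self._sites[tf]

    def n_sites(self, tf: str) -> int:
        return len(self._sites[tf])

    def index(self, tf: str) -> IntervalIndex:
        if tf not in self._index:
            self._index[tf] = IntervalIndex(self._sites[tf])
        return self._index[tf]

    def all_intervals(self) -> list[GenomicInterval]:
        return [iv for ivs in self._sites.values() for iv in ivs]

    def __contains__(self, tf: str) -> bool:
        return tf in self._sites

    def __len__(self) -> int:
        return len(self._sites)


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path, normalize_chroms: bool = True) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into intervals (column 4 becomes ``name``)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 columns")
            chrom = normalize_chrom(parts[0]) if normalize_chroms else parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            strand = parts[5] if len(parts) > 5 else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, strand))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals in BED form; columns adapt to the populated fields."""
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.strand != ".":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
                )
            elif iv.name is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_tfbs_bed(path: str | Path, normalize_chroms: bool = True) -> TFBSCollection:
    """Read a name-grouped BED (column 4 = TF) into a TFBSCollection."""
    grouped: dict[str, list[GenomicInterval]] = {}
    for iv in read_bed(path, normalize_chroms=normalize_chroms):
        if iv.name is None:
            raise ParseError(f"{path}: TFBS BED requires a name (TF) column")
        grouped.setdefault(iv.name, []).append(iv)
    return TFBSCollection(grouped)


# ---------------------------------------------------------------------------
# Matrices


@dataclass
class SampleMatrix:
    """Row-feature x sample numeric matrix (methylation betas or expression).

    ``kind='methylation'`` enforces beta values within [0, 1] (NaN allowed);
    ``kind='expression'`` enforces non-negative values.
    """

    data: pd.DataFrame
    kind: str | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate row IDs: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample IDs")
        vals = self.data.to_numpy(dtype=float)
        if self.kind == "methylation":
            with np.errstate(invalid="ignore"):
                bad = (vals < 0) | (vals > 1)
            if np.any(bad & ~np.isnan(vals)):
                r, c = np.argwhere(bad & ~np.isnan(vals))[0]
                raise ValueError(
                    f"methylation beta out of [0,1] at row {self.data.index[r]!r}, "
                    f"sample {self.data.columns[c]!r}: {vals[r, c]}"
                )
        elif self.kind == "expression":
            with np.errstate(invalid="ignore"):
                bad = vals < 0
            if np.any(bad & ~np.isnan(vals)):
                r, c = np.argwhere(bad & ~np.isnan(vals))[0]
                raise ValueError(
                    f"negative expression at row {self.data.index[r]!r}, "
                    f"sample {self.data.columns[c]!r}: {vals[r, c]}"
                )

    @property
    def row_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_rows(self, rows: Sequence[str]) -> "SampleMatrix":
        return SampleMatrix(self.data.loc[list(rows)], kind=self.kind)

    def subset_samples(self, samples: Sequence[str]) -> "SampleMatrix":
        return SampleMatrix(self.data.loc[:, list(samples)], kind=self.kind)

    def to_tsv(self, path: str | Path, float_format: str = "%.6g") -> None:
        self.data.to_csv(path, sep="\t", float_format=float_format, index_label="id")


def read_matrix(path: str | Path, kind: str | None = None) -> SampleMatrix:
    """Read a TSV matrix (first column row IDs, header sample IDs)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate row IDs: {dupes[:5]}")
    num = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cleaned = raw[col].mask(raw[col].isin(["", "NA"]))
        converted = pd.to_numeric(cleaned, errors="coerce")
        bad = converted.isna() & raw[col].notna() & ~raw[col].isin(["", "NA", "nan", "NaN"])
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: non-numeric cell at row {row!r}, sample {col!r}: "
                f"{raw.loc[row, col]!r}"
            )
        num[col] = converted
    try:
        return SampleMatrix(num, kind=kind)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# CpG manifest


class CpGManifest:
    """Mapping probe_id -> (chrom, 0-based position)."""

    def __init__(self, df: pd.DataFrame):
        required = {"chrom", "pos"}
        if not required.issubset(df.columns):
            raise ValueError(f"manifest requires columns {sorted(required)}")
        if df.index.has_duplicates:
            raise ValueError("duplicate probe IDs in manifest")
        if (df["pos"] < 0).any():
            raise ValueError("negative CpG position in manifest")
        self.df = df[["chrom", "pos"]].copy()
        self.df["pos"] = self.df["pos"].astype(np.int64)

    @property
    def probe_ids(self) -> list[str]:
        return self.df.index.tolist()

    def positions(self, probes: Sequence[str] | None = None) -> pd.DataFrame:
        if probes is None:
            return self.df
        missing = [p for p in probes if p not in self.df.index]
        if missing:
            raise KeyError(f"unknown probes: {missing[:5]}")
        return self.df.loc[list(probes)]

    def subset(self, probes: Sequence[str]) -> "CpGManifest":
        return CpGManifest(self.positions(probes))

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path: str | Path, one_based: bool = False) -> None:
        out = self.df.copy()
        if one_based:
            out["pos"] = out["pos"] + 1
        out.to_csv(path, sep="\t", index_label="probe_id")


def read_manifest(
    path: str | Path, one_based: bool = True, normalize_chroms: bool = True
) -> CpGManifest:
    """Read a probe manifest TSV (probe_id, chrom, pos).

    Illumina manifests are 1-based; the default converts to internal 0-based.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if normalize_chroms:
        df["chrom"] = df["chrom"].astype(str).map(normalize_chrom)
    if one_based:
        df["pos"] = df["pos"] - 1
    return CpGManifest(df)


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortBundle:
    """Expression + methylation for one cohort, restricted to shared samples."""

    name: str
    expression: SampleMatrix
    methylation: SampleMatrix

    def __post_init__(self) -> None:
        if self.expression.sample_ids != self.methylation.sample_ids:
            raise ValueError("expression and methylation sample sets/orders differ")
        if len(self.samples) < 3:
            raise ValueError(f"cohort {self.name!r} has fewer than 3 shared samples")

    @property
    def samples(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def align_cohort(name: str, expression: SampleMatrix, methylation: SampleMatrix) -> CohortBundle:
    """Restrict both matrices to the (sorted) intersection of sample IDs."""
    shared = sorted(set(expression.sample_ids) & set(methylation.sample_ids))
    if not shared:
        raise ValueError(f"cohort {name!r}: no shared samples")
    return CohortBundle(
        name=name,
        expression=expression.subset_samples(shared),
        methylation=methylation.subset_samples(shared),
    )


# ---------------------------------------------------------------------------
# Gene annotation / regulatory map


class GeneAnnotation:
    """Gene bodies with strand-derived TSS and optional exon intervals."""

    def __init__(self, df: pd.DataFrame, exons: Mapping[str, Sequence[GenomicInterval]] | None = None):
        required = {"chrom", "start", "end", "strand"}
        if not required.issubset(df.columns):
            raise ValueError(f"annotation requires columns {sorted(required)}")
        if df.empty:
            raise ValueError("empty gene annotation")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValueError("gene strand must be + or -")
        self.df = df[["chrom", "start", "end", "strand"]].copy()
        self.df["tss"] = np.where(self.df["strand"] == "+", self.df["start"], self.df["end"] - 1)
        self.exons = {g: list(ivs) for g, ivs in (exons or {}).items()}

    @property
    def gene_ids(self) -> list[str]:
        return self.df.index.tolist()

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path: str | Path) -> None:
        self.df[["chrom", "start", "end", "strand"]].to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path, exon_bed: str | Path | None = None) -> "GeneAnnotation":
        df = pd.read_csv(path, sep="\t", index_col=0)
        exons: dict[str, list[GenomicInterval]] = {}
        if exon_bed is not None:
            for iv in read_bed(exon_bed):
                if iv.name is None:
                    raise ParseError(f"{exon_bed}: exon BED requires a gene name column")
                exons.setdefault(iv.name, []).append(iv)
        return cls(df, exons)


class RegulatoryMap:
    """Regulatory element intervals mapped to target genes (BED + gene column)."""

    def __init__(self, records: Sequence[tuple[GenomicInterval, str]]):
        self.records = list(records)
        rows = [
            (iv.chrom, iv.start, iv.end, gene) for iv, gene in self.records
        ]
        self.df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
        # per-chrom arrays sorted by start for containment queries
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._max_len = 0
        for chrom, sub in self.df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            self._by_chrom[chrom] = (
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
                sub["gene"].to_numpy(object),
            )
            if len(sub):
                self._max_len = max(self._max_len, int((sub["end"] - sub["start"]).max()))

    def genes_at(self, chrom: str, pos: int) -> list[str]:
        """Target genes of every element containing the position."""
        if chrom not in self._by_chrom:
            return []
        starts, ends, genes = self._by_chrom[chrom]
        hi = int(np.searchsorted(starts, pos, side="right"))
        lo = int(np.searchsorted(starts, pos - self._max_len, side="left"))
        out = [genes[i] for i in range(lo, hi) if starts[i] <= pos < ends[i]]
        return sorted(set(out))

    def __len__(self) -> int:
        return len(self.records)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iv, gene in self.records:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gene}\n")

    @classmethod
    def from_bed(cls, path: str | Path) -> "RegulatoryMap":
        records = []
        for iv in read_bed(path):
            if iv.name is None:
                raise ParseError(f"{path}: regulatory map requires a gene column")
            records.append((dataclasses.replace(iv, name=None), iv.name))
        return cls(records)
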