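"""Binding-signature characterisation of CpG flanks.

Window construction around CpGs, %GC, two-set differential TFBS enrichment
(one-sided Fisher via the hypergeometric tail, BH-adjusted across TFBS sets),
HOMER-style genomic-context annotation, and TF-list overlap tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import CpGManifest, GeneAnnotation, GenomicInterval, IntervalIndex, TFBSCollection
from .stats import bh_adjust, hypergeom_tail

__all__ = [
    "RegionSet",
    "window_regions",
    "gc_content",
    "differential_tfbs_enrichment",
    "annotate_genomic_context",
    "list_overlap_fisher",
]


@dataclass
class RegionSet:
    """A named, deduplicated set of genomic regions."""

    name: str
    regions: list[GenomicInterval]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, int]] = set()
        unique = []
        for r in self.regions:
            key = (r.chrom, r.start, r.end)
            if key not in seen:
                seen.add(key)
                unique.append(r)
        self.regions = unique

    def __len__(self) -> int:
        return len(self.regions)

    def keys(self) -> set[tuple[str, int, int]]:
        return {(r.chrom, r.start, r.end) for r in self.regions}


def window_regions(
    probes: Sequence[str],
    manifest: CpGManifest,
    flank: int = 200,
    chrom_sizes: Mapping[str, int] | None = None,
    name: str = "regions",
) -> RegionSet:
    """±flank windows centred on CpGs: ``[pos - flank, pos + flank + 1)``,
    clipped at chromosome bounds (length 2*flank+1 when unclipped)."""
    pos = manifest.positions(probes)
    regions = []
    for probe, row in pos.iterrows():
        start = max(0, int(row["pos"]) - flank)
        end = int(row["pos"]) + flank + 1
        if chrom_sizes is not None and row["chrom"] in chrom_sizes:
            end = min(end, chrom_sizes[row["chrom"]])
        regions.append(GenomicInterval(row["chrom"], start, end, name=probe))
    return RegionSet(name=name, regions=regions)


def gc_content(regions: Sequence[GenomicInterval], fasta_path: str) -> np.ndarray:
    """(G+C) / region length per region, case-insensitive; ambiguous bases
    count in the denominator only (the bedtools-nuc convention)."""
    from pyfaidx import Fasta

    fa = Fasta(fasta_path)
    out = np.empty(len(regions))
    for i, r in enumerate(regions):
        if r.chrom not in fa:
            raise KeyError(f"contig {r.chrom!r} absent from {fasta_path}")
        if r.end > len(fa[r.chrom]):
            raise ValueError(f"region {r.chrom}:{r.start}-{r.end} beyond contig end")
        seq = str(fa[r.chrom][r.start : r.end]).upper()
        out[i] = (seq.count("G") + seq.count("C")) / len(seq)
    return out


def differential_tfbs_enrichment(
    foreground: RegionSet, other: RegionSet, tfbs: TFBSCollection
) -> pd.DataFrame:
    """Two-set differential TFBS enrichment.

    The universe is ``foreground ∪ other``; for each TFBS set a region counts
    as supported when it shares >= 1 bp with a binding site. One-sided Fisher
    p (foreground enriched) via the hypergeometric tail; odds ratios use the
    Haldane 0.5 correction when a zero cell occurs; BH adjustment across TFBS
    sets; rows sorted by (p, -odds_ratio).
    """
    if foreground.keys() & other.keys():
        raise ValueError("foreground and other region sets must be disjoint")

    def support(regions: list[GenomicInterval], index: IntervalIndex) -> int:
        count = 0
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, rs in by_chrom.items():
            starts = np.array([r.start for r in rs])
            ends = np.array([r.end for r in rs])
            count += int(index.overlaps_regions(chrom, starts, ends).sum())
        return count

    n_fg, n_ot = len(foreground), len(other)
    rows = []
    for tf in tfbs.tf_names:
        if tfbs.n_sites(tf) == 0:
            rows.append((tf, 0, n_fg, 0, n_ot, np.nan, 1.0))
            continue
        index = tfbs.index(tf)
        a = support(foreground.regions, index)
        c = support(other.regions, index)
        b, d = n_fg - a, n_ot - c
        if min(a, b, c, d) == 0:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c)
        p = hypergeom_tail(a, population=n_fg + n_ot, successes=a + c, draws=n_fg)
        rows.append((tf, a, b, c, d, odds, p))
    df = pd.DataFrame(rows, columns=["tfbs_set", "a", "b", "c", "d", "odds_ratio", "p"])
    df["p_adjusted"] = bh_adjust(df["p"].to_numpy())
    df = df.sort_values(["p", "odds_ratio"], ascending=[True, False], kind="mergesort")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Genomic context

PROMOTER_UPSTREAM = 1000  # HOMER-style promoter window around the TSS
PROMOTER_DOWNSTREAM = 100
CATEGORIES = ["promoter", "exon", "intron", "intergenic"]


def annotate_genomic_context(
    probes: Sequence[str], manifest: CpGManifest, annotation: GeneAnnotation
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each CpG a genomic category with precedence
    promoter > exon > intron > intergenic.

    Promoter: strand-aware TSS window (-1000 .. +100). Returns the per-CpG
    category and a count/fraction distribution table.
    """
    pos = manifest.positions(probes)
    genes = annotation.df
    exon_index: dict[str, IntervalIndex] = {}
    exon_ivs = [iv for g in annotation.exons for iv in annotation.exons[g]]
    if exon_ivs:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in exon_ivs:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        exon_index = {c: IntervalIndex(ivs) for c, ivs in by_chrom.items()}

    categories = []
    for probe, row in pos.iterrows():
        chrom, q = row["chrom"], int(row["pos"])
        sub = genes[genes["chrom"] == chrom]
        offset = np.where(sub["strand"] == "+", q - sub["tss"], sub["tss"] - q)
        if np.any((offset >= -PROMOTER_UPSTREAM) & (offset <= PROMOTER_DOWNSTREAM)):
            categories.append("promoter")
            continue
        in_body = (sub["start"] <= q) & (q < sub["end"])
        if in_body.any():
            in_exon = chrom in exon_index and bool(
                exon_index[chrom].overlaps_points(chrom, np.array([q]))[0]
            )
            categories.append("exon" if in_exon else "intron")
        else:
            categories.append("intergenic")
    cats = pd.Series(categories, index=pos.index, name="category")
    counts = cats.value_counts().reindex(CATEGORIES, fill_value=0)
    dist = pd.DataFrame({"count": counts, "fraction": counts / max(len(cats), 1)})
    return cats, dist


def list_overlap_fisher(
    set_a: Iterable[str], set_b: Iterable[str], universe_size: int
) -> tuple[int, float, float]:
    """Fisher/hypergeometric overlap test between two item lists.

    ``universe_size`` is deliberately a required argument: the result depends
    strongly on it and no default is defensible.

    Returns (overlap, odds_ratio, one-sided p = P(X >= overlap)).
    """
    a, b = set(set_a), set(set_b)
    if universe_size < len(a | b):
        raise ValueError("universe smaller than the union of the two sets")
    k = len(a & b)
    n_a, n_b = len(a), len(b)
    t11 = k
    t12 = n_a - k
    t21 = n_b - k
    t22 = universe_size - n_a - n_b + k
    if min(t11, t12, t21, t22) == 0:
        odds = ((t11 + 0.5) * (t22 + 0.5)) / ((t12 + 0.5) * (t21 + 0.5))
    else:
        odds = (t11 * t22) / (t12 * t21)
    p = hypergeom_tail(k, population=universe_size, successes=n_b, draws=n_a)
    return k, float(odds), p
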