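"""Genomic-context features of NUPTs: flanking genes/TEs, nearest genes, GC.

The published analyses relate NUPT methylation to the composition of the
surrounding genome: the number of genes within 50 kb on each side (100 kb
total), the number of transposable elements within 5 kb on each side (10 kb
total), the distance to the nearest gene, and the GC content of the NUPT
versus its flanks.  Associations with methylation are quantified with
Pearson's correlation and its two-sided t-test p-value.

Annotations are consumed as GFF3 (1-based inclusive, converted on parsing)
or BED (already 0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .divergence import gc_content

__all__ = [
    "AnnotationTrack",
    "count_in_flanks",
    "nearest_gene_distance",
    "pearson_correlation",
    "flank_gc_profile",
]


@dataclass
class AnnotationTrack:
    """A sorted list of typed genomic intervals (0-based half-open)."""

    intervals: list[tuple[str, int, int, str, str]] = field(default_factory=list)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        for chrom, start, end, _strand, _type in self.intervals:
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
        self.intervals = sorted(self.intervals, key=lambda iv: (iv[0], iv[1], iv[2]))

    def __len__(self) -> int:
        return len(self.intervals)

    def tree(self, chrom: str) -> IntervalTree:
        if chrom not in self._trees:
            self._trees[chrom] = IntervalTree.from_tuples(
                (s, e, i)
                for i, (c, s, e, _st, _ty) in enumerate(self.intervals)
                if c == chrom
            )
        return self._trees[chrom]

    @classmethod
    def from_gff3(cls, path, feature_types: Sequence[str] = ("gene",)) -> "AnnotationTrack":
        """Load features of the given GFF3 types (coordinates converted to
        0-based half-open)."""
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        wanted = set(feature_types)
        intervals = []
        for ftype in wanted:
            for feat in db.features_of_type(ftype):
                kind = "gene" if ftype == "gene" else "TE"
                intervals.append(
                    (feat.seqid, feat.start - 1, feat.end, feat.strand or ".", kind)
                )
        return cls(intervals)

    @classmethod
    def from_bed(cls, path, feature_type: str = "TE") -> "AnnotationTrack":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        intervals = []
        for row in df.itertuples(index=False):
            chrom, start, end = str(row[0]), int(row[1]), int(row[2])
            strand = str(row[5]) if len(row) > 5 else "."
            intervals.append((chrom, start, end, strand, feature_type))
        return cls(intervals)


def count_in_flanks(
    nupt: tuple[str, int, int],
    track: AnnotationTrack,
    flank_bp: int,
    *,
    chrom_length: int | None = None,
) -> int:
    """Number of track intervals overlapping the two flank windows by >= 1 bp.

    The windows are ``[start - flank, start)`` and ``[end, end + flank)``,
    truncated at chromosome ends; an interval touching both windows counts
    once, and an interval lying entirely inside the NUPT counts zero.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    chrom, start, end = nupt
    windows = []
    lo = max(0, start - flank_bp)
    if lo < start:
        windows.append((lo, start))
    hi = end + flank_bp if chrom_length is None else min(end + flank_bp, chrom_length)
    if end < hi:
        windows.append((end, hi))
    seen: set[int] = set()
    tree = track.tree(chrom)
    for s, e in windows:
        for iv in tree.overlap(s, e):
            seen.add(iv.data)
    return len(seen)


def nearest_gene_distance(
    nupt: tuple[str, int, int], track: AnnotationTrack
) -> int | None:
    """Gap distance from the NUPT to the nearest gene on its chromosome.

    Zero when a gene overlaps the NUPT; ``None`` when the chromosome carries
    no genes at all.
    """
    chrom, start, end = nupt
    best: int | None = None
    for c, gs, ge, _strand, _type in track.intervals:
        if c != chrom:
            continue
        if ge <= start:
            d = start - ge
        elif gs >= end:
            d = gs - end
        else:
            d = 0
        if best is None or d < best:
            best = d
            if best == 0:
                break
    return best


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-test p-value.

    Pairs with a missing value (None/NaN) on either side are dropped.  The
    p-value tests rho = 0 via ``t = rho * sqrt((n-2)/(1-rho^2))`` against a
    t distribution with n-2 degrees of freedom.  Requires n >= 3 retained
    pairs and non-degenerate variance in both variables.
    """
    pairs = [
        (float(a), float(b))
        for a, b in zip(x, y)
        if a is not None and b is not None
        and not (np.isnan(float(a)) or np.isnan(float(b)))
    ]
    if len(pairs) < 3:
        raise ValueError("Pearson correlation requires >= 3 complete pairs")
    xs = np.array([p[0] for p in pairs])
    ys = np.array([p[1] for p in pairs])
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    res = stats.pearsonr(xs, ys)
    return float(res.statistic), float(res.pvalue)


def flank_gc_profile(
    nupt: tuple[str, int, int],
    genome: Mapping[str, str],
    flank_bp: int,
) -> tuple[float, float]:
    """GC fraction of the NUPT sequence and of its pooled flanks.

    Flanks are truncated at chromosome ends; a NUPT at a chromosome edge is
    profiled against the one available flank.  Raises ``ValueError`` when a
    region contains no countable base.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    chrom, start, end = nupt
    seq = genome[chrom]
    nupt_gc = gc_content(seq[start:end])
    flank_seq = seq[max(0, start - flank_bp) : start] + seq[end : end + flank_bp]
    return nupt_gc, gc_content(flank_seq)
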