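"""NUPT discovery: homology hits, the published filter cascade, assembly.

A NUPT candidate is a pairwise alignment between the plastid genome (query)
and the nuclear genome (subject).  Candidates come either from BLASTN tabular
output (``-outfmt "6 std qseq sseq"``) or from the built-in seed-and-extend
aligner used on synthetic genomes.  The filter cascade mirrors the published
procedure:

* ``short``          — gap-free aligned length < 100 bp;
* ``diverged``       — AT-transversion distance d_AT > 0.06;
* ``duplicate``      — identical or fully contained nuclear intervals;
* ``ambiguous_mito`` — the plastid side overlaps a plastid region that is
  itself similar to the mitochondrial genome, so the hit's organellar origin
  is ambiguous.

Unflagged hits become ``NuptRecord``s carrying their substitution spectrum,
d_AT and age bin.  All internal coordinates are 0-based half-open; BLAST's
1-based inclusive coordinates are converted at the parsing boundary, and
minus-strand subject hits are normalized so the stored nuclear string is
always the plus strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, TextIO

from . import divergence
from .divergence import (
    SubstitutionSpectrum,
    assign_age_bin,
    at_transversion_distance,
    count_substitutions,
    reverse_complement,
)

__all__ = [
    "HomologyHit",
    "NuptRecord",
    "parse_homology_hits",
    "write_homology_hits",
    "naive_local_align",
    "filter_length",
    "filter_distance",
    "dedupe_hits",
    "find_mito_similar_regions",
    "flag_mito_ambiguous",
    "assemble_nupt_set",
]

logger = logging.getLogger(__name__)

FLAGS = ("short", "diverged", "ambiguous_mito", "duplicate")


@dataclass
class HomologyHit:
    """One plastid <-> nuclear aligned pair, nuclear side on the plus strand.

    ``nuclear_strand`` records the orientation of the plastid match: '-'
    means the nuclear plus strand aligns to the reverse complement of the
    plastid interval.  ``aligned_plastid_seq`` is stored in that same
    orientation so the two gapped strings pair column by column.
    """

    nuclear_chrom: str
    nuclear_start: int
    nuclear_end: int
    nuclear_strand: str
    plastid_start: int
    plastid_end: int
    aligned_plastid_seq: str
    aligned_nuclear_seq: str
    percent_identity: float
    score: float
    flags: set[str] = field(default_factory=set)
    _spectrum: SubstitutionSpectrum | None = field(
        default=None, repr=False, compare=False
    )

    def validate(self) -> None:
        if len(self.aligned_plastid_seq) != len(self.aligned_nuclear_seq):
            raise ValueError("gapped strings differ in length")
        if self.nuclear_start >= self.nuclear_end:
            raise ValueError("nuclear interval empty or inverted")
        n_len = len(self.aligned_nuclear_seq.replace("-", ""))
        p_len = len(self.aligned_plastid_seq.replace("-", ""))
        if n_len != self.nuclear_end - self.nuclear_start:
            raise ValueError("nuclear coordinates inconsistent with alignment")
        if p_len != self.plastid_end - self.plastid_start:
            raise ValueError("plastid coordinates inconsistent with alignment")

    @property
    def spectrum(self) -> SubstitutionSpectrum:
        if self._spectrum is None:
            self._spectrum = count_substitutions(
                self.aligned_plastid_seq, self.aligned_nuclear_seq
            )
        return self._spectrum

    @property
    def aligned_gap_free_length(self) -> int:
        return self.spectrum.l_align

    def d_at(self) -> float:
        return at_transversion_distance(self.spectrum)


@dataclass
class NuptRecord:
    """A filtered NUPT with its spectrum, relative age and age bin."""

    nupt_id: str
    hit: HomologyHit
    spectrum: SubstitutionSpectrum
    d_at: float
    age_bin: str


# ---------------------------------------------------------------------------
# BLAST tabular I/O
# ---------------------------------------------------------------------------

_STD_COLUMNS = 12  # qseqid sseqid pident length mismatch gapopen qstart qend
#                    sstart send evalue bitscore, then qseq sseq


def parse_homology_hits(
    stream: TextIO | Iterable[str], *, strict: bool = False
) -> list[HomologyHit]:
    """Parse BLAST tabular rows with aligned sequences (outfmt "6 std qseq sseq").

    The query is the plastid genome, the subject the nuclear genome.  1-based
    inclusive coordinates become 0-based half-open.  Subject rows with
    sstart > send are minus-strand matches: they are normalized to the plus
    strand (``nuclear_strand = '-'``, both gapped strings reverse
    complemented).  Percent identity is recomputed from the aligned strings
    (matching columns / total columns); the bit score column is kept as the
    hit score.  Malformed rows raise in strict mode and are skipped with a
    warning otherwise.
    """
    hits = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        try:
            if len(fields) < _STD_COLUMNS + 2:
                raise ValueError(f"expected >= {_STD_COLUMNS + 2} columns, got {len(fields)}")
            (_qid, sid, _pident, _length, _mm, _gapopen,
             qstart, qend, sstart, send, _evalue, bitscore) = fields[:_STD_COLUMNS]
            qseq, sseq = fields[_STD_COLUMNS], fields[_STD_COLUMNS + 1]
            qseq, sseq = qseq.upper(), sseq.upper()
            if len(qseq) != len(sseq):
                raise ValueError("aligned strings of unequal length")
            qstart, qend = int(qstart), int(qend)
            sstart, send = int(sstart), int(send)
            if qstart > qend:
                raise ValueError("query coordinates reversed")
            if sstart <= send:
                strand = "+"
                n_start, n_end = sstart - 1, send
            else:
                strand = "-"
                n_start, n_end = send - 1, sstart
                qseq = reverse_complement(qseq)
                sseq = reverse_complement(sseq)
            spec = count_substitutions(qseq, sseq)
            hit = HomologyHit(
                nuclear_chrom=sid,
                nuclear_start=n_start,
                nuclear_end=n_end,
                nuclear_strand=strand,
                plastid_start=qstart - 1,
                plastid_end=qend,
                aligned_plastid_seq=qseq,
                aligned_nuclear_seq=sseq,
                percent_identity=spec.matches / len(qseq) if qseq else 0.0,
                score=float(bitscore),
            )
            hit.validate()
        except (ValueError, IndexError) as exc:
            if strict:
                raise ValueError(f"line {lineno}: {exc}") from exc
            logger.warning("skipping malformed hit line %d: %s", lineno, exc)
            continue
        hits.append(hit)
    return hits


def write_homology_hits(
    hits: Sequence[HomologyHit], stream: TextIO, *, query_id: str = "plastid"
) -> None:
    """Write hits as BLAST tabular outfmt "6 std qseq sseq" (round-trips
    through ``parse_homology_hits``)."""
    for h in hits:
        qseq, sseq = h.aligned_plastid_seq, h.aligned_nuclear_seq
        if h.nuclear_strand == "-":
            # restore BLAST's subject-descending representation
            qseq, sseq = reverse_complement(qseq), reverse_complement(sseq)
            sstart, send = h.nuclear_end, h.nuclear_start + 1
        else:
            sstart, send = h.nuclear_start + 1, h.nuclear_end
        spec = h.spectrum
        cols = len(h.aligned_plastid_seq)
        mism = spec.n_substitutions
        gapopen = sum(
            1
            for i in range(cols)
            if ("-" in (h.aligned_plastid_seq[i], h.aligned_nuclear_seq[i]))
            and (i == 0 or "-" not in (h.aligned_plastid_seq[i - 1], h.aligned_nuclear_seq[i - 1]))
        )
        row = [
            query_id, h.nuclear_chrom,
            f"{100.0 * h.percent_identity:.3f}", str(cols), str(mism), str(gapopen),
            str(h.plastid_start + 1), str(h.plastid_end),
            str(sstart), str(send),
            "0.0", f"{h.score:g}",
            qseq, sseq,
        ]
        stream.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Built-in seed-and-extend aligner (gapless; for simulator output)
# ---------------------------------------------------------------------------


def _extend_ungapped(
    a: str, b: str, a_start: int, a_end: int, b_start: int, b_end: int,
    match: int, mismatch: int, xdrop: int,
) -> tuple[int, int]:
    """Extend an exact seed on both sides with X-drop; return offsets
    (left, right) such that the extended segment on ``a`` is
    [a_start - left, a_end + right) and correspondingly on ``b``."""
    # rightward
    best = cur = 0
    right = 0
    i, j = a_end, b_end
    step = 0
    while i < len(a) and j < len(b):
        cur += match if a[i] == b[j] else mismatch
        step += 1
        if cur > best:
            best, right = cur, step
        elif best - cur > xdrop:
            break
        i += 1
        j += 1
    # leftward
    best = cur = 0
    left = 0
    i, j = a_start - 1, b_start - 1
    step = 0
    while i >= 0 and j >= 0:
        cur += match if a[i] == b[j] else mismatch
        step += 1
        if cur > best:
            best, left = cur, step
        elif best - cur > xdrop:
            break
        i -= 1
        j -= 1
    return left, right


def naive_local_align(
    plastid: str,
    nuclear_genome: Mapping[str, str],
    k: int = 11,
    min_len: int = 100,
    *,
    match: int = 1,
    mismatch: int = -1,
    xdrop: int = 30,
    merge_gap: int = 200,
) -> list[HomologyHit]:
    """Gapless seed-and-extend homology search of the plastid against a genome.

    Exact ``k``-mer seeds (both orientations) are extended without gaps using
    an X-drop criterion and trimmed back to the maximal-score endpoints;
    co-diagonal segments separated by at most ``merge_gap`` bp are merged into
    one gapless alignment (legitimate because same-diagonal segments share the
    plastid/nuclear offset).  Suited to simulator output, which contains no
    indels; real genomes should use BLASTN and ``parse_homology_hits``.

    Only hits with gap-free aligned length >= ``min_len`` are emitted.
    """
    if k < 8:
        raise ValueError("seed length k must be >= 8")
    plastid = plastid.upper()
    plen = len(plastid)
    rc_plastid = reverse_complement(plastid)

    index: dict[str, list[tuple[str, int]]] = {}
    for strand, seq in (("+", plastid), ("-", rc_plastid)):
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((strand, i))

    hits: list[HomologyHit] = []
    for chrom in sorted(nuclear_genome):
        seq = nuclear_genome[chrom].upper()
        # seeds grouped by (strand, diagonal); diag = nuclear_pos - plastid_pos
        # (plastid position in rc coordinates for '-' seeds)
        segments: dict[tuple[str, int], list[tuple[int, int]]] = {}
        covered: dict[tuple[str, int], int] = {}
        for npos in range(len(seq) - k + 1):
            entry = index.get(seq[npos : npos + k])
            if not entry:
                continue
            for strand, ppos in entry:
                key = (strand, npos - ppos)
                if npos < covered.get(key, 0):
                    continue  # inside a previous extension on this diagonal
                ref = plastid if strand == "+" else rc_plastid
                left, right = _extend_ungapped(
                    ref, seq, ppos, ppos + k, npos, npos + k, match, mismatch, xdrop
                )
                seg = (npos - left, npos + k + right)
                segments.setdefault(key, []).append(seg)
                covered[key] = seg[1]
        for (strand, diag), segs in segments.items():
            segs.sort()
            merged = [list(segs[0])]
            for s, e in segs[1:]:
                if s - merged[-1][1] <= merge_gap:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            ref = plastid if strand == "+" else rc_plastid
            for n_start, n_end in merged:
                r_start, r_end = n_start - diag, n_end - diag
                aligned_n = seq[n_start:n_end]
                aligned_p = ref[r_start:r_end]
                matches = sum(1 for x, y in zip(aligned_p, aligned_n) if x == y)
                length = n_end - n_start
                if length < min_len:
                    continue
                if strand == "+":
                    p_start, p_end = r_start, r_end
                else:
                    p_start, p_end = plen - r_end, plen - r_start
                hits.append(
                    HomologyHit(
                        nuclear_chrom=chrom,
                        nuclear_start=n_start,
                        nuclear_end=n_end,
                        nuclear_strand=strand,
                        plastid_start=p_start,
                        plastid_end=p_end,
                        aligned_plastid_seq=aligned_p,
                        aligned_nuclear_seq=aligned_n,
                        percent_identity=matches / length,
                        score=float(match * matches + mismatch * (length - matches)),
                    )
                )
    hits.sort(key=lambda h: (h.nuclear_chrom, h.nuclear_start, h.nuclear_end))
    return hits


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------


def filter_length(hits: Sequence[HomologyHit], min_len: int = 100) -> list[HomologyHit]:
    """Flag hits whose gap-free aligned length is below ``min_len`` as ``short``.

    Length is measured on gap-free unambiguous columns (the same L_align that
    d_AT divides by), so gap columns never count toward the 100-bp rule.
    """
    for h in hits:
        if h.aligned_gap_free_length < min_len:
            h.flags.add("short")
    return list(hits)


def filter_distance(hits: Sequence[HomologyHit], max_d: float = 0.06) -> list[HomologyHit]:
    """Flag hits with d_AT strictly greater than ``max_d`` as ``diverged``.

    A hit at exactly the cutoff is kept.  Hits with zero gap-free aligned
    length (d_AT undefined, no basis for claiming homology) are also flagged.
    """
    for h in hits:
        if h.spectrum.l_align == 0 or h.d_at() > max_d:
            h.flags.add("diverged")
    return list(hits)


def dedupe_hits(hits: Sequence[HomologyHit]) -> list[HomologyHit]:
    """Flag redundant hits as ``duplicate``.

    Among hits with identical nuclear intervals only the best by
    (score desc, start asc, end asc, plastid_start asc) survives; a hit whose
    nuclear interval is fully contained in another hit's interval with a
    score >= its own is also flagged.  Partially overlapping hits are all
    kept.  This replaces the published manual inspection with a deterministic
    rule.
    """
    order = sorted(
        hits,
        key=lambda h: (h.nuclear_chrom, -h.score, h.nuclear_start, h.nuclear_end, h.plastid_start),
    )
    accepted: dict[str, list[HomologyHit]] = {}
    for h in order:
        chrom_acc = accepted.setdefault(h.nuclear_chrom, [])
        dup = False
        for g in chrom_acc:
            same = (g.nuclear_start == h.nuclear_start and g.nuclear_end == h.nuclear_end)
            contained = (
                g.nuclear_start <= h.nuclear_start
                and h.nuclear_end <= g.nuclear_end
                and not same
            )
            if same or (contained and g.score >= h.score):
                dup = True
                break
        if dup:
            h.flags.add("duplicate")
        else:
            chrom_acc.append(h)
    return list(hits)


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s < out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def find_mito_similar_regions(
    plastid: str | None,
    mitochondrial: str | None,
    *,
    hits: Sequence[HomologyHit] | None = None,
    k: int = 12,
    min_len: int = 100,
) -> list[tuple[int, int]]:
    """Plastid intervals similar to the mitochondrial genome.

    Runs the built-in aligner between the two organellar genomes (or consumes
    pre-parsed hits whose *nuclear* side is the plastid) and returns the
    merged plastid-side intervals of all hits passing the ``min_len`` rule.
    With no mitochondrial genome the list is empty and downstream ambiguity
    filtering becomes a no-op, matching how species without a sequenced
    mitochondrial genome are handled.
    """
    if hits is None:
        if not mitochondrial or not plastid:
            return []
        hits = naive_local_align(
            mitochondrial, {"plastid": plastid}, k=k, min_len=min_len
        )
    qualifying = [
        (h.nuclear_start, h.nuclear_end)
        for h in hits
        if h.aligned_gap_free_length >= min_len
    ]
    return _merge_intervals(qualifying)


def flag_mito_ambiguous(
    hits: Sequence[HomologyHit], mito_intervals: Sequence[tuple[int, int]]
) -> list[HomologyHit]:
    """Flag hits whose plastid interval overlaps a mito-similar plastid
    interval by >= 1 bp (half-open adjacency does not count)."""
    if not mito_intervals:
        return list(hits)
    for h in hits:
        for s, e in mito_intervals:
            if h.plastid_start < e and s < h.plastid_end:
                h.flags.add("ambiguous_mito")
                break
    return list(hits)


def assemble_nupt_set(
    hits: Sequence[HomologyHit],
    *,
    edges: Sequence[tuple[float, float]] = divergence.AGE_BIN_EDGES,
    labels: Sequence[str] = divergence.AGE_BIN_LABELS,
    id_prefix: str = "nupt",
) -> list[NuptRecord]:
    """Turn the unflagged hits into the final NUPT set.

    Records carry the substitution spectrum, d_AT and age bin, are stably
    sorted by nuclear coordinates and numbered ``nupt_1..n`` in that order.
    Assumes the filter cascade has already run (every surviving hit must have
    a defined, binnable d_AT).
    """
    kept = [h for h in hits if not h.flags]
    kept.sort(key=lambda h: (h.nuclear_chrom, h.nuclear_start, h.nuclear_end))
    records = []
    for i, h in enumerate(kept, 1):
        d = h.d_at()
        records.append(
            NuptRecord(
                nupt_id=f"{id_prefix}_{i}",
                hit=h,
                spectrum=h.spectrum,
                d_at=d,
                age_bin=assign_age_bin(d, edges, labels),
            )
        )
    return records
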