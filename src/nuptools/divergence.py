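"""Directional substitution spectra and divergence clocks for plastid-derived insertions.

Plastid genomes evolve slowly relative to plant nuclear genomes, so when a
plastid fragment (NUPT) is compared with its plastid counterpart, essentially
all observed differences are assumed to have arisen on the nuclear copy.  Each
aligned column therefore yields a *directed* substitution plastid -> nuclear.

Two statistics built on the spectrum drive the downstream analyses:

* ``d_AT``, the AT-transversion distance ``(N[A->T] + N[T->A]) / L_align`` —
  a relative age clock chosen because A<->T transversions are untouched by
  methylation-driven cytosine deamination (which inflates C->T / G->A).
* the transition ratio ``(N[T->C] + N[A->G]) / (N[C->T] + N[G->A])`` — values
  far below 1 indicate deamination-driven bias; values near 1 indicate a
  symmetric substitution process.

NUPTs are grouped into young / middle / old age bins on ``d_AT``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "BASES",
    "SUB_PAIRS",
    "AGE_BIN_EDGES",
    "AGE_BIN_LABELS",
    "PLOTTED_CATEGORIES",
    "SubstitutionSpectrum",
    "BinSummary",
    "count_substitutions",
    "at_transversion_distance",
    "transition_ratio",
    "gc_content",
    "assign_age_bin",
    "summarize_bins",
    "reverse_complement",
]

BASES = ("A", "C", "G", "T")
#: the 12 ordered pairs of distinct bases, plastid base first.
SUB_PAIRS = tuple((x, y) for x in BASES for y in BASES if x != y)

#: default age bins on d_AT: half-open, except the last bin which is closed
#: at the top so the 0.06 divergence cutoff itself still bins.
AGE_BIN_EDGES = ((0.00, 0.02), (0.02, 0.04), (0.04, 0.06))
AGE_BIN_LABELS = ("young", "middle", "old")

#: the four substitution classes plotted in bin summaries (strand-symmetric
#: pools).  A<->T and C<->G transversions are intentionally not plotted
#: classes, so plotted fractions sum to <= 1.
PLOTTED_CATEGORIES = {
    "CT_GA": (("C", "T"), ("G", "A")),  # deamination-type transitions
    "TC_AG": (("T", "C"), ("A", "G")),  # reverse transitions
    "CA_GT": (("C", "A"), ("G", "T")),
    "AC_TG": (("A", "C"), ("T", "G")),
}

_COMPLEMENT = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")


def reverse_complement(seq: str) -> str:
    """Reverse-complement, preserving gap characters and N."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SubstitutionSpectrum:
    """Directed substitution counts from one (or a pool of) pairwise alignments.

    ``counts[(x, y)]`` is the number of aligned columns with plastid base ``x``
    and nuclear base ``y`` (x != y).  Columns containing a gap on either side
    are tallied in ``skipped_gap``; columns with a non-ACGT character on either
    side in ``skipped_ambiguous``; neither kind enters ``l_align``.
    """

    counts: dict[tuple[str, str], int] = field(
        default_factory=lambda: {p: 0 for p in SUB_PAIRS}
    )
    matches: int = 0
    skipped_gap: int = 0
    skipped_ambiguous: int = 0

    @property
    def n_substitutions(self) -> int:
        return sum(self.counts.values())

    @property
    def l_align(self) -> int:
        """Gap-free, unambiguous aligned length (matches + substitutions)."""
        return self.matches + self.n_substitutions

    @property
    def total_columns(self) -> int:
        return self.l_align + self.skipped_gap + self.skipped_ambiguous

    def __add__(self, other: "SubstitutionSpectrum") -> "SubstitutionSpectrum":
        merged = {p: self.counts[p] + other.counts[p] for p in SUB_PAIRS}
        return SubstitutionSpectrum(
            counts=merged,
            matches=self.matches + other.matches,
            skipped_gap=self.skipped_gap + other.skipped_gap,
            skipped_ambiguous=self.skipped_ambiguous + other.skipped_ambiguous,
        )

    def __radd__(self, other):
        # allows sum(spectra) starting from 0
        if other == 0:
            return self
        return NotImplemented

    def as_flat_dict(self) -> dict[str, int]:
        """Counts keyed ``N_XY`` plus bookkeeping fields, for tabular output."""
        out = {f"N_{x}{y}": self.counts[(x, y)] for x, y in SUB_PAIRS}
        out["matches"] = self.matches
        out["skipped_gap"] = self.skipped_gap
        out["skipped_ambiguous"] = self.skipped_ambiguous
        return out

    @classmethod
    def from_flat_dict(cls, row: Mapping) -> "SubstitutionSpectrum":
        counts = {(x, y): int(row[f"N_{x}{y}"]) for x, y in SUB_PAIRS}
        return cls(
            counts=counts,
            matches=int(row["matches"]),
            skipped_gap=int(row["skipped_gap"]),
            skipped_ambiguous=int(row["skipped_ambiguous"]),
        )


def count_substitutions(aligned_plastid: str, aligned_nuclear: str) -> SubstitutionSpectrum:
    """Tally directed substitutions from a pairwise alignment.

    Lowercase input is normalized to uppercase.  Per column: a gap (``-``) on
    either side is skipped as a gap column; a character outside ACGT on either
    side (N, IUPAC ambiguity codes, ...) is skipped as ambiguous; equal bases
    count as a match; anything else increments ``counts[(plastid, nuclear)]``.

    Raises ``ValueError`` on unequal string lengths.
    """
    if len(aligned_plastid) != len(aligned_nuclear):
        raise ValueError(
            "aligned strings differ in length: "
            f"{len(aligned_plastid)} vs {len(aligned_nuclear)}"
        )
    a = aligned_plastid.upper()
    b = aligned_nuclear.upper()
    spec = SubstitutionSpectrum()
    counts = spec.counts
    bases = frozenset(BASES)
    matches = gaps = ambiguous = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            gaps += 1
        elif x not in bases or y not in bases:
            ambiguous += 1
        elif x == y:
            matches += 1
        else:
            counts[(x, y)] += 1
    spec.matches = matches
    spec.skipped_gap = gaps
    spec.skipped_ambiguous = ambiguous
    return spec


def at_transversion_distance(spectrum: SubstitutionSpectrum) -> float:
    """``d_AT = (N[A->T] + N[T->A]) / L_align``.

    Insensitive to the methylation-coupled C->T / G->A excess, hence used as
    the relative integration-age clock.  Undefined (``ValueError``) when the
    gap-free aligned length is zero.
    """
    if spectrum.l_align == 0:
        raise ValueError("d_AT undefined: gap-free aligned length is zero")
    n_at = spectrum.counts[("A", "T")] + spectrum.counts[("T", "A")]
    return n_at / spectrum.l_align


def transition_ratio(spectrum: SubstitutionSpectrum) -> float:
    """``(N[T->C] + N[A->G]) / (N[C->T] + N[G->A])``.

    Raises ``ValueError`` when the denominator is zero (callers report NA).
    """
    num = spectrum.counts[("T", "C")] + spectrum.counts[("A", "G")]
    den = spectrum.counts[("C", "T")] + spectrum.counts[("G", "A")]
    if den == 0:
        raise ValueError("transition ratio undefined: no C->T / G->A transitions")
    return num / den


def gc_content(sequence: str) -> float:
    """GC fraction over unambiguous bases; gaps and non-ACGT are excluded."""
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    total = gc + at
    if total == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return gc / total


def assign_age_bin(
    d_at: float,
    edges: Sequence[tuple[float, float]] = AGE_BIN_EDGES,
    labels: Sequence[str] = AGE_BIN_LABELS,
) -> str:
    """Map a d_AT value onto an age-bin label.

    Bins are half-open ``[lo, hi)`` except the last, which is closed at its
    upper edge so the divergence cutoff value itself is still binnable.
    """
    if len(edges) != len(labels):
        raise ValueError("edges and labels differ in length")
    if d_at < edges[0][0]:
        raise ValueError(f"d_AT {d_at} below first bin")
    for (lo, hi), label in zip(edges, labels):
        if lo <= d_at < hi:
            return label
    if d_at == edges[-1][1]:
        return labels[-1]
    raise ValueError(f"d_AT {d_at} above last bin edge {edges[-1][1]}")


@dataclass
class BinSummary:
    """Pooled per-age-bin spectrum with the plotted summary statistics.

    ``transition_ratio`` and ``category_fractions`` are computed on pooled
    counts (the bin-level substitution totals), not averaged per NUPT, and are
    ``None`` when undefined (empty bin / zero denominator).
    """

    label: str
    n_nupts: int
    spectrum: SubstitutionSpectrum
    transition_ratio: float | None
    category_fractions: dict[str, float] | None
    mean_gc_nupt: float | None
    mean_gc_plastid: float | None


def _record_gc(record, nuclear_seqs, plastid_seq) -> tuple[float, float] | None:
    hit = record.hit
    if nuclear_seqs is not None and plastid_seq is not None:
        nupt = nuclear_seqs[hit.nuclear_chrom][hit.nuclear_start : hit.nuclear_end]
        plas = plastid_seq[hit.plastid_start : hit.plastid_end]
    elif hit.aligned_nuclear_seq and hit.aligned_plastid_seq:
        nupt = hit.aligned_nuclear_seq.replace("-", "")
        plas = hit.aligned_plastid_seq.replace("-", "")
    else:
        return None
    try:
        return gc_content(nupt), gc_content(plas)
    except ValueError:
        return None


def summarize_bins(
    records: Sequence,
    *,
    nuclear_seqs: Mapping[str, str] | None = None,
    plastid_seq: str | None = None,
    labels: Sequence[str] = AGE_BIN_LABELS,
) -> list[BinSummary]:
    """Pool NUPT spectra per age bin and derive the plotted statistics.

    ``records`` are objects carrying ``age_bin``, ``spectrum`` and ``hit``
    (see ``nuptools.discovery.NuptRecord``).  GC contents are taken from the
    provided genome sequences when given, otherwise from the records' own
    aligned (ungapped) strings.  Empty bins yield ``n_nupts == 0`` summaries
    with ``None`` statistics.
    """
    out = []
    for label in labels:
        members = [r for r in records if r.age_bin == label]
        pooled = sum((r.spectrum for r in members), SubstitutionSpectrum())
        ratio = None
        fractions = None
        if members:
            try:
                ratio = transition_ratio(pooled)
            except ValueError:
                ratio = None
            nsub = pooled.n_substitutions
            if nsub > 0:
                fractions = {}
                for name, pairs in PLOTTED_CATEGORIES.items():
                    fractions[name] = sum(pooled.counts[p] for p in pairs) / nsub
        gcs = [
            g
            for r in members
            if (g := _record_gc(r, nuclear_seqs, plastid_seq)) is not None
        ]
        mean_gc_nupt = sum(g[0] for g in gcs) / len(gcs) if gcs else None
        mean_gc_plastid = sum(g[1] for g in gcs) / len(gcs) if gcs else None
        out.append(
            BinSummary(
                label=label,
                n_nupts=len(members),
                spectrum=pooled,
                transition_ratio=ratio,
                category_fractions=fractions,
                mean_gc_nupt=mean_gc_nupt,
                mean_gc_plastid=mean_gc_plastid,
            )
        )
    return out
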