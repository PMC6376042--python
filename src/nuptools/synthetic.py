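"""Synthetic genomes with plastid insertions of known age, plus methylomes.

The generator encodes the mutational/epigenetic model the analysis pipeline
is built to detect, with complete ground truth:

* a plastid-like genome and a nuclear genome, i.i.d. bases at configurable
  GC content;
* NUPT insertions copied from the plastid (possibly reverse-complemented)
  into non-overlapping nuclear loci, each with a true age ``a`` expressed in
  d_AT units;
* a neutral substitution clock: every directed base change X->Y receives
  probability ``basal_rate * a`` per site (at most one substitution per
  site), calibrated so that the expected d_AT of an insertion equals its age
  at the default base composition;
* methylation-coupled deamination: each cytosine (either strand) carries an
  *extra* C->T (G->A on the plus strand for minus-strand cytosines) chance
  ``deamination_rate * a * m_bar``, with ``m_bar`` the cytosine's
  time-averaged methylation over the insertion's lifetime — this creates the
  C/G -> T/A excess that decays as methylation decays;
* per-context methylation decaying exponentially from an initial level m0
  toward the flanking background: ``m(a) = flank + (m0 - flank) e^(-lambda a)``;
* bisulfite-style per-cytosine read counts: Poisson coverage, binomial
  methylated counts with a symmetric conversion-error floor;
* gene and TE annotation tracks, with optional TE enrichment near a subset
  of insertions whose methylation is boosted in step (to plant a detectable
  TE-methylation correlation);
* a simulated hypomethylation mutant: NUPT methylation multiplied by a
  per-context factor, flanks untouched.

All randomness flows from one seed through ``numpy``'s ``SeedSequence``;
identical configs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import methylome
from .divergence import reverse_complement
from .methylome import CONTEXTS, MethylationTable

__all__ = [
    "SimulationConfig",
    "Substitution",
    "Insertion",
    "SyntheticTruth",
    "SimulationResult",
    "simulate_plastid_genome",
    "insert_nupts",
    "mutate_segment",
    "segment_mean_methylation",
    "current_methylation",
    "time_averaged_methylation",
    "expected_d_at",
    "simulate_methylome",
    "simulate_annotations",
    "simulate_dataset",
    "write_fasta",
    "read_fasta",
    "write_bed",
    "write_gff3",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i
# base code -> the 3 alternative base codes, in ACGT order
_TARGETS = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]], dtype=np.int8)
# slot index of the deamination product: C (code 1) -> T is slot 2;
# G (code 2) -> A is slot 0
_DEAM_SLOT = {1: 2, 2: 0}


def _per_context(value, name: str) -> dict[str, float]:
    """Broadcast a scalar to all three contexts; validate dict keys."""
    if isinstance(value, Mapping):
        missing = [c for c in CONTEXTS if c not in value]
        if missing:
            raise ValueError(f"{name} missing contexts: {missing}")
        return {c: float(value[c]) for c in CONTEXTS}
    return {c: float(value) for c in CONTEXTS}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Ages are in d_AT units (the AT-transversion clock of the analysis), so
    ``age_range`` defaults to the binnable [0, 0.06].  ``basal_rate`` is the
    per-site, per-directed-change substitution probability per age unit; the
    default 1.5625 makes E[d_AT] equal the true age at the default 36% GC
    composition (1 / (f_A + f_T) with f_A + f_T = 0.64).  Methylation
    parameters are per-context mappings (scalars broadcast).
    """

    seed: int = 1
    plastid_length: int = 120_000
    plastid_gc: float = 0.36
    n_chromosomes: int = 2
    chromosome_lengths: Sequence[int] = (450_000, 450_000)
    nuclear_gc: float = 0.36
    n_insertions: int = 300
    insertion_length_range: tuple[int, int] = (150, 2000)
    age_range: tuple[float, float] = (0.0, 0.06)
    basal_rate: float = 1.5625
    deamination_rate: float = 20.0
    meth_init: Mapping[str, float] | float = field(
        default_factory=lambda: {"CpG": 0.85, "CpHpG": 0.60, "CpHpH": 0.30}
    )
    meth_decay: Mapping[str, float] | float = 50.0
    flank_meth: Mapping[str, float] | float = field(
        default_factory=lambda: {"CpG": 0.08, "CpHpG": 0.04, "CpHpH": 0.02}
    )
    coverage_mean: float = 20.0
    conversion_error: float = 0.005
    gene_density: float = 23.0  # genes per 100 kb
    te_density: float = 2.0  # TEs per 10 kb
    mutant_effect: Mapping[str, float] | float = 0.2
    te_enrichment_factor: float = 3.0
    te_enriched_fraction: float = 0.5
    te_meth_boost: float = 0.3

    def __post_init__(self):
        self.meth_init = _per_context(self.meth_init, "meth_init")
        self.meth_decay = _per_context(self.meth_decay, "meth_decay")
        self.flank_meth = _per_context(self.flank_meth, "flank_meth")
        self.mutant_effect = _per_context(self.mutant_effect, "mutant_effect")
        self.chromosome_lengths = tuple(int(x) for x in self.chromosome_lengths)
        self.validate()

    def validate(self) -> None:
        if self.plastid_length < 1000:
            raise ValueError("plastid_length must be >= 1 kb")
        if not 0.0 <= self.plastid_gc <= 1.0 or not 0.0 <= self.nuclear_gc <= 1.0:
            raise ValueError("GC fractions must lie in [0, 1]")
        if self.n_chromosomes != len(self.chromosome_lengths):
            raise ValueError("n_chromosomes inconsistent with chromosome_lengths")
        if any(l <= 0 for l in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.n_insertions < 0:
            raise ValueError("n_insertions must be >= 0")
        lmin, lmax = self.insertion_length_range
        if not 0 < lmin <= lmax:
            raise ValueError("invalid insertion_length_range")
        if lmax > self.plastid_length:
            raise ValueError("insertions cannot exceed the plastid length")
        a0, a1 = self.age_range
        if not 0.0 <= a0 <= a1:
            raise ValueError("invalid age_range")
        for name, mapping in (
            ("meth_init", self.meth_init),
            ("flank_meth", self.flank_meth),
            ("mutant_effect", self.mutant_effect),
        ):
            for c, v in mapping.items():
                if not 0.0 <= v <= (1.0 if name != "mutant_effect" else 10.0):
                    raise ValueError(f"{name}[{c}] = {v} out of range")
        if any(v < 0 for v in self.meth_decay.values()):
            raise ValueError("meth_decay must be >= 0")
        if not 0.0 <= self.conversion_error <= 0.5:
            raise ValueError("conversion_error must lie in [0, 0.5]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.gene_density < 0 or self.te_density < 0:
            raise ValueError("densities must be >= 0")
        if not 0.0 <= self.te_enriched_fraction <= 1.0:
            raise ValueError("te_enriched_fraction must lie in [0, 1]")
        if self.te_enrichment_factor < 1.0:
            raise ValueError("te_enrichment_factor must be >= 1")
        # at most one substitution per site: per-site probabilities must sum
        # below 1 at the oldest possible, maximally methylated cytosine
        a1 = self.age_range[1]
        worst = 0.0
        for c in CONTEXTS:
            m0 = min(1.0, self.meth_init[c] + self.te_meth_boost)
            mbar = time_averaged_methylation(
                a1, m0, self.meth_decay[c], self.flank_meth[c]
            )
            worst = max(worst, self.deamination_rate * a1 * mbar)
        if 3 * self.basal_rate * a1 + worst >= 1.0:
            raise ValueError(
                "substitution probabilities exceed 1 per site at the oldest age; "
                "lower basal_rate, deamination_rate or the age range"
            )


@dataclass(frozen=True)
class Substitution:
    """One applied substitution, position relative to the inserted segment
    (nuclear plus strand), pre-mutation base first."""

    offset: int
    ref: str
    alt: str
    cause: str  # 'basal' | 'deamination'


@dataclass
class Insertion:
    """Ground truth for one NUPT insertion."""

    insertion_id: str
    chrom: str
    start: int
    end: int
    strand: str
    plastid_start: int
    plastid_end: int
    age: float
    te_rich: bool
    meth_init_eff: dict[str, float]  # m0 after any TE-coupling boost
    meth_levels: dict[str, float]  # current m(age) per context
    substitutions: list[Substitution] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SyntheticTruth:
    insertions: list[Insertion] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.insertions)


# ---------------------------------------------------------------------------
# Methylation kinetics
# ---------------------------------------------------------------------------


def current_methylation(age: float, m0: float, lam: float, flank: float) -> float:
    """``m(a) = flank + (m0 - flank) * exp(-lambda * a)``."""
    return flank + (m0 - flank) * math.exp(-lam * age)


def time_averaged_methylation(age: float, m0: float, lam: float, flank: float) -> float:
    """Average of ``m(t)`` over [0, age] — the methylation a cytosine was
    exposed to while deamination could act: ``flank + (m0 - flank) *
    (1 - exp(-lambda a)) / (lambda a)``; limits to m0 as ``lambda * a -> 0``."""
    if age < 0:
        raise ValueError("age must be >= 0")
    la = lam * age
    if la < 1e-12:
        return m0
    return flank + (m0 - flank) * (1.0 - math.exp(-la)) / la


def expected_d_at(
    composition: Mapping[str, float] | str, age: float, basal_rate: float
) -> float:
    """Analytic expectation of d_AT for a segment mutated at ``age``.

    Under the one-substitution-per-site model every A has probability
    ``basal_rate * age`` of becoming T and vice versa, so
    ``E[d_AT] = (f_A + f_T) * basal_rate * age`` with f the base fractions of
    the ancestral segment (pass the segment itself or a fraction mapping).
    """
    if isinstance(composition, str):
        s = composition.upper()
        n = sum(s.count(b) for b in "ACGT")
        f_at = (s.count("A") + s.count("T")) / n
    else:
        f_at = composition["A"] + composition["T"]
    return f_at * basal_rate * age


# ---------------------------------------------------------------------------
# Sequence generation and mutation
# ---------------------------------------------------------------------------


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    if length <= 0:
        raise ValueError("sequence length must be positive")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASE_BYTES[idx].tobytes().decode("ascii")


def simulate_plastid_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> str:
    """I.i.d. plastid-like sequence at the configured GC content."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return _random_sequence(config.plastid_length, config.plastid_gc, rng)


_CTX_CODE = {None: -1, "CpG": 0, "CpHpG": 1, "CpHpH": 2}
_TRI_TABLE: np.ndarray | None = None  # lazily built 5x5 downstream-pair table


def _tri_table() -> np.ndarray:
    """Context code for a cytosine given its two downstream base codes
    (0..3 = ACGT, 4 = other), built by querying the methylome classifier."""
    global _TRI_TABLE
    if _TRI_TABLE is None:
        table = np.full((5, 5), -1, dtype=np.int8)
        alphabet = "ACGTN"
        for i, b1 in enumerate(alphabet):
            for j, b2 in enumerate(alphabet):
                ctx = methylome.classify_context("C" + b1 + b2, "ref", 0, "+")
                table[i, j] = _CTX_CODE[ctx]
        _TRI_TABLE = table
    return _TRI_TABLE


def _cytosine_contexts(seq_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Positions and context codes of cytosines on both strands of a coded
    sequence (-1 codes for unclassifiable sites are filtered out).

    Returns ``(plus_pos, plus_ctx, minus_pos, minus_ctx)``; minus-strand
    cytosines are plus-strand G's, their downstream bases read upstream and
    complemented.  The last/first two positions per sequence rely on the same
    table with out-of-range bases treated as unclassifiable, matching the
    classifier's edge rule except for the terminal CpG special case, which is
    handled explicitly.
    """
    n = len(seq_codes)
    codes5 = np.where(seq_codes < 0, 4, seq_codes).astype(np.int8)
    table = _tri_table()

    plus_pos = np.flatnonzero(seq_codes == 1)
    b1 = np.where(plus_pos + 1 < n, codes5[np.minimum(plus_pos + 1, n - 1)], 4)
    b2 = np.where(plus_pos + 2 < n, codes5[np.minimum(plus_pos + 2, n - 1)], 4)
    plus_ctx = table[b1, b2]
    # a terminal C..G pair is still CpG even with nothing beyond it
    edge = (plus_pos + 1 == n - 1) & (b1 == 2)
    plus_ctx[edge] = 0

    minus_pos = np.flatnonzero(seq_codes == 2)
    comp = np.array([3, 2, 1, 0, 4], dtype=np.int8)
    c1 = np.where(minus_pos - 1 >= 0, comp[codes5[np.maximum(minus_pos - 1, 0)]], 4)
    c2 = np.where(minus_pos - 2 >= 0, comp[codes5[np.maximum(minus_pos - 2, 0)]], 4)
    minus_ctx = table[c1, c2]
    edge = (minus_pos - 1 == 0) & (c1 == 2)
    minus_ctx[edge] = 0

    keep_p = plus_ctx >= 0
    keep_m = minus_ctx >= 0
    return plus_pos[keep_p], plus_ctx[keep_p], minus_pos[keep_m], minus_ctx[keep_m]


def segment_mean_methylation(
    segment: str, age: float, meth_init_eff: Mapping[str, float], config: SimulationConfig
) -> np.ndarray:
    """Per-position time-averaged methylation of the segment's cytosines.

    Positions holding a plus-strand C or a minus-strand C (plus-strand G) get
    the time-averaged level of their context; everything else, including
    cytosines whose context window runs off the segment, gets 0 (no
    deamination exposure).
    """
    codes = _CODE_OF[np.frombuffer(segment.encode("ascii"), dtype=np.uint8)]
    mbar = np.zeros(len(segment))
    by_ctx = {
        c: time_averaged_methylation(
            age, meth_init_eff[c], config.meth_decay[c], config.flank_meth[c]
        )
        for c in CONTEXTS
    }
    ctx_values = np.array([by_ctx[c] for c in CONTEXTS])
    pp, pc, mp, mc = _cytosine_contexts(codes)
    mbar[pp] = ctx_values[pc]
    mbar[mp] = ctx_values[mc]
    return mbar


def mutate_segment(
    segment: str,
    age: float,
    methylation_state: np.ndarray | None,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[str, list[Substitution]]:
    """Apply the basal clock plus methylation-coupled deamination to a segment.

    Each site receives at most one substitution: every directed change gets
    probability ``basal_rate * age``, and the deamination product of a
    cytosine (C->T on its own strand, seen as G->A for minus-strand
    cytosines) gets an extra ``deamination_rate * age * m_bar`` with
    ``m_bar`` the site's time-averaged methylation from
    ``methylation_state`` (zeros when ``None``).  Returns the mutated
    segment and an exact substitution log.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    codes = _CODE_OF[np.frombuffer(segment.encode("ascii"), dtype=np.uint8)]
    n = len(codes)
    if methylation_state is None:
        methylation_state = np.zeros(n)
    mbar = np.asarray(methylation_state, dtype=float)
    if mbar.shape != (n,):
        raise ValueError("methylation_state must have one value per position")

    pb = config.basal_rate * age
    extra = config.deamination_rate * age * mbar
    p0 = np.full(n, pb)
    p1 = np.full(n, pb)
    p2 = np.full(n, pb)
    p0 = p0 + np.where(codes == 2, extra, 0.0)  # G -> A lives in slot 0
    p2 = p2 + np.where(codes == 1, extra, 0.0)  # C -> T lives in slot 2
    cum1 = p0
    cum2 = p0 + p1
    cum3 = cum2 + p2
    if n and float(cum3.max()) > 1.0:
        raise ValueError("per-site substitution probability exceeds 1")

    u = rng.random(n)
    slot = np.where(u < cum1, 0, np.where(u < cum2, 1, np.where(u < cum3, 2, -1)))
    slot[codes < 0] = -1  # never mutate non-ACGT characters

    out = codes.copy()
    log: list[Substitution] = []
    for i in np.flatnonzero(slot >= 0):
        b = int(codes[i])
        s = int(slot[i])
        alt = int(_TARGETS[b, s])
        cause = "basal"
        if b in _DEAM_SLOT and s == _DEAM_SLOT[b]:
            # the deamination slot covers [lo, lo + pb + extra); the basal
            # share pb comes first, the excess is attributed to deamination
            lo = 0.0 if s == 0 else float(cum2[i])
            if u[i] >= lo + pb:
                cause = "deamination"
        out[i] = alt
        log.append(
            Substitution(
                offset=int(i),
                ref="ACGT"[b],
                alt="ACGT"[alt],
                cause=cause,
            )
        )
    # rebuild the string, leaving any non-ACGT characters untouched
    raw = np.frombuffer(segment.encode("ascii"), dtype=np.uint8).copy()
    keep = codes >= 0
    raw[keep] = _BASE_BYTES[out[keep]]
    return raw.tobytes().decode("ascii"), log


# ---------------------------------------------------------------------------
# Insertion placement
# ---------------------------------------------------------------------------


def insert_nupts(
    nuclear_genome: Mapping[str, str],
    plastid: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Copy mutated plastid segments into non-overlapping nuclear loci.

    Each insertion replaces the nuclear bases at its locus (chromosome
    lengths are preserved, which keeps all coordinates stable).  The
    returned truth records coordinates, source interval, strand, age,
    effective methylation parameters and the exact substitution log.
    Raises ``ValueError`` when the genome cannot host the requested number
    of non-overlapping insertions.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chroms = sorted(nuclear_genome)
    seqs = {c: bytearray(nuclear_genome[c].encode("ascii")) for c in chroms}
    lengths = np.array([len(seqs[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    truth = SyntheticTruth()
    lmin, lmax = config.insertion_length_range
    a0, a1 = config.age_range
    coupling = config.te_enrichment_factor > 1.0 or config.te_meth_boost > 0.0

    for i in range(config.n_insertions):
        length = int(rng.integers(lmin, lmax + 1))
        ps = int(rng.integers(0, len(plastid) - length + 1))
        age = float(rng.uniform(a0, a1))
        strand = "+" if rng.random() < 0.5 else "-"
        te_rich = bool(coupling and rng.random() < config.te_enriched_fraction)
        for attempt in range(1000):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            if len(seqs[chrom]) < length:
                continue
            start = int(rng.integers(0, len(seqs[chrom]) - length + 1))
            end = start + length
            if all(e <= start or end <= s for s, e in placed[chrom]):
                break
        else:
            raise ValueError(
                "could not place insertions without overlap; genome too small"
            )
        m0_eff = {
            c: min(1.0, config.meth_init[c] + (config.te_meth_boost if te_rich else 0.0))
            for c in CONTEXTS
        }
        source = plastid[ps : ps + length]
        segment = reverse_complement(source) if strand == "-" else source
        mbar = segment_mean_methylation(segment, age, m0_eff, config)
        mutated, log = mutate_segment(segment, age, mbar, config, rng)
        seqs[chrom][start:end] = mutated.encode("ascii")
        placed[chrom].append((start, end))
        truth.insertions.append(
            Insertion(
                insertion_id=f"ins_{i + 1}",
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                plastid_start=ps,
                plastid_end=ps + length,
                age=age,
                te_rich=te_rich,
                meth_init_eff=m0_eff,
                meth_levels={
                    c: current_methylation(
                        age, m0_eff[c], config.meth_decay[c], config.flank_meth[c]
                    )
                    for c in CONTEXTS
                },
                substitutions=log,
            )
        )
    genome = {c: seqs[c].decode("ascii") for c in chroms}
    return genome, truth


# ---------------------------------------------------------------------------
# Methylome simulation
# ---------------------------------------------------------------------------


def simulate_methylome(
    genome: Mapping[str, str],
    truth: SyntheticTruth,
    config: SimulationConfig,
    *,
    mutant: bool = False,
    rng: np.random.Generator | None = None,
) -> MethylationTable:
    """Bisulfite-style counts for every classifiable cytosine, both strands.

    True level: the insertion's ``m(age)`` for sites inside a NUPT (times the
    per-context ``mutant_effect`` when ``mutant``), the flank background
    elsewhere.  Coverage is Poisson(``coverage_mean``) with zero-coverage
    sites dropped; methylated counts are binomial with the true level mixed
    with a symmetric ``conversion_error``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    flank_arr = np.array([config.flank_meth[c] for c in CONTEXTS])
    frames = []
    ins_by_chrom: dict[str, list[Insertion]] = {}
    for ins in truth.insertions:
        ins_by_chrom.setdefault(ins.chrom, []).append(ins)
    for chrom in sorted(genome):
        codes = _CODE_OF[np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8)]
        pp, pc, mp, mc = _cytosine_contexts(codes)
        pos = np.concatenate([pp, mp])
        ctx = np.concatenate([pc, mc])
        strand = np.concatenate([np.repeat("+", len(pp)), np.repeat("-", len(mp))])
        level = flank_arr[ctx]
        for ins in ins_by_chrom.get(chrom, ()):
            ins_levels = np.array(
                [
                    ins.meth_levels[c] * (config.mutant_effect[c] if mutant else 1.0)
                    for c in CONTEXTS
                ]
            )
            sel = (pos >= ins.start) & (pos < ins.end)
            level[sel] = ins_levels[ctx[sel]]
        cov = rng.poisson(config.coverage_mean, size=len(pos))
        e = config.conversion_error
        p = np.clip(level * (1.0 - e) + (1.0 - level) * e, 0.0, 1.0)
        meth = rng.binomial(cov, p)
        keep = cov >= 1
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos[keep],
                    "strand": strand[keep],
                    "context": np.array(CONTEXTS)[ctx[keep]],
                    "meth": meth[keep],
                    "unmeth": cov[keep] - meth[keep],
                }
            )
        )
    frame = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=MethylationTable.COLUMNS)
    )
    return MethylationTable(frame)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def _place_track(
    n: int,
    length_range: tuple[int, int],
    genome_lengths: Mapping[str, int],
    occupied: dict[str, list[tuple[int, int]]],
    rng: np.random.Generator,
    *,
    windows: Sequence[tuple[str, int, int]] | None = None,
    max_tries: int = 2000,
    strict: bool = True,
) -> list[tuple[str, int, int, str]]:
    """Place ``n`` non-overlapping intervals, optionally confined to windows.

    When ``strict`` a placement failure raises (the track's density exceeds
    the genome's capacity); otherwise the feature is skipped, which is the
    behaviour wanted for best-effort enrichment inside small flank windows.
    """
    chroms = sorted(genome_lengths)
    lens = np.array([genome_lengths[c] for c in chroms], dtype=float)
    weights = lens / lens.sum()
    out = []
    for _ in range(n):
        size = int(rng.integers(length_range[0], length_range[1] + 1))
        for attempt in range(max_tries):
            if windows is not None:
                chrom, wlo, whi = windows[int(rng.choice(len(windows)))]
                if whi - wlo < size:
                    continue
                start = int(rng.integers(wlo, whi - size + 1))
            else:
                chrom = chroms[int(rng.choice(len(chroms), p=weights))]
                if genome_lengths[chrom] < size:
                    continue
                start = int(rng.integers(0, genome_lengths[chrom] - size + 1))
            end = start + size
            if all(e <= start or end <= s for s, e in occupied.setdefault(chrom, [])):
                occupied[chrom].append((start, end))
                strand = "+" if rng.random() < 0.5 else "-"
                out.append((chrom, start, end, strand))
                break
        else:
            if strict:
                raise ValueError(
                    "annotation density exceeds genome capacity (placement failed)"
                )
    return out


def simulate_annotations(
    genome: Mapping[str, str],
    truth: SyntheticTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, int, int, str, str]], list[tuple[str, int, int, str, str]]]:
    """Gene and TE tracks at the configured densities.

    Baseline features are placed uniformly (non-overlapping within a track).
    When TE enrichment is on, ``(factor - 1) * te_density`` extra TEs are
    added inside the 5-kb flanks of each TE-rich insertion — the same subset
    whose methylation the truth boosted, creating the planted TE-methylation
    correlation.  Returns (genes, TEs) sorted by position.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    glen = {c: len(genome[c]) for c in genome}
    total = sum(glen.values())
    n_genes = int(round(config.gene_density * total / 100_000))
    n_tes = int(round(config.te_density * total / 10_000))

    gene_occ: dict[str, list[tuple[int, int]]] = {}
    genes = [
        (c, s, e, st, "gene")
        for c, s, e, st in _place_track(n_genes, (800, 4000), glen, gene_occ, rng)
    ]

    te_occ: dict[str, list[tuple[int, int]]] = {}
    tes = [
        (c, s, e, st, "TE")
        for c, s, e, st in _place_track(n_tes, (300, 3000), glen, te_occ, rng)
    ]
    n_extra = int(round((config.te_enrichment_factor - 1.0) * config.te_density))
    if n_extra > 0:
        for ins in truth.insertions:
            if not ins.te_rich:
                continue
            windows = []
            lo = max(0, ins.start - 5000)
            if lo < ins.start:
                windows.append((ins.chrom, lo, ins.start))
            hi = min(glen[ins.chrom], ins.end + 5000)
            if ins.end < hi:
                windows.append((ins.chrom, ins.end, hi))
            if not windows:
                continue
            tes.extend(
                (c, s, e, st, "TE")
                for c, s, e, st in _place_track(
                    n_extra, (300, 1500), glen, te_occ, rng,
                    windows=windows, strict=False,
                )
            )
    genes.sort(key=lambda iv: (iv[0], iv[1], iv[2]))
    tes.sort(key=lambda iv: (iv[0], iv[1], iv[2]))
    return genes, tes


# ---------------------------------------------------------------------------
# File output and the one-call driver
# ---------------------------------------------------------------------------


def write_fasta(seqs: Mapping[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seqs[name]), id=name, description="") for name in sorted(seqs)]
    seqio_write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(intervals, path) -> None:
    """BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for i, (chrom, start, end, strand, kind) in enumerate(intervals, 1):
            fh.write(f"{chrom}\t{start}\t{end}\t{kind}_{i}\t0\t{strand}\n")


def write_gff3(intervals, path, feature_type: str = "gene") -> None:
    """GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, (chrom, start, end, strand, kind) in enumerate(intervals, 1):
            fh.write(
                f"{chrom}\tnuptools\t{feature_type}\t{start + 1}\t{end}\t.\t{strand}\t.\t"
                f"ID={kind}_{i}\n"
            )


def write_truth(truth: SyntheticTruth, outdir) -> None:
    outdir = Path(outdir)
    ins_rows = []
    sub_rows = []
    for ins in truth.insertions:
        row = {
            "insertion_id": ins.insertion_id,
            "chrom": ins.chrom,
            "start": ins.start,
            "end": ins.end,
            "strand": ins.strand,
            "plastid_start": ins.plastid_start,
            "plastid_end": ins.plastid_end,
            "age": ins.age,
            "te_rich": ins.te_rich,
            "n_substitutions": len(ins.substitutions),
        }
        for c in CONTEXTS:
            row[f"m0_{c}"] = ins.meth_init_eff[c]
            row[f"m_{c}"] = ins.meth_levels[c]
        ins_rows.append(row)
        for sub in ins.substitutions:
            sub_rows.append(
                {
                    "insertion_id": ins.insertion_id,
                    "offset": sub.offset,
                    "ref": sub.ref,
                    "alt": sub.alt,
                    "cause": sub.cause,
                }
            )
    pd.DataFrame(ins_rows).to_csv(outdir / "truth_insertions.tsv", sep="\t", index=False)
    pd.DataFrame(
        sub_rows, columns=["insertion_id", "offset", "ref", "alt", "cause"]
    ).to_csv(outdir / "truth_substitutions.tsv", sep="\t", index=False)


@dataclass
class SimulationResult:
    config: SimulationConfig
    plastid: str
    genome: dict[str, str]
    truth: SyntheticTruth
    methylome_wt: MethylationTable
    methylome_mutant: MethylationTable
    genes: list[tuple[str, int, int, str, str]]
    tes: list[tuple[str, int, int, str, str]]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta({"plastid": self.plastid}, outdir / "plastid.fa")
        write_fasta(self.genome, outdir / "nuclear.fa")
        self.methylome_wt.write_tsv(outdir / "methylation_wt.tsv")
        self.methylome_mutant.write_tsv(outdir / "methylation_mutant.tsv")
        write_gff3(self.genes, outdir / "genes.gff3")
        write_bed(self.tes, outdir / "tes.bed")
        write_truth(self.truth, outdir)


def simulate_dataset(config: SimulationConfig) -> SimulationResult:
    """Run the full generator: genomes, truth, WT + mutant methylomes, tracks."""
    ss = np.random.SeedSequence(config.seed)
    r_pl, r_nuc, r_ins, r_wt, r_mut, r_ann = (
        np.random.default_rng(child) for child in ss.spawn(6)
    )
    plastid = simulate_plastid_genome(config, r_pl)
    nuclear = {
        f"chr{i + 1}": _random_sequence(L, config.nuclear_gc, r_nuc)
        for i, L in enumerate(config.chromosome_lengths)
    }
    genome, truth = insert_nupts(nuclear, plastid, config, r_ins)
    wt = simulate_methylome(genome, truth, config, mutant=False, rng=r_wt)
    mut = simulate_methylome(genome, truth, config, mutant=True, rng=r_mut)
    genes, tes = simulate_annotations(genome, truth, config, r_ann)
    return SimulationResult(config, plastid, genome, truth, wt, mut, genes, tes)
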