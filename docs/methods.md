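# Methods

## Substitution model and the age clock

Every aligned plastid–nuclear column is classified with the plastid base
taken as ancestral, giving twelve directed substitution counts
N<sub>X→Y</sub>, a match count, and counts of skipped columns (gaps, and any
non-ACGT character on either side).  The gap-free unambiguous length
L<sub>align</sub> = matches + substitutions is the denominator of every rate.
This "plastid = ancestor" assumption rests on the much lower mutation rate
of plastid genomes relative to nuclear ones; it is an approximation, and a
small fraction of counted changes will in reality be plastid-lineage
substitutions.

Relative integration age is measured by the AT-transversion distance
d_AT = (N_{A→T} + N_{T→A}) / L_align.  A↔T transversions are used precisely
because methylation-coupled deamination inflates C→T/G→A and would bias any
all-substitution distance.  Age bins are half-open — young [0.00, 0.02),
middle [0.02, 0.04), old [0.04, 0.06] — with the top edge closed so the 0.06
retention cutoff itself is binnable; the source wording for both boundaries
is ambiguous, and half-open-with-closed-top is the convention adopted here.
The methylation report accepts alternative bin edges (e.g. a 0.01 lower
edge) through `RunConfig.bin_edges`.

The per-bin transition ratio and category fractions are computed on pooled
counts, not averaged per NUPT: the ratio's numerator and denominator are
group-level transition totals, so pooling is the faithful reading and keeps
the statistic well-defined when individual NUPTs have empty denominators.

## Discovery cascade

Candidates carry flags rather than being deleted, so filters commute, are
idempotent, and removal counts per filter can be reported.

* `short`: gap-free aligned length < 100 bp.  The 100-bp rule is measured on
  L_align (the same length d_AT divides by); the alternative — total columns
  including gaps — was rejected for consistency, as the choice is not
  specified by the published procedure.
* `diverged`: d_AT strictly greater than 0.06; a hit exactly at 0.06 stays.
  Hits with L_align = 0 are also flagged (no basis for homology).
* `duplicate`: a deterministic replacement for manual curation — among
  identical nuclear intervals the best by (score desc, start, end,
  plastid_start) survives; an interval fully contained in another with at
  least its score is dropped; partial overlaps are all kept.
* `ambiguous_mito`: the hit's plastid interval overlaps, by ≥ 1 bp, a merged
  plastid region that itself aligns to the mitochondrial genome at ≥ 100 bp.
  Without a mitochondrial genome this filter is a no-op (with a logged
  warning), matching how species lacking a sequenced mitochondrial genome
  are handled.

Coordinates are 0-based half-open internally; BLAST (1-based inclusive,
subject possibly descending) and GFF3 are converted at the parsing boundary,
and minus-strand hits are normalized so the stored nuclear string is always
the plus strand.

The built-in aligner is a gapless seed-and-extend search (exact k-mers,
X-drop extension trimmed to maximal-score endpoints, co-diagonal merging)
sufficient for simulator output, which contains no indels.  Defaults
k = 11, match +1 / mismatch −1, X-drop 30, merge gap 200 bp were chosen so
that insertions at the oldest simulated divergence (~25–35 % total
substitution load) are still seeded and recovered with near-exact
boundaries; the mild mismatch penalty stops the maximal-score endpoint from
trimming mutation-dense tails, and same-diagonal merging is exact for
gapless alignments (both segments share the plastid/nuclear offset).  Real
genomes should use BLASTN (`-outfmt "6 std qseq sseq"`) and
`parse_homology_hits`, which recomputes identity from the aligned strings
and keeps the file's bit score.

## Methylation

Cytosine context is read 5'→3' on the site's own strand: CpG, then CpHpG,
then CpHpH (H = A, C, T); windows running off the chromosome or containing
an ambiguous base yield no context and the site is excluded.  Both strands
of a CG dinucleotide are CpG (symmetric), as the classification must be.

Region levels use the weighted form M_weighted = ΣC_i / Σ(C_i + T_i): pooled
reads, so deeply covered sites weigh more and the statistic is associative
under pooling.  A region with no covered site is *undefined* and propagates
as missing — never coerced to zero, which would fabricate hypomethylation.
The per-site minimum coverage defaults to 1 read and is configurable; no
stricter threshold is imposed because none is specified by the source
procedure.

Flank association uses 1-kb windows on each side, truncated at chromosome
ends; the High/Low dichotomy (High iff level ≥ 0.5) is computed per context
on the pooled counts of both flanks, and the separate 5'/3' levels are also
emitted because the pooling choice is not settled by the source figures.

Statistical comparisons:

* chi-square of independence, without continuity correction, on the
  bins × (methylated, unmethylated) pooled-read table — the table
  construction is this package's choice, as only the test is named in the
  source;
* two-sided Wilcoxon rank-sum on per-NUPT level distributions.  Samples
  with both sizes ≤ 8 use the exact permutation distribution (all group
  relabelings, ties respected, via scipy's `PermutationMethod`; singleton
  samples fall back to the exact U null); larger samples use the normal
  approximation with tie correction.  "n.s." labels p ≥ 0.05.
* Pearson correlation with p from t = ρ√((n−2)/(1−ρ²)) on n−2 degrees of
  freedom (scipy), pairs with missing levels dropped.

The wild-type/mutant comparison takes two summaries over the same NUPT set,
tests each context separately and emits a per-NUPT delta table; it is
deliberately generic over what the "mutant" is.

## Context features

Gene abundance uses 50-kb flanks on each side, TE abundance 5-kb flanks;
a feature counts if it overlaps either window by ≥ 1 bp and counts once
even when spanning both — the overlap convention is this package's choice.
Windows are truncated at chromosome ends and never negative.  Nearest-gene
distance is the gap to the nearer NUPT edge, 0 for overlap (never negative),
undefined on gene-less chromosomes.  Gene tracks are read from GFF3 `gene`
records (via gffutils), TE tracks from BED or GFF3, with configurable type
filters.

## The simulator: what it emulates, and what it does not

The generator encodes the mutational/epigenetic model the analyses are
designed to detect, with exact ground truth.

**Ages in d_AT units.**  Insertion ages are drawn uniformly over
[0, 0.06] — the binnable range — and the basal clock is calibrated so the
expected d_AT of an insertion equals its age: every directed change X→Y has
probability `basal_rate · age` per site, and the default
basal_rate = 1.5625 = 1/(f_A + f_T) at the default 36 % GC (plastid-like)
composition.  Each site receives at most one substitution (substitution
probabilities, not hazards, are drawn; the configuration is validated so
their per-site sum stays below 1).  This makes E[N_{A→T}] = f_A·basal·age
exactly linear, so recovery tests have closed forms
(`expected_d_at`).  At these ages multiple hits per site are negligible and
the truth log remains exact.

**Methylation-coupled deamination.**  Each cytosine (either strand) carries
an extra probability `deamination_rate · age · m̄` of its deamination product
(C→T on its own strand), where m̄ is the *time-averaged* methylation of its
context over the insertion's lifetime, (1/a)∫₀ᵃ m(t) dt.  Methylation decays
exponentially toward the flank background,
m(a) = flank + (m₀ − flank)·e^(−λa) — the simplest decay consistent with
the qualitative observation that methylation fades with relative age; the
functional form is a modeling stand-in, not an inferred law.  Defaults
m₀ = 0.85/0.60/0.30 and flank = 0.08/0.04/0.02 for CpG/CpHpG/CpHpH mimic
plant heterochromatic insertions in a euchromatic background; λ = 50 per
d_AT unit makes the decay essentially complete within the observable age
range (λ·0.06 = 3).  deamination_rate = 20 then yields a young-bin pooled
transition ratio near 0.27 rising monotonically with age — the regime the
real data show.

**Bisulfite counts.**  Coverage is Poisson (default mean 20; zero-coverage
sites are absent from the table), methylated counts are binomial with the
true level mixed with a symmetric conversion error (default 0.005).

**Annotations and the planted TE signal.**  Genes (23 per 100 kb, the
*A. thaliana*-like density) and TEs (2 per 10 kb) are placed uniformly and
non-overlapping per track.  A configurable fraction of insertions is marked
TE-rich: extra TEs are placed in their 5-kb flanks *and* their initial
methylation is boosted, planting a TE-abundance/methylation correlation.
At the default decay rate this signal is weak — the boost fades with age
and CpG has little headroom below saturation — so default-condition
correlations are small and clearest in the non-CpG contexts, which mirrors
the weak correlations seen in real data; a no-decay configuration recovers
the planted signal strongly and is used to validate the machinery.

**The mutant** multiplies NUPT methylation (not flank methylation) by a
per-context factor — default 0.2 everywhere, emulating a chromatin-
remodeler-deficient line; a context-specific factor emulates
pathway-specific mutants.  No pathway biology is modeled: a multiplicative
loss suffices to exercise the comparison statistics.

**Not emulated:** indels and recombination (alignment-gap handling is
tested on hand-made alignments instead), read-level bisulfite data,
realistic plastid gene content, insertion-site preferences, and segmental
duplications of NUPTs after insertion.  Passing tests therefore demonstrate
correctness of the estimators and statistics under this generative model,
not robustness to alignment gaps or mapping artifacts in real data.

**Scale.**  The default dataset is a deliberately scaled-down study: a
120-kb plastid-like genome and two 450-kb chromosomes carrying 300
insertions of 150–2000 bp, small enough that the full pipeline (simulation,
alignment, every report) runs in well under a minute while leaving ~100
NUPTs per age bin for the rank tests.  One consequence of the compression
is a much higher insertion density than any real genome; the planted TE
enrichment partially leaks into neighboring flanks, which further weakens
the default-condition TE correlation (see above).

**Determinism.**  All randomness derives from one `SeedSequence`; the same
configuration reproduces byte-identical outputs, including FASTA/BED/GFF3/
TSV files.

## Numerical and edge-case conventions

* Undefined statistics (empty bins, zero denominators, uncovered regions)
  are `None`/`NA` in tables, never zero; the transition ratio and d_AT
  raise on undefined input at the library level.
* Lowercase sequence is normalized to uppercase; IUPAC ambiguity codes are
  treated as ambiguous and skipped, as are alignment gap columns.
* Dedup ties break by (score desc, start asc, end asc, plastid_start asc).
* Flank and annotation windows truncate at chromosome ends; empty windows
  contribute nothing.
* Insertions replace the nuclear bases at their locus, keeping chromosome
  lengths and all downstream coordinates stable.
* Output TSVs carry a provenance comment with a hash of the analysis
  parameters (output paths excluded), so reruns are verifiably identical.

## Known limitations

* The built-in aligner is gapless by design; genomes with indel-bearing
  NUPTs require an external aligner.
* Precision/recall of discovery is evaluated by ≥ 90 % reciprocal overlap
  against truth insertions passing the same published filters applied to
  truth values; boundary-trimming of heavily mutated tails occasionally
  fragments the oldest, shortest insertions.
* The chi-square on pooled reads treats reads as independent; within-site
  overdispersion is not modeled (in the simulator reads truly are
  independent, so the test is exact there).
* `compare_wt_mutant` assumes the two samples cover the same NUPT set and
  drops NUPTs undefined in either sample.
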