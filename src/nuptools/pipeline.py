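"""Stage orchestration, run configuration and all tabular file dialects.

The pipeline turns a genome pair (plus optional mitochondrial genome,
pre-computed BLAST hits, methylation call tables and annotations) into the
analysis tables: the filtered NUPT set, per-age-bin substitution spectra,
per-age-bin methylation with tests, flank High/Low association, wild-type vs
mutant deltas, and context correlations.  Every output TSV has a header, a
stable column order and a provenance comment line with a hash of the run
configuration; a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import context as context_mod
from . import discovery, divergence, methylome
from .discovery import HomologyHit, NuptRecord
from .divergence import SubstitutionSpectrum
from .methylome import CONTEXTS, MethylationTable
from .synthetic import read_fasta

__all__ = [
    "RunConfig",
    "run_discover",
    "run_diverge",
    "run_methylome",
    "run_context",
    "run_report",
    "run_all",
    "write_nupt_table",
    "load_nupt_table",
    "evaluate_discovery",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run.

    Defaults are the published values: 100-bp minimum hit length, 0.06
    divergence cutoff, 0.02/0.04 age-bin edges, 1-kb methylation flanks with
    a 0.5 High/Low threshold, 50-kb gene flanks and 5-kb TE flanks.
    """

    genome: str | None = None
    plastid: str | None = None
    mito: str | None = None
    hits: str | None = None
    methylation: str | None = None
    mutant_methylation: str | None = None
    genes: str | None = None
    tes: str | None = None
    out_dir: str = "nupt_out"
    min_len: int = 100
    max_d: float = 0.06
    bin_edges: Sequence[Sequence[float]] = ((0.00, 0.02), (0.02, 0.04), (0.04, 0.06))
    meth_flank: int = 1000
    gene_flank: int = 50_000
    te_flank: int = 5_000
    high_low_threshold: float = 0.5
    min_coverage: int = 1
    aligner_k: int = 11
    seed: int = 0
    strict_parse: bool = False

    def __post_init__(self):
        self.bin_edges = tuple(tuple(float(x) for x in e) for e in self.bin_edges)

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load a flat key-value (YAML) config file; keyword overrides win
        and are logged."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, value in overrides.items():
            if value is None:
                continue
            if key in data and data[key] != value:
                logger.info("config override: %s = %r (file had %r)", key, value, data[key])
            data[key] = value
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output location is not an
        analysis parameter, so reruns into different directories agree)."""
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @property
    def bin_labels(self) -> tuple[str, ...]:
        return divergence.AGE_BIN_LABELS[: len(self.bin_edges)]


def _provenance(config: RunConfig) -> str:
    return f"# nuptools config_hash={config.config_hash()} seed={config.seed}"


def _write_tsv(df: pd.DataFrame, path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config) + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", lineterminator="\n")


def _fmt(value) -> object:
    return "NA" if value is None else value


# ---------------------------------------------------------------------------
# NUPT table serialization
# ---------------------------------------------------------------------------

_NUPT_FIXED = [
    "nupt_id", "nuclear_chrom", "nuclear_start", "nuclear_end", "nuclear_strand",
    "plastid_start", "plastid_end", "l_align", "percent_identity", "score",
    "d_at", "age_bin",
]


def write_nupt_table(records: Sequence[NuptRecord], path, config: RunConfig) -> None:
    rows = []
    for r in records:
        h = r.hit
        row = {
            "nupt_id": r.nupt_id,
            "nuclear_chrom": h.nuclear_chrom,
            "nuclear_start": h.nuclear_start,
            "nuclear_end": h.nuclear_end,
            "nuclear_strand": h.nuclear_strand,
            "plastid_start": h.plastid_start,
            "plastid_end": h.plastid_end,
            "l_align": r.spectrum.l_align,
            "percent_identity": round(h.percent_identity, 6),
            "score": h.score,
            "d_at": round(r.d_at, 6),
            "age_bin": r.age_bin,
        }
        row.update(r.spectrum.as_flat_dict())
        rows.append(row)
    columns = _NUPT_FIXED + list(SubstitutionSpectrum().as_flat_dict())
    _write_tsv(pd.DataFrame(rows, columns=columns), path, config)


def load_nupt_table(path) -> list[NuptRecord]:
    """Rebuild NUPT records from a table written by ``write_nupt_table``.

    The aligned strings are not stored in the table, so the rebuilt hits
    carry empty alignment strings; spectra, coordinates, d_AT and bins are
    exact.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for row in df.to_dict("records"):
        spec = SubstitutionSpectrum.from_flat_dict(row)
        hit = HomologyHit(
            nuclear_chrom=str(row["nuclear_chrom"]),
            nuclear_start=int(row["nuclear_start"]),
            nuclear_end=int(row["nuclear_end"]),
            nuclear_strand=str(row["nuclear_strand"]),
            plastid_start=int(row["plastid_start"]),
            plastid_end=int(row["plastid_end"]),
            aligned_plastid_seq="",
            aligned_nuclear_seq="",
            percent_identity=float(row["percent_identity"]),
            score=float(row["score"]),
        )
        hit._spectrum = spec
        records.append(
            NuptRecord(
                nupt_id=str(row["nupt_id"]),
                hit=hit,
                spectrum=spec,
                d_at=float(row["d_at"]),
                age_bin=str(row["age_bin"]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def run_discover(config: RunConfig) -> tuple[list[NuptRecord], dict[str, int]]:
    """Homology search plus the published filter cascade; writes nupts.tsv.

    Returns the records and the per-filter removal counts, which are also
    logged (the published supplements report these per species).
    """
    if config.genome is None or config.plastid is None:
        raise ValueError("discovery requires genome and plastid FASTA paths")
    genome = read_fasta(config.genome)
    plastid_seqs = read_fasta(config.plastid)
    plastid = next(iter(plastid_seqs.values()))
    if config.hits:
        with open(config.hits) as fh:
            hits = discovery.parse_homology_hits(fh, strict=config.strict_parse)
    else:
        hits = discovery.naive_local_align(
            plastid, genome, k=config.aligner_k, min_len=min(config.min_len, 100)
        )
    discovery.filter_length(hits, config.min_len)
    discovery.filter_distance(hits, config.max_d)
    discovery.dedupe_hits(hits)
    if config.mito:
        mito = next(iter(read_fasta(config.mito).values()))
        mito_regions = discovery.find_mito_similar_regions(
            plastid, mito, k=config.aligner_k, min_len=config.min_len
        )
    else:
        logger.warning(
            "no mitochondrial genome supplied; ambiguity filtering is a no-op"
        )
        mito_regions = []
    discovery.flag_mito_ambiguous(hits, mito_regions)
    labels = config.bin_labels
    records = discovery.assemble_nupt_set(
        hits, edges=config.bin_edges, labels=labels
    )
    counts = {
        "total_hits": len(hits),
        "removed_short": sum(1 for h in hits if "short" in h.flags),
        "removed_diverged": sum(1 for h in hits if "diverged" in h.flags),
        "removed_duplicate": sum(1 for h in hits if "duplicate" in h.flags),
        "removed_ambiguous_mito": sum(1 for h in hits if "ambiguous_mito" in h.flags),
        "nupts": len(records),
    }
    for key, value in counts.items():
        logger.info("discover: %s = %d", key, value)
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_nupt_table(records, outdir / "nupts.tsv", config)
    return records, counts


def run_diverge(config: RunConfig, records: Sequence[NuptRecord] | None = None) -> pd.DataFrame:
    """Per-age-bin pooled spectra, transition ratios and GC (bin_spectra.tsv)."""
    outdir = Path(config.out_dir)
    if records is None:
        records = load_nupt_table(outdir / "nupts.tsv")
    genome = read_fasta(config.genome) if config.genome else None
    plastid = (
        next(iter(read_fasta(config.plastid).values())) if config.plastid else None
    )
    summaries = divergence.summarize_bins(
        records, nuclear_seqs=genome, plastid_seq=plastid, labels=config.bin_labels
    )
    rows = []
    for s in summaries:
        row = {
            "age_bin": s.label,
            "n_nupts": s.n_nupts,
            "l_align": s.spectrum.l_align,
            "transition_ratio": _fmt(s.transition_ratio),
        }
        for name in divergence.PLOTTED_CATEGORIES:
            row[f"frac_{name}"] = _fmt(
                s.category_fractions[name] if s.category_fractions else None
            )
        row["mean_gc_nupt"] = _fmt(s.mean_gc_nupt)
        row["mean_gc_plastid"] = _fmt(s.mean_gc_plastid)
        row.update(s.spectrum.as_flat_dict())
        rows.append(row)
    df = pd.DataFrame(rows)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(df, outdir / "bin_spectra.tsv", config)
    return df


def _summaries_for(
    records: Sequence[NuptRecord], table: MethylationTable, config: RunConfig
) -> dict[str, methylome.MethylationSummary]:
    out = {}
    for r in records:
        h = r.hit
        out[r.nupt_id] = methylome.summarize_interval(
            table, h.nuclear_chrom, h.nuclear_start, h.nuclear_end,
            interval_id=r.nupt_id, min_coverage=config.min_coverage,
        )
    return out


def run_methylome(
    config: RunConfig, records: Sequence[NuptRecord] | None = None
) -> dict[str, pd.DataFrame]:
    """Methylation tables: per-NUPT levels, age-bin comparison with tests,
    flank High/Low association, and (when a mutant table is supplied) the
    wild-type vs mutant tests and deltas."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if records is None:
        records = load_nupt_table(outdir / "nupts.tsv")
    if config.methylation is None:
        raise ValueError("methylome stage requires a methylation table")
    table = MethylationTable.read_tsv(config.methylation)
    genome = read_fasta(config.genome) if config.genome else None
    chrom_lengths = {c: len(s) for c, s in genome.items()} if genome else {}
    summaries = _summaries_for(records, table, config)

    per_rows = []
    for r in records:
        s = summaries[r.nupt_id]
        row = {"nupt_id": r.nupt_id, "d_at": r.d_at, "age_bin": r.age_bin,
               "has_data": s.has_data}
        for ctx in CONTEXTS:
            cl = s.contexts[ctx]
            row[f"level_{ctx}"] = _fmt(cl.level)
            row[f"n_sites_{ctx}"] = cl.n_sites
            row[f"meth_{ctx}"] = cl.meth
            row[f"total_{ctx}"] = cl.total
        per_rows.append(row)
    per_nupt = pd.DataFrame(per_rows)
    _write_tsv(per_nupt, outdir / "nupt_methylation.tsv", config)
    n_excluded = sum(1 for s in summaries.values() if not s.has_data)
    if n_excluded:
        logger.info("methylome: %d NUPTs with no methylome data excluded", n_excluded)

    labels = config.bin_labels
    bin_rows, test_rows = [], []
    for ctx in CONTEXTS:
        levels_by_bin = {}
        counts_by_bin = {}
        for label in labels:
            members = [r for r in records if r.age_bin == label]
            vals = [
                summaries[r.nupt_id].level(ctx)
                for r in members
                if summaries[r.nupt_id].level(ctx) is not None
            ]
            levels_by_bin[label] = vals
            meth = sum(summaries[r.nupt_id].contexts[ctx].meth for r in members)
            total = sum(summaries[r.nupt_id].contexts[ctx].total for r in members)
            counts_by_bin[label] = (meth, total - meth)
            bin_rows.append(
                {
                    "context": ctx,
                    "age_bin": label,
                    "n_nupts": len(vals),
                    "mean_level": _fmt(float(np.mean(vals)) if vals else None),
                    "median_level": _fmt(float(np.median(vals)) if vals else None),
                    "pooled_meth": meth,
                    "pooled_total": total,
                }
            )
        try:
            report = methylome.compare_age_bins(levels_by_bin, counts_by_bin)
        except ValueError:
            continue
        if report["chi2"] is not None:
            test_rows.append(
                {
                    "context": ctx, "test": "chi2",
                    "comparison": "x".join(report["chi2"]["bins"]),
                    "statistic": report["chi2"]["statistic"],
                    "p": report["chi2"]["p"],
                    "significance": report["chi2"]["significance"],
                }
            )
        for (a, b), res in report["wilcoxon"].items():
            test_rows.append(
                {
                    "context": ctx, "test": "wilcoxon", "comparison": f"{a}_vs_{b}",
                    "statistic": res["U"], "p": res["p"],
                    "significance": res["significance"],
                }
            )
    bin_table = pd.DataFrame(bin_rows)
    tests_table = pd.DataFrame(
        test_rows,
        columns=["context", "test", "comparison", "statistic", "p", "significance"],
    )
    _write_tsv(bin_table, outdir / "bin_methylation.tsv", config)
    _write_tsv(tests_table, outdir / "bin_methylation_tests.tsv", config)

    flank_rows = []
    for r in records:
        h = r.hit
        rep = methylome.flank_methylation(
            table, h.nuclear_chrom, h.nuclear_start, h.nuclear_end,
            flank=config.meth_flank, threshold=config.high_low_threshold,
            chrom_length=chrom_lengths.get(h.nuclear_chrom),
            interval_id=r.nupt_id, min_coverage=config.min_coverage,
        )
        for ctx in CONTEXTS:
            flank_rows.append(
                {
                    "nupt_id": r.nupt_id, "age_bin": r.age_bin, "context": ctx,
                    "nupt_level": _fmt(summaries[r.nupt_id].level(ctx)),
                    "flank_level": _fmt(rep.combined[ctx].level),
                    "five_prime_level": _fmt(rep.five_prime.level(ctx)),
                    "three_prime_level": _fmt(rep.three_prime.level(ctx)),
                    "flank_label": _fmt(rep.labels[ctx]),
                }
            )
    flank_table = pd.DataFrame(flank_rows)
    _write_tsv(flank_table, outdir / "flank_association.tsv", config)

    out = {
        "per_nupt": per_nupt,
        "bins": bin_table,
        "tests": tests_table,
        "flanks": flank_table,
    }
    if config.mutant_methylation and records:
        mut_table = MethylationTable.read_tsv(config.mutant_methylation)
        mut_summaries = _summaries_for(records, mut_table, config)
        tests, deltas = methylome.compare_wt_mutant(summaries, mut_summaries)
        mut_rows = [
            {
                "context": ctx,
                "n": res["n"], "statistic": res["U"], "p": res["p"],
                "mean_delta": res["mean_delta"], "significance": res["significance"],
            }
            for ctx, res in tests.items()
            if res is not None
        ]
        mut_tests = pd.DataFrame(
            mut_rows, columns=["context", "n", "statistic", "p", "mean_delta", "significance"]
        )
        deltas = deltas.rename(columns={"interval_id": "nupt_id"})
        _write_tsv(mut_tests, outdir / "mutant_tests.tsv", config)
        _write_tsv(deltas, outdir / "mutant_deltas.tsv", config)
        out["mutant_tests"] = mut_tests
        out["mutant_deltas"] = deltas
    return out


def run_context(
    config: RunConfig, records: Sequence[NuptRecord] | None = None
) -> dict[str, pd.DataFrame]:
    """Flanking gene/TE abundance, nearest genes, GC profile and the
    TE-methylation correlations (context_features.tsv + correlations)."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if records is None:
        records = load_nupt_table(outdir / "nupts.tsv")
    genome = read_fasta(config.genome) if config.genome else None
    chrom_lengths = {c: len(s) for c, s in genome.items()} if genome else {}
    gene_track = (
        context_mod.AnnotationTrack.from_gff3(config.genes) if config.genes else None
    )
    te_track = context_mod.AnnotationTrack.from_bed(config.tes) if config.tes else None
    meth_levels: dict[str, dict[str, float | None]] = {}
    if config.methylation:
        table = MethylationTable.read_tsv(config.methylation)
        for r in records:
            s = methylome.summarize_interval(
                table, r.hit.nuclear_chrom, r.hit.nuclear_start, r.hit.nuclear_end,
                min_coverage=config.min_coverage,
            )
            meth_levels[r.nupt_id] = {ctx: s.level(ctx) for ctx in CONTEXTS}

    rows = []
    for r in records:
        h = r.hit
        iv = (h.nuclear_chrom, h.nuclear_start, h.nuclear_end)
        clen = chrom_lengths.get(h.nuclear_chrom)
        row = {"nupt_id": r.nupt_id, "d_at": r.d_at, "age_bin": r.age_bin}
        row["gene_count_flanks"] = (
            context_mod.count_in_flanks(iv, gene_track, config.gene_flank, chrom_length=clen)
            if gene_track is not None
            else "NA"
        )
        row["te_count_flanks"] = (
            context_mod.count_in_flanks(iv, te_track, config.te_flank, chrom_length=clen)
            if te_track is not None
            else "NA"
        )
        row["nearest_gene_bp"] = (
            _fmt(context_mod.nearest_gene_distance(iv, gene_track))
            if gene_track is not None
            else "NA"
        )
        if genome is not None:
            try:
                nupt_gc, flank_gc = context_mod.flank_gc_profile(iv, genome, config.meth_flank)
            except ValueError:
                nupt_gc = flank_gc = None
            row["nupt_gc"] = _fmt(nupt_gc)
            row["flank_gc"] = _fmt(flank_gc)
        else:
            row["nupt_gc"] = row["flank_gc"] = "NA"
        for ctx in CONTEXTS:
            row[f"level_{ctx}"] = _fmt(meth_levels.get(r.nupt_id, {}).get(ctx))
        rows.append(row)
    features = pd.DataFrame(rows)
    _write_tsv(features, outdir / "context_features.tsv", config)

    corr_rows = []
    if te_track is not None and meth_levels:
        for ctx in CONTEXTS:
            xs, ys = [], []
            for r in records:
                lv = meth_levels.get(r.nupt_id, {}).get(ctx)
                if lv is None:
                    continue
                iv = (r.hit.nuclear_chrom, r.hit.nuclear_start, r.hit.nuclear_end)
                xs.append(
                    context_mod.count_in_flanks(
                        iv, te_track, config.te_flank,
                        chrom_length=chrom_lengths.get(r.hit.nuclear_chrom),
                    )
                )
                ys.append(lv)
            try:
                rho, p = context_mod.pearson_correlation(xs, ys)
                corr_rows.append(
                    {
                        "context": ctx, "n": len(xs), "pearson_rho": rho, "p": p,
                        "significance": "n.s." if p >= 0.05 else "p<0.05",
                    }
                )
            except ValueError:
                corr_rows.append(
                    {"context": ctx, "n": len(xs), "pearson_rho": "NA", "p": "NA",
                     "significance": "NA"}
                )
    correlations = pd.DataFrame(
        corr_rows, columns=["context", "n", "pearson_rho", "p", "significance"]
    )
    _write_tsv(correlations, outdir / "context_correlations.tsv", config)
    return {"features": features, "correlations": correlations}


def run_report(config: RunConfig) -> None:
    """All reporting stages over an existing nupts.tsv."""
    records = load_nupt_table(Path(config.out_dir) / "nupts.tsv")
    run_diverge(config, records)
    if config.methylation:
        run_methylome(config, records)
    run_context(config, records)


def run_all(config: RunConfig) -> list[NuptRecord]:
    records, _counts = run_discover(config)
    run_diverge(config, records)
    if config.methylation:
        run_methylome(config, records)
    run_context(config, records)
    return records


# ---------------------------------------------------------------------------
# Evaluation against synthetic truth
# ---------------------------------------------------------------------------


def truth_passing_filters(truth, min_len: int = 100, max_d: float = 0.06):
    """Truth insertions that survive the published filters applied to truth
    values: length >= ``min_len`` and truth-side d_AT (exact, from the
    substitution log over the gapless insertion length) <= ``max_d``."""
    kept = []
    for ins in truth.insertions:
        n_at = sum(
            1 for s in ins.substitutions if (s.ref, s.alt) in (("A", "T"), ("T", "A"))
        )
        if ins.length >= min_len and n_at / ins.length <= max_d:
            kept.append(ins)
    filtered = type(truth)()
    filtered.insertions = kept
    return filtered


def _matches(record: NuptRecord, insertions, min_reciprocal_overlap: float):
    h = record.hit
    out = []
    for ins in insertions:
        if ins.chrom != h.nuclear_chrom:
            continue
        inter = min(ins.end, h.nuclear_end) - max(ins.start, h.nuclear_start)
        if inter <= 0:
            continue
        union = max(ins.end, h.nuclear_end) - min(ins.start, h.nuclear_start)
        if inter / union >= min_reciprocal_overlap:
            out.append(ins.insertion_id)
    return out


def evaluate_discovery(
    records: Sequence[NuptRecord],
    truth,
    min_reciprocal_overlap: float = 0.9,
    *,
    min_len: int = 100,
    max_d: float = 0.06,
) -> dict:
    """Precision/recall of discovered NUPTs against simulator ground truth.

    A record matches a truth insertion when intersection/union of the two
    nuclear intervals (same chromosome) is at least ``min_reciprocal_overlap``.
    Precision is judged against *all* truth insertions (recovering a real
    insertion that the truth-side filters would drop is not a false
    discovery); recall is judged against the truth insertions that pass the
    published filters applied to truth values (``truth_passing_filters``),
    since hits the cascade is designed to remove cannot be expected in the
    output.
    """
    eligible = truth_passing_filters(truth, min_len=min_len, max_d=max_d)
    matched_truth: set[str] = set()
    matched_records = 0
    for r in records:
        hits_all = _matches(r, truth.insertions, min_reciprocal_overlap)
        if hits_all:
            matched_records += 1
        matched_truth.update(_matches(r, eligible.insertions, min_reciprocal_overlap))
    precision = matched_records / len(records) if records else float("nan")
    recall = (
        len(matched_truth) / len(eligible.insertions)
        if len(eligible.insertions)
        else float("nan")
    )
    return {
        "n_records": len(records),
        "n_truth": len(truth.insertions),
        "n_truth_eligible": len(eligible.insertions),
        "precision": precision,
        "recall": recall,
    }
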