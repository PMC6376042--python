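"""Bisulfite methylation summaries for NUPTs: contexts, weighted levels, tests.

Works from per-cytosine count tables (chrom, position, strand, methylated
count C_i, unmethylated count T_i), the standard output shape of bisulfite
methylation extractors.  Plant methylation is analyzed in the three cytosine
sequence contexts CpG, CpHpG and CpHpH (H = A, C or T), read 5'->3' on the
cytosine's own strand.

The region-level statistic throughout is the *weighted* methylation level

    M_weighted = sum_i C_i / sum_i (C_i + T_i)

pooled over the covered cytosines of one context in a region; it is undefined
(``None``), never zero, when a region has no covered site.  Comparisons use a
chi-square test of independence on pooled read counts and two-sided Wilcoxon
rank-sum tests on per-region level distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CONTEXTS",
    "CytosineSite",
    "ContextLevel",
    "MethylationSummary",
    "FlankReport",
    "MethylationTable",
    "classify_context",
    "weighted_methylation",
    "summarize_interval",
    "flank_methylation",
    "rank_sum_test",
    "chi_square_counts",
    "compare_age_bins",
    "compare_wt_mutant",
]

CONTEXTS = ("CpG", "CpHpG", "CpHpH")
_H = frozenset("ACT")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class CytosineSite:
    """One cytosine with its strand, sequence context and read counts."""

    chrom: str
    pos: int  # 0-based position of the cytosine on the plus strand
    strand: str  # '+' or '-'
    context: str | None
    meth: int  # C_i, reads supporting methylation
    unmeth: int  # T_i, reads supporting no methylation


def classify_context(reference, chrom: str, pos: int, strand: str) -> str | None:
    """Classify the cytosine at (chrom, pos, strand) as CpG / CpHpG / CpHpH.

    ``reference`` is a mapping chrom -> plus-strand sequence (a bare string is
    also accepted, in which case ``chrom`` is ignored).  Reading 5'->3' on the
    site's strand: next base G -> CpG; next base H then G -> CpHpG; next two
    bases H -> CpHpH.  Returns ``None`` when the needed window runs off the
    chromosome end or contains a non-ACGT base; raises ``ValueError`` when the
    addressed base is not a cytosine on the stated strand.
    """
    seq = reference if isinstance(reference, str) else reference[chrom]
    if pos < 0 or pos >= len(seq):
        raise ValueError(f"position {pos} out of range for {chrom}")
    base = seq[pos].upper()
    if strand == "+":
        if base != "C":
            raise ValueError(f"{chrom}:{pos}+ is {base}, not C")
        b1 = seq[pos + 1].upper() if pos + 1 < len(seq) else None
        b2 = seq[pos + 2].upper() if pos + 2 < len(seq) else None
    elif strand == "-":
        if base != "G":
            raise ValueError(f"{chrom}:{pos}- is {base}, not C on the minus strand")
        b1 = _COMP.get(seq[pos - 1].upper()) if pos - 1 >= 0 else None
        b2 = _COMP.get(seq[pos - 2].upper()) if pos - 2 >= 0 else None
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if b1 is None:
        return None
    if b1 == "G":
        return "CpG"
    if b1 not in _H:
        return None  # N or other ambiguity in the window
    if b2 is None:
        return None
    if b2 == "G":
        return "CpHpG"
    if b2 in _H:
        return "CpHpH"
    return None


def weighted_methylation(sites: Iterable) -> float | None:
    """Pooled weighted level over sites; ``None`` when total coverage is zero.

    Accepts ``CytosineSite`` objects or plain ``(meth, unmeth)`` pairs.
    """
    c = t = 0
    for s in sites:
        if isinstance(s, CytosineSite):
            c += s.meth
            t += s.unmeth
        else:
            c += s[0]
            t += s[1]
    total = c + t
    if total == 0:
        return None
    return c / total


@dataclass
class ContextLevel:
    """Pooled counts and weighted level for one context in one interval."""

    n_sites: int = 0
    meth: int = 0
    total: int = 0

    @property
    def level(self) -> float | None:
        return self.meth / self.total if self.total > 0 else None


@dataclass
class MethylationSummary:
    interval_id: str | None
    contexts: dict[str, ContextLevel] = field(
        default_factory=lambda: {c: ContextLevel() for c in CONTEXTS}
    )

    def level(self, context: str) -> float | None:
        return self.contexts[context].level

    @property
    def has_data(self) -> bool:
        return any(cl.total > 0 for cl in self.contexts.values())


class MethylationTable:
    """Per-cytosine count table indexed for fast interval queries.

    Backed by a DataFrame with columns ``chrom, pos, strand, context, meth,
    unmeth`` (``pos`` 0-based).  On-disk format is TSV with 1-based positions,
    as emitted by the synthetic-data generator.
    """

    COLUMNS = ["chrom", "pos", "strand", "context", "meth", "unmeth"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"methylation table missing columns: {missing}")
        df = frame[self.COLUMNS].sort_values(["chrom", "pos"], kind="stable")
        self.frame = df.reset_index(drop=True)
        self._by_chrom: dict[str, tuple[int, int]] = {}
        chroms = self.frame["chrom"].to_numpy()
        if len(chroms):
            bounds = np.flatnonzero(np.r_[True, chroms[1:] != chroms[:-1]])
            bounds = np.r_[bounds, len(chroms)]
            for i in range(len(bounds) - 1):
                self._by_chrom[chroms[bounds[i]]] = (int(bounds[i]), int(bounds[i + 1]))
        self._pos = self.frame["pos"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def read_tsv(cls, path) -> "MethylationTable":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            dtype={"chrom": str, "strand": str, "context": str},
        )
        df = df.rename(
            columns={
                "count_methylated": "meth",
                "count_unmethylated": "unmeth",
            }
        )
        df["pos"] = df["pos"].astype(int) - 1  # file is 1-based
        return cls(df)

    def write_tsv(self, path) -> None:
        out = self.frame.copy()
        out["pos"] = out["pos"] + 1
        out = out.rename(
            columns={"meth": "count_methylated", "unmeth": "count_unmethylated"}
        )
        out.to_csv(path, sep="\t", index=False)

    def sites_in(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """Sites with start <= pos < end on either strand."""
        if chrom not in self._by_chrom or end <= start:
            return self.frame.iloc[0:0]
        lo, hi = self._by_chrom[chrom]
        i = lo + np.searchsorted(self._pos[lo:hi], start, side="left")
        j = lo + np.searchsorted(self._pos[lo:hi], end, side="left")
        return self.frame.iloc[int(i) : int(j)]


def _accumulate(summary: MethylationSummary, sites: pd.DataFrame, min_coverage: int):
    for ctx in CONTEXTS:
        sub = sites[sites["context"] == ctx]
        if min_coverage > 1 and len(sub):
            sub = sub[(sub["meth"] + sub["unmeth"]) >= min_coverage]
        cl = summary.contexts[ctx]
        cl.n_sites += int(len(sub))
        cl.meth += int(sub["meth"].sum())
        cl.total += int((sub["meth"] + sub["unmeth"]).sum())


def summarize_interval(
    table: MethylationTable,
    chrom: str,
    start: int,
    end: int,
    *,
    interval_id: str | None = None,
    min_coverage: int = 1,
    reference: Mapping[str, str] | None = None,
) -> MethylationSummary:
    """Per-context pooled weighted levels over [start, end).

    Site contexts are taken from the table; rows with a missing context are
    classified from ``reference`` when one is given and dropped otherwise.
    Intervals with no covered cytosine come back with all contexts undefined —
    callers exclude such intervals from downstream comparisons.
    """
    sites = table.sites_in(chrom, start, end)
    if sites["context"].isna().any():
        sites = sites.copy()
        if reference is not None:
            mask = sites["context"].isna()
            sites.loc[mask, "context"] = [
                classify_context(reference, chrom, int(p), s)
                for p, s in zip(sites.loc[mask, "pos"], sites.loc[mask, "strand"])
            ]
        sites = sites.dropna(subset=["context"])
    summary = MethylationSummary(interval_id)
    _accumulate(summary, sites, min_coverage)
    return summary


@dataclass
class FlankReport:
    """Methylation of the two 1-kb (by default) flanks of a NUPT.

    ``combined`` pools read counts of both flanks per context; ``labels``
    carries the High/Low dichotomy used for flank-association tables: High
    iff the combined level is >= the threshold, ``None`` when undefined.
    A pooled all-context label is stored under the key ``"all"``.
    """

    interval_id: str | None
    five_prime: MethylationSummary
    three_prime: MethylationSummary
    combined: dict[str, ContextLevel]
    labels: dict[str, str | None]


def flank_methylation(
    table: MethylationTable,
    chrom: str,
    start: int,
    end: int,
    *,
    flank: int = 1000,
    threshold: float = 0.5,
    chrom_length: int | None = None,
    interval_id: str | None = None,
    min_coverage: int = 1,
    reference: Mapping[str, str] | None = None,
) -> FlankReport:
    """Summaries for the 5' and 3' flanks plus the combined High/Low call.

    Flank windows are truncated at chromosome ends; a NUPT at a chromosome
    start simply has an empty 5' flank and the combined call reduces to the
    3' side.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    f_start, f_end = max(0, start - flank), start
    t_start = end
    t_end = end + flank if chrom_length is None else min(end + flank, chrom_length)
    five = summarize_interval(
        table, chrom, f_start, f_end,
        interval_id=interval_id, min_coverage=min_coverage, reference=reference,
    )
    three = summarize_interval(
        table, chrom, t_start, t_end,
        interval_id=interval_id, min_coverage=min_coverage, reference=reference,
    )
    combined: dict[str, ContextLevel] = {}
    labels: dict[str, str | None] = {}
    all_meth = all_total = 0
    for ctx in CONTEXTS:
        a, b = five.contexts[ctx], three.contexts[ctx]
        cl = ContextLevel(
            n_sites=a.n_sites + b.n_sites, meth=a.meth + b.meth, total=a.total + b.total
        )
        combined[ctx] = cl
        labels[ctx] = None if cl.level is None else ("High" if cl.level >= threshold else "Low")
        all_meth += cl.meth
        all_total += cl.total
    labels["all"] = (
        None if all_total == 0 else ("High" if all_meth / all_total >= threshold else "Low")
    )
    return FlankReport(interval_id, five, three, combined, labels)


def rank_sum_test(x: Sequence[float], y: Sequence[float], *, exact_max_n: int = 8):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    For small samples (both sizes <= ``exact_max_n``) the p-value is the exact
    permutation p-value (all group relabelings enumerated, ties included);
    larger samples use the normal approximation with tie correction.  Returns
    ``(U, p)`` with U the Mann-Whitney statistic of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("rank-sum test requires non-empty samples")
    if max(len(x), len(y)) <= exact_max_n:
        # exact permutation; scipy's PermutationMethod needs >= 2 per group,
        # singleton samples fall back to the exact null of the U statistic
        if min(len(x), len(y)) >= 2:
            method = stats.PermutationMethod(n_resamples=10**6)
        else:
            method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi_square_counts(table: Sequence[Sequence[float]]):
    """Chi-square test of independence on a counts table, no continuity
    correction.  Returns ``(statistic, p, dof)``."""
    arr = np.asarray(table, dtype=float)
    stat, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), float(p), int(dof)


def compare_age_bins(
    levels_by_bin: Mapping[str, Sequence[float]],
    counts_by_bin: Mapping[str, tuple[int, int]] | None = None,
    *,
    alpha: float = 0.05,
) -> dict:
    """Compare per-NUPT methylation across age bins.

    ``levels_by_bin`` maps bin label -> per-NUPT weighted levels (NaN/None
    entries are dropped); ``counts_by_bin`` maps bin label -> pooled
    (methylated, unmethylated) read counts.  Produces (a) a chi-square test of
    independence on the bins x (meth, unmeth) pooled table and (b) pairwise
    two-sided Wilcoxon rank-sum tests between bin level distributions, each
    annotated ``"n.s."`` when p >= alpha.  Requires >= 2 non-empty bins.
    """
    clean = {
        b: [v for v in vals if v is not None and not (isinstance(v, float) and math.isnan(v))]
        for b, vals in levels_by_bin.items()
    }
    nonempty = [b for b, vals in clean.items() if vals]
    if len(nonempty) < 2:
        raise ValueError("age-bin comparison requires >= 2 non-empty bins")
    report: dict = {"n": {b: len(v) for b, v in clean.items()}}
    chi2 = None
    if counts_by_bin is not None:
        rows = [
            (b, counts_by_bin[b])
            for b in counts_by_bin
            if sum(counts_by_bin[b]) > 0
        ]
        if len(rows) >= 2:
            stat, p, dof = chi_square_counts([c for _, c in rows])
            chi2 = {
                "bins": [b for b, _ in rows],
                "statistic": stat,
                "p": p,
                "dof": dof,
                "significance": "n.s." if p >= alpha else f"p<{alpha}",
            }
    report["chi2"] = chi2
    wilcoxon = {}
    for i, a in enumerate(nonempty):
        for b in nonempty[i + 1 :]:
            u, p = rank_sum_test(clean[a], clean[b])
            wilcoxon[(a, b)] = {
                "U": u,
                "p": p,
                "significance": "n.s." if p >= alpha else f"p<{alpha}",
            }
    report["wilcoxon"] = wilcoxon
    return report


def compare_wt_mutant(
    wt_summaries: Mapping[str, MethylationSummary],
    mutant_summaries: Mapping[str, MethylationSummary],
    *,
    alpha: float = 0.05,
) -> tuple[dict, pd.DataFrame]:
    """Wild type vs mutant methylation over a shared NUPT set.

    Per context, runs a two-sided Wilcoxon rank-sum test between the WT and
    mutant per-NUPT weighted levels (NUPTs with a defined level in both
    samples).  Also returns a per-NUPT delta table (mutant - WT) for
    scatter-style outputs.  Raises ``ValueError`` on disjoint id sets.
    """
    shared = sorted(set(wt_summaries) & set(mutant_summaries))
    if not shared:
        raise ValueError("no shared interval ids between WT and mutant summaries")
    tests: dict = {}
    rows = []
    for ctx in CONTEXTS:
        wt_levels, mut_levels = [], []
        for nid in shared:
            w = wt_summaries[nid].level(ctx)
            m = mutant_summaries[nid].level(ctx)
            if w is not None and m is not None:
                wt_levels.append(w)
                mut_levels.append(m)
                rows.append(
                    {
                        "interval_id": nid,
                        "context": ctx,
                        "wt_level": w,
                        "mutant_level": m,
                        "delta": m - w,
                    }
                )
        if wt_levels:
            u, p = rank_sum_test(wt_levels, mut_levels)
            tests[ctx] = {
                "n": len(wt_levels),
                "U": u,
                "p": p,
                "significance": "n.s." if p >= alpha else f"p<{alpha}",
                "mean_delta": float(np.mean(np.array(mut_levels) - np.array(wt_levels))),
            }
        else:
            tests[ctx] = None
    deltas = pd.DataFrame(
        rows, columns=["interval_id", "context", "wt_level", "mutant_level", "delta"]
    )
    return tests, deltas
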