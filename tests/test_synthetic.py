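"""Generator correctness: determinism, truth-log consistency, recovery."""

from collections import Counter

import numpy as np
import pytest

from nuptools.divergence import (
    at_transversion_distance,
    count_substitutions,
    reverse_complement,
    transition_ratio,
)
from nuptools.methylome import CONTEXTS, weighted_methylation
from nuptools.synthetic import (
    SimulationConfig,
    current_methylation,
    expected_d_at,
    insert_nupts,
    mutate_segment,
    segment_mean_methylation,
    simulate_annotations,
    simulate_dataset,
    simulate_methylome,
    simulate_plastid_genome,
    time_averaged_methylation,
    write_bed,
    _random_sequence,
)


def _basal_only(**kw):
    kw.setdefault("deamination_rate", 0.0)
    kw.setdefault("te_enrichment_factor", 1.0)
    kw.setdefault("te_meth_boost", 0.0)
    return SimulationConfig(**kw)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"plastid_length": 500},
            {"plastid_gc": 1.5},
            {"n_chromosomes": 3},
            {"insertion_length_range": (0, 100)},
            {"age_range": (-0.1, 0.05)},
            {"conversion_error": 0.9},
            {"meth_init": {"CpG": 1.2, "CpHpG": 0.5, "CpHpH": 0.2}},
            {"te_enrichment_factor": 0.5},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(**kw)

    def test_overdriven_mutation_rejected(self):
        """Hazards summing above 1 per site are impossible under the
        one-substitution-per-site model."""
        with pytest.raises(ValueError):
            SimulationConfig(deamination_rate=60.0)

    def test_scalar_methylation_parameters_broadcast(self):
        cfg = SimulationConfig(meth_init=0.5, flank_meth=0.1, mutant_effect=1.0)
        assert cfg.meth_init == {c: 0.5 for c in CONTEXTS}


class TestPlastidGenome:
    def test_gc_concentrates_at_target(self):
        cfg = SimulationConfig(seed=1, plastid_length=100_000, plastid_gc=0.36)
        seq = simulate_plastid_genome(cfg)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.36, abs=0.02)

    def test_gc_zero_gives_only_at(self):
        cfg = SimulationConfig(seed=2, plastid_length=2000, plastid_gc=0.0)
        assert set(simulate_plastid_genome(cfg)) <= {"A", "T"}

    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=3)
        assert simulate_plastid_genome(cfg) == simulate_plastid_genome(cfg)


class TestMethylationKinetics:
    def test_exponential_decay_form(self):
        m0, lam, flank = 0.8, 50.0, 0.1
        assert current_methylation(0.0, m0, lam, flank) == pytest.approx(m0)
        a = 0.03
        assert current_methylation(a, m0, lam, flank) == pytest.approx(
            flank + (m0 - flank) * np.exp(-lam * a)
        )

    def test_time_average_limits(self):
        assert time_averaged_methylation(0.0, 0.8, 50.0, 0.1) == pytest.approx(0.8)
        assert time_averaged_methylation(0.05, 0.8, 0.0, 0.1) == pytest.approx(0.8)
        # time average lies between the current level and the initial level
        a, m0, lam, flank = 0.05, 0.8, 50.0, 0.1
        mbar = time_averaged_methylation(a, m0, lam, flank)
        assert current_methylation(a, m0, lam, flank) < mbar < m0


class TestMutateSegment:
    def test_age_zero_no_substitutions(self, rng):
        cfg = SimulationConfig()
        seg = _random_sequence(5000, 0.36, rng)
        out, log = mutate_segment(seg, 0.0, None, cfg, rng)
        assert out == seg and log == []

    def test_log_is_exact(self, rng):
        cfg = SimulationConfig()
        seg = _random_sequence(20_000, 0.36, rng)
        mbar = segment_mean_methylation(seg, 0.05, cfg.meth_init, cfg)
        out, log = mutate_segment(seg, 0.05, mbar, cfg, rng)
        assert len(out) == len(seg)
        for sub in log:
            assert seg[sub.offset] == sub.ref
            assert out[sub.offset] == sub.alt
        untouched = set(range(len(seg))) - {s.offset for s in log}
        assert all(seg[i] == out[i] for i in untouched)

    def test_basal_only_d_at_matches_analytic_expectation(self, rng):
        """d_AT over >= 1e5 sites recovers (f_A + f_T) * basal_rate * age
        within 3 standard errors."""
        cfg = _basal_only()
        age = 0.03
        seg = _random_sequence(200_000, 0.36, rng)
        out, _log = mutate_segment(seg, age, None, cfg, rng)
        spec = count_substitutions(seg, out)
        d_hat = at_transversion_distance(spec)
        expect = expected_d_at(seg, age, cfg.basal_rate)
        n_at = seg.count("A") + seg.count("T")
        q = cfg.basal_rate * age
        se = np.sqrt(n_at * q * (1 - q)) / len(seg)
        assert abs(d_hat - expect) <= 3 * se

    def test_strong_deamination_drives_ratio_far_below_one(self, rng):
        """deamination >> basal with full, non-decaying methylation: the
        transition ratio collapses toward b/(b + d)."""
        cfg = SimulationConfig(
            basal_rate=0.5,
            deamination_rate=10.0,
            meth_init=1.0,
            meth_decay=0.0,
            flank_meth=1.0,
            te_meth_boost=0.0,
        )
        age = 0.05
        seg = _random_sequence(150_000, 0.5, rng)
        mbar = segment_mean_methylation(seg, age, cfg.meth_init, cfg)
        out, log = mutate_segment(seg, age, mbar, cfg, rng)
        ratio = transition_ratio(count_substitutions(seg, out))
        assert ratio < 0.3
        # at 50% GC the composition prefactor is 1, so the expectation is
        # close to b / (b + d * m) with m slightly below 1 (edge cytosines)
        assert ratio == pytest.approx(
            cfg.basal_rate / (cfg.basal_rate + cfg.deamination_rate), rel=0.25
        )
        assert any(s.cause == "deamination" for s in log)

    def test_deamination_is_strand_symmetric(self, rng):
        cfg = SimulationConfig(
            basal_rate=0.0, deamination_rate=10.0, meth_init=1.0,
            meth_decay=0.0, flank_meth=1.0, te_meth_boost=0.0,
        )
        seg = _random_sequence(100_000, 0.5, rng)
        mbar = segment_mean_methylation(seg, 0.05, cfg.meth_init, cfg)
        out, _ = mutate_segment(seg, 0.05, mbar, cfg, rng)
        spec = count_substitutions(seg, out)
        ct, ga = spec.counts[("C", "T")], spec.counts[("G", "A")]
        assert ct > 0 and ga > 0
        assert abs(ct - ga) / (ct + ga) < 0.1
        # nothing but deamination products
        others = spec.n_substitutions - ct - ga
        assert others == 0


class TestInsertNupts:
    def test_zero_insertions_leaves_genome_unchanged(self, rng):
        cfg = SimulationConfig(n_insertions=0)
        nuclear = {"chr1": _random_sequence(10_000, 0.36, rng)}
        plastid = _random_sequence(5_000, 0.36, rng)
        genome, truth = insert_nupts(nuclear, plastid, cfg, rng)
        assert genome == nuclear
        assert len(truth) == 0

    def test_age_zero_basal_zero_identical_to_source(self, rng):
        cfg = _basal_only(
            basal_rate=0.0, n_insertions=5, age_range=(0.0, 0.0),
            n_chromosomes=1, chromosome_lengths=(50_000,), plastid_length=20_000,
        )
        plastid = simulate_plastid_genome(cfg, rng)
        nuclear = {"chr1": _random_sequence(50_000, 0.36, rng)}
        genome, truth = insert_nupts(nuclear, plastid, cfg, rng)
        for ins in truth.insertions:
            src = plastid[ins.plastid_start : ins.plastid_end]
            if ins.strand == "-":
                src = reverse_complement(src)
            assert genome[ins.chrom][ins.start : ins.end] == src
            assert ins.substitutions == []

    def test_truth_log_reproduces_spectrum_exactly(self, small_sim):
        """Re-aligning every inserted segment to its source reproduces the
        logged substitutions one for one (oracle equivalence)."""
        res = small_sim
        for ins in res.truth.insertions:
            src = res.plastid[ins.plastid_start : ins.plastid_end]
            if ins.strand == "-":
                src = reverse_complement(src)
            obs = res.genome[ins.chrom][ins.start : ins.end]
            spec = count_substitutions(src, obs)
            logged = Counter((s.ref, s.alt) for s in ins.substitutions)
            assert dict(logged) == {k: v for k, v in spec.counts.items() if v}

    def test_insertions_do_not_overlap(self, small_sim):
        by_chrom = {}
        for ins in small_sim.truth.insertions:
            by_chrom.setdefault(ins.chrom, []).append((ins.start, ins.end))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_impossible_placement_raises(self, rng):
        cfg = SimulationConfig(
            n_insertions=30, n_chromosomes=1, chromosome_lengths=(4_000,),
            insertion_length_range=(1_000, 1_000), plastid_length=50_000,
        )
        plastid = _random_sequence(50_000, 0.36, rng)
        nuclear = {"chr1": _random_sequence(4_000, 0.36, rng)}
        with pytest.raises(ValueError, match="overlap"):
            insert_nupts(nuclear, plastid, cfg, rng)

    def test_truth_methylation_follows_decay_curve(self, small_sim):
        cfg = small_sim.config
        for ins in small_sim.truth.insertions:
            for c in CONTEXTS:
                assert ins.meth_levels[c] == pytest.approx(
                    current_methylation(
                        ins.age, ins.meth_init_eff[c], cfg.meth_decay[c], cfg.flank_meth[c]
                    )
                )


class TestSimulateMethylome:
    def test_zero_level_zero_error_all_unmethylated(self, rng):
        cfg = SimulationConfig(
            n_insertions=0, meth_init=0.0, flank_meth=0.0, conversion_error=0.0,
            n_chromosomes=1, chromosome_lengths=(20_000,),
        )
        genome = {"chr1": _random_sequence(20_000, 0.36, rng)}
        from nuptools.synthetic import SyntheticTruth

        table = simulate_methylome(genome, SyntheticTruth(), cfg, rng=rng)
        assert len(table) > 0
        assert (table.frame["meth"] == 0).all()

    def test_known_level_recovered_by_pooling(self, rng):
        cfg = SimulationConfig(
            n_insertions=0, meth_init=0.3, flank_meth=0.3, conversion_error=0.0,
            n_chromosomes=1, chromosome_lengths=(30_000,),
        )
        genome = {"chr1": _random_sequence(30_000, 0.36, rng)}
        from nuptools.synthetic import SyntheticTruth

        table = simulate_methylome(genome, SyntheticTruth(), cfg, rng=rng)
        cpg = table.frame[table.frame["context"] == "CpG"]
        assert len(cpg) >= 1000
        level = weighted_methylation(list(zip(cpg["meth"], cpg["unmeth"])))
        assert level == pytest.approx(0.30, abs=0.02)

    def test_mutant_effect_zero_leaves_conversion_error_floor(self, small_sim, rng):
        cfg_dict = {**small_sim.config.__dict__, "mutant_effect": 0.0}
        cfg = SimulationConfig(**{k: v for k, v in cfg_dict.items()
                                  if k in SimulationConfig.__dataclass_fields__})
        table = simulate_methylome(
            small_sim.genome, small_sim.truth, cfg, mutant=True, rng=rng
        )
        ins = max(small_sim.truth.insertions, key=lambda i: i.length)
        sites = table.sites_in(ins.chrom, ins.start, ins.end)
        level = weighted_methylation(list(zip(sites["meth"], sites["unmeth"])))
        assert level == pytest.approx(cfg.conversion_error, abs=0.02)

    def test_context_labels_match_classifier(self, small_sim):
        from nuptools.methylome import classify_context

        frame = small_sim.methylome_wt.frame.sample(200, random_state=0)
        for row in frame.itertuples(index=False):
            assert (
                classify_context(small_sim.genome, row.chrom, int(row.pos), row.strand)
                == row.context
            )


class TestAnnotations:
    def test_zero_te_density_gives_empty_track(self, rng):
        cfg = SimulationConfig(
            n_insertions=0, te_density=0.0, n_chromosomes=1,
            chromosome_lengths=(50_000,), gene_density=5.0,
        )
        from nuptools.synthetic import SyntheticTruth

        genome = {"chr1": _random_sequence(50_000, 0.36, rng)}
        genes, tes = simulate_annotations(genome, SyntheticTruth(), cfg, rng)
        assert tes == []
        assert len(genes) > 0

    def test_tracks_are_non_overlapping_and_sorted(self, small_sim):
        for track in (small_sim.genes, small_sim.tes):
            by_chrom = {}
            for c, s, e, _st, _ty in track:
                by_chrom.setdefault(c, []).append((s, e))
            for ivs in by_chrom.values():
                assert ivs == sorted(ivs)
                assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_fixed_seed_byte_identical_bed(self, tmp_path):
        cfg = SimulationConfig(
            seed=9, n_insertions=10, n_chromosomes=1,
            chromosome_lengths=(60_000,), plastid_length=20_000,
        )
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        write_bed(simulate_dataset(cfg).tes, p1)
        write_bed(simulate_dataset(cfg).tes, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_te_enrichment_couples_to_methylation(self):
        """Planted scenario: TE enrichment near half the insertions with a
        methylation boost and no decay -> positive TE-count/methylation
        correlation recovered by the context machinery."""
        from nuptools.context import AnnotationTrack, count_in_flanks, pearson_correlation
        from nuptools.methylome import summarize_interval

        cfg = SimulationConfig(
            seed=21, n_insertions=80, n_chromosomes=1, chromosome_lengths=(400_000,),
            plastid_length=60_000, meth_decay=0.0, deamination_rate=5.0,
            te_enrichment_factor=5.0, te_meth_boost=0.4, te_enriched_fraction=0.5,
        )
        res = simulate_dataset(cfg)
        track = AnnotationTrack(res.tes)
        xs, ys = [], []
        for ins in res.truth.insertions:
            s = summarize_interval(res.methylome_wt, ins.chrom, ins.start, ins.end)
            if s.level("CpG") is None:
                continue
            xs.append(
                count_in_flanks(
                    (ins.chrom, ins.start, ins.end), track, 5_000,
                    chrom_length=len(res.genome[ins.chrom]),
                )
            )
            ys.append(s.level("CpG"))
        rho, p = pearson_correlation(xs, ys)
        assert rho > 0.3
        assert p < 0.01


class TestDeterminism:
    def test_same_config_identical_outputs(self):
        cfg = dict(
            seed=13, n_insertions=15, n_chromosomes=1,
            chromosome_lengths=(80_000,), plastid_length=25_000,
        )
        a = simulate_dataset(SimulationConfig(**cfg))
        b = simulate_dataset(SimulationConfig(**cfg))
        assert a.plastid == b.plastid
        assert a.genome == b.genome
        assert a.genes == b.genes and a.tes == b.tes
        assert a.methylome_wt.frame.equals(b.methylome_wt.frame)
        assert a.methylome_mutant.frame.equals(b.methylome_mutant.frame)
        for x, y in zip(a.truth.insertions, b.truth.insertions):
            assert x == y
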