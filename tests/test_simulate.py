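"""Synthetic-genome construction, read simulation and down-sampling."""

import numpy as np
import pytest
from scipy import stats

from tebench.core_io import Interval, ReferenceGenome, SimConfig, TELibrary
from tebench.simulate import (
    build_synthetic_genome,
    downsample,
    plan_insertion,
    reverse_complement,
    simulate_reads,
    InsertionPlan,
)


class TestPlanInsertion:
    def test_forced_plan(self, tiny_genome):
        lib = TELibrary({"TY1": "ACGT"})
        sites = [Interval("chrI", 100, 101)]
        cfg = SimConfig(strand_policy="fixed+", tsd_len=5)
        for seed in (0, 1, 99):
            plan = plan_insertion(tiny_genome, lib, sites, cfg, np.random.default_rng(seed))
            assert plan == InsertionPlan("chrI", 100, "TY1", "+", 5)

    def test_equal_width_sites_drawn_uniformly(self, tiny_genome, tiny_library):
        sites = [Interval("chrI", 0, 100), Interval("chrII", 0, 100)]
        cfg = SimConfig()
        rng = np.random.default_rng(2024)
        counts = {"chrI": 0, "chrII": 0}
        for _ in range(10_000):
            counts[plan_insertion(tiny_genome, tiny_library, sites, cfg, rng).chrom] += 1
        chi2 = sum((c - 5000) ** 2 / 5000 for c in counts.values())
        assert chi2 < stats.chi2.ppf(0.99, df=1)

    def test_width_proportional_sampling(self, tiny_genome, tiny_library):
        # 3:1 width ratio -> 3:1 expected draws
        sites = [Interval("chrI", 0, 300), Interval("chrII", 0, 100)]
        rng = np.random.default_rng(5)
        n = 8000
        hits = sum(
            plan_insertion(tiny_genome, tiny_library, sites, SimConfig(), rng).chrom == "chrI"
            for _ in range(n)
        )
        se = np.sqrt(n * 0.75 * 0.25)
        assert abs(hits - 0.75 * n) < 4 * se

    def test_deterministic_given_seed(self, tiny_genome, tiny_library):
        sites = [Interval("chrI", 0, 500)]
        cfg = SimConfig(seed=9)
        p1 = plan_insertion(tiny_genome, tiny_library, sites, cfg, np.random.default_rng(9))
        p2 = plan_insertion(tiny_genome, tiny_library, sites, cfg, np.random.default_rng(9))
        assert p1 == p2

    def test_empty_or_degenerate_sites_rejected(self, tiny_genome, tiny_library):
        with pytest.raises(ValueError):
            plan_insertion(tiny_genome, tiny_library, [], SimConfig(), np.random.default_rng(0))
        with pytest.raises(ValueError, match="narrower"):
            plan_insertion(
                tiny_genome, tiny_library, [Interval("chrI", 5, 5)], SimConfig(),
                np.random.default_rng(0),
            )


class TestBuildSyntheticGenome:
    def test_worked_example(self):
        genome = ReferenceGenome({"c": "ACGTACGTAC"})
        lib = TELibrary({"TE": "TTTT"})
        syn, truth = build_synthetic_genome(genome, lib, InsertionPlan("c", 4, "TE", "+", 2))
        assert syn["c"] == "ACGTACTTTTACGTAC"
        assert len(syn["c"]) == 16
        assert (truth.tsd_start, truth.tsd_end) == (4, 6)

    def test_zero_tsd(self):
        genome = ReferenceGenome({"c": "ACGTACGTAC"})
        lib = TELibrary({"TE": "TTTT"})
        syn, truth = build_synthetic_genome(genome, lib, InsertionPlan("c", 4, "TE", "+", 0))
        assert len(syn["c"]) == len(genome["c"]) + 4
        assert truth.tsd_len == 0

    def test_five_bp_flanks_identical(self, toy):
        """The duplicated target site appears immediately 5' and 3' of the TE."""
        plan = InsertionPlan("chrI", 12_345, "TY1", "+", 5)
        syn, truth = build_synthetic_genome(toy.genome, toy.library, plan)
        te_len = len(toy.library.consensus["TY1"])
        p = plan.breakpoint
        left = syn["chrI"][p : p + 5]
        right = syn["chrI"][p + 5 + te_len : p + 10 + te_len]
        assert left == right == toy.genome["chrI"][p : p + 5]

    def test_length_conservation_property(self, toy, rng):
        for _ in range(20):
            fam = toy.library.families[rng.integers(0, 3)]
            chrom = list(toy.genome.sequences)[rng.integers(0, 3)]
            p = int(rng.integers(0, len(toy.genome[chrom]) - 10))
            strand = "+" if rng.random() < 0.5 else "-"
            plan = InsertionPlan(chrom, p, fam, strand, 5)
            syn, _ = build_synthetic_genome(toy.genome, toy.library, plan)
            assert len(syn[chrom]) - len(toy.genome[chrom]) == len(toy.library.consensus[fam]) + 5

    def test_excision_reconstructs_reference(self, toy):
        plan = InsertionPlan("chrII", 7_000, "TY2", "-", 5)
        syn, truth = build_synthetic_genome(toy.genome, toy.library, plan)
        te_len = len(toy.library.consensus["TY2"])
        s = syn["chrII"]
        p = truth.tsd_start
        # drop the TE plus one TSD copy
        restored = s[: p + 5] + s[p + 5 + te_len + 5 :]
        assert restored == toy.genome["chrII"]

    def test_minus_strand_is_reverse_complement_of_plus(self, toy):
        plus, _ = build_synthetic_genome(
            toy.genome, toy.library, InsertionPlan("chrI", 9_000, "TY3", "+", 5)
        )
        minus, _ = build_synthetic_genome(
            toy.genome, toy.library, InsertionPlan("chrI", 9_000, "TY3", "-", 5)
        )
        te = toy.library.consensus["TY3"]
        start = 9_000 + 5
        assert minus["chrI"][start : start + len(te)] == reverse_complement(te)
        assert plus["chrI"][start : start + len(te)] == te

    def test_errors(self, toy):
        with pytest.raises(ValueError, match="family"):
            build_synthetic_genome(toy.genome, toy.library, InsertionPlan("chrI", 0, "NOPE", "+", 5))
        with pytest.raises(ValueError, match="exceeds"):
            build_synthetic_genome(
                toy.genome, toy.library, InsertionPlan("chrI", 39_998, "TY1", "+", 5)
            )


class TestSimulateReads:
    def test_pair_count_formula(self, rng):
        genome = ReferenceGenome({"c": "ACGT" * 2500})  # L = 10,000
        cfg = SimConfig(read_len=100, insert_mean=300, insert_sd=0)
        reads = simulate_reads(genome, cfg, 10, rng)
        assert reads.n_pairs == 500  # round(10 * 10000 / (2*100))

    def test_error_free_reads_are_substrings(self, toy, rng):
        cfg = SimConfig(read_len=80, insert_mean=250, insert_sd=20, error_rate=0.0)
        sub = ReferenceGenome({"chrI": toy.genome["chrI"][:5000]})
        reads = simulate_reads(sub, cfg, 4, rng)
        seq = sub["chrI"]
        for r1, r2 in zip(reads.mate1, reads.mate2):
            assert r1.seq in seq
            assert reverse_complement(r2.seq) in seq

    def test_mate_ids_and_lengths(self, toy, rng):
        cfg = SimConfig(read_len=60, insert_mean=200)
        sub = ReferenceGenome({"chrI": toy.genome["chrI"][:4000]})
        reads = simulate_reads(sub, cfg, 3, rng)
        assert len(reads.mate1) == len(reads.mate2)
        for r1, r2 in zip(reads.mate1, reads.mate2):
            assert r1.id[:-2] == r2.id[:-2]
            assert r1.id.endswith("/1") and r2.id.endswith("/2")
            assert len(r1.seq) == len(r2.seq) == 60

    def test_empirical_depth_matches_target(self, rng):
        """Brute-force interval stacking recovers the requested fold-coverage."""
        L, cov, rl = 20_000, 30, 100
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=L)])
        genome = ReferenceGenome({"c": seq})
        cfg = SimConfig(read_len=rl, insert_mean=300, insert_sd=30, error_rate=0.0)
        reads = simulate_reads(genome, cfg, cov, rng)
        # total sequenced bases / L is the mean depth by construction
        total = sum(len(r.seq) for r in reads.mate1) + sum(len(r.seq) for r in reads.mate2)
        assert abs(total / L - cov) < 0.01 * cov
        # relocate every read by exact search and stack intervals
        depth = np.zeros(L)
        for r in reads.mate1:
            i = seq.find(r.seq)
            assert i >= 0
            depth[i : i + rl] += 1
        for r in reads.mate2:
            i = seq.find(reverse_complement(r.seq))
            assert i >= 0
            depth[i : i + rl] += 1
        inner = depth[500:-500]
        assert abs(inner.mean() - cov) < 3 * np.sqrt(cov)  # per-base binomial SD

    def test_error_rate_calibration(self, rng):
        genome = ReferenceGenome({"c": "A" * 20_000})
        cfg = SimConfig(read_len=100, insert_mean=300, error_rate=0.05)
        reads = simulate_reads(genome, cfg, 10, rng)
        bases = "".join(r.seq for r in reads.mate1)
        # mate1 comes from the forward strand of an all-A genome
        n = len(bases)
        errs = sum(b != "A" for b in bases)
        se = np.sqrt(n * 0.05 * 0.95)
        assert abs(errs - 0.05 * n) < 4 * se

    def test_single_end_mode(self, toy, rng):
        cfg = SimConfig(read_len=50, paired=False)
        sub = ReferenceGenome({"chrI": toy.genome["chrI"][:10_000]})
        reads = simulate_reads(sub, cfg, 5, rng)
        assert not reads.paired
        assert reads.n_pairs == round(5 * 10_000 / 50)

    def test_validation(self, rng):
        genome = ReferenceGenome({"c": "ACGT" * 100})
        with pytest.raises(ValueError, match="coverage"):
            simulate_reads(genome, SimConfig(), 0, rng)
        with pytest.raises(ValueError, match="insert_mean"):
            simulate_reads(genome, SimConfig(read_len=100, insert_mean=50), 5, rng)
        with pytest.raises(NotImplementedError):
            simulate_reads(genome, SimConfig(simulator="art"), 5, rng)


class TestDownsample:
    def test_identity_when_target_not_below(self, toy, rng):
        cfg = SimConfig(read_len=50, insert_mean=200)
        sub = ReferenceGenome({"chrI": toy.genome["chrI"][:5000]})
        reads = simulate_reads(sub, cfg, 10, rng)
        assert downsample(reads, 10, 10, rng) is reads
        assert downsample(reads, 10, 50, rng) is reads

    def test_binomial_keep_fraction(self, rng):
        genome = ReferenceGenome({"c": "ACGT" * 25_000})
        cfg = SimConfig(read_len=100, insert_mean=300)
        reads = simulate_reads(genome, cfg, 40, rng)  # 20,000 pairs
        n = reads.n_pairs
        out = downsample(reads, 100, 50, rng)
        p = 0.5
        se = np.sqrt(n * p * (1 - p))
        assert abs(out.n_pairs - n * p) < 3 * se
        # mates stay together
        for r1, r2 in zip(out.mate1, out.mate2):
            assert r1.id[:-2] == r2.id[:-2]

    def test_deterministic(self, toy):
        cfg = SimConfig(read_len=50, insert_mean=200)
        sub = ReferenceGenome({"chrI": toy.genome["chrI"][:5000]})
        reads = simulate_reads(sub, cfg, 20, np.random.default_rng(3))
        a = downsample(reads, 20, 10, np.random.default_rng(11))
        b = downsample(reads, 20, 10, np.random.default_rng(11))
        assert a.mate1 == b.mate1 and a.mate2 == b.mate2

    def test_target_must_be_positive(self, toy, rng):
        cfg = SimConfig(read_len=50, insert_mean=200)
        sub = ReferenceGenome({"chrI": toy.genome["chrI"][:5000]})
        reads = simulate_reads(sub, cfg, 5, rng)
        with pytest.raises(ValueError):
            downsample(reads, 5, 0, rng)
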