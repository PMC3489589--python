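"""Simulator contracts: determinism, ground truth, bias direction."""

import numpy as np
import pytest

from ligbias.profiles import build_construct
from ligbias.sequences import AdapterSet, trim_read
from ligbias.simulate import (
    SimulationConfig,
    make_read,
    simulate_duplex_counts,
    simulate_hd_vs_standard,
    simulate_library,
    write_reads_fasta,
)
from ligbias.mirna import detect_arm_switch


@pytest.fixture
def toy_std():
    return AdapterSet("GUUCAGAGUU", "AUCUCGUAUG", 0)


@pytest.fixture
def toy_hd():
    return AdapterSet("GUUCAGAGUU", "AUCUCGUAUG", 4)


class TestSimulateLibrary:
    def test_identical_seeds_identical_outputs(self, toy_std):
        cfg = SimulationConfig(insert_length=6, pool_size=300, depth=2000,
                               beta3=1.0, seed=11)
        a, b = simulate_library(cfg, toy_std), simulate_library(cfg, toy_std)
        assert a.table.counts == b.table.counts
        assert np.array_equal(a.truth.weights, b.truth.weights)

    def test_weights_normalized_and_positive(self, toy_std):
        cfg = SimulationConfig(insert_length=6, pool_size=200, depth=500,
                               beta3=2.0, beta5=2.0, seed=0)
        lib = simulate_library(cfg, toy_std)
        assert lib.truth.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(lib.truth.weights > 0)

    def test_unbiased_sampling_is_uniform_multinomial(self):
        """beta = 0 gives exactly uniform weights (Poisson-compatible null)."""
        cfg = SimulationConfig(insert_length=6, pool_size=500, depth=100, seed=4)
        lib = simulate_library(cfg)
        assert np.allclose(lib.truth.weights, 1 / 500)

    def test_pool_exceeding_space_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(insert_length=3, pool_size=100, depth=10)

    def test_depth_and_distinct_bookkeeping(self, toy_std):
        cfg = SimulationConfig(insert_length=6, pool_size=400, depth=3000, seed=9)
        lib = simulate_library(cfg, toy_std)
        assert lib.table.total_reads == 3000
        assert lib.table.n_distinct <= 400

    def test_hd_run_records_tag_provenance(self, toy_hd):
        cfg = SimulationConfig(insert_length=6, pool_size=50, depth=400,
                               tag_length=4, tag_samples=4, seed=2)
        lib = simulate_library(cfg, toy_hd)
        assert sum(lib.tagged_counts.values()) == 400
        for (insert, pair) in lib.tagged_counts:
            assert len(insert) == 6 and len(pair.tag5) == 4

    def test_emitted_reads_round_trip_through_trimming(self, toy_hd, tmp_path):
        """Raw reads written by the simulator trim back to pool inserts."""
        cfg = SimulationConfig(insert_length=16, pool_size=30, depth=100,
                               tag_length=4, tag_samples=4, seed=3)
        lib = simulate_library(cfg, toy_hd)
        pool = set(lib.truth.inserts)
        for (insert, pair) in lib.tagged_counts:
            read = make_read(insert, toy_hd, pair.tag5, pair.tag3)
            res = trim_read(read, toy_hd, min_insert=16)
            assert res.ok and res.insert in pool
        path = tmp_path / "reads.fasta"
        n = write_reads_fasta(lib, toy_hd, path, max_reads=50)
        assert n == 50
        assert path.read_text().count(">") == 50

    def test_beta3_increases_junction_pairing_monotonically(self, toy_std):
        """Mean pairing of the base upstream of the 3' junction, weighted by
        sampling probability, rises over the bias grid beta3 in {0,1,2,3}."""
        means = []
        for beta3 in (0.0, 1.0, 2.0, 3.0):
            cfg = SimulationConfig(insert_length=7, pool_size=128, depth=1000,
                                   beta3=beta3, seed=21)
            lib = simulate_library(cfg, toy_std)
            from ligbias.folding import fold

            paired = []
            for ins, w in zip(lib.truth.inserts, lib.truth.weights):
                seq, ctx = build_construct(ins, toy_std, "insert_plus_3")
                mask = fold(seq).paired_mask()
                paired.append(w * mask[ctx.junction3 - 1])
            means.append(sum(paired))
        assert means == sorted(means)
        assert means[-1] > means[0]


class TestHdVsStandard:
    def test_unbiased_arms_statistically_indistinguishable(self, toy_std, toy_hd):
        """With beta = 0 both arms are uniform samples of the same pool:
        capture fractions agree within 3 binomial standard errors."""
        diffs = []
        for seed in range(4):
            cfg = SimulationConfig(insert_length=7, pool_size=512, depth=1024,
                                   tag_samples=4, seed=seed)
            cmp = simulate_hd_vs_standard(cfg, toy_std, toy_hd)
            q = 1 - np.exp(-2.0)  # expected capture at lambda = 2
            se = np.sqrt(2 * q * (1 - q) / 512)
            diffs.append(abs(cmp.capture_hd - cmp.capture_standard) < 3 * se)
        assert sum(diffs) >= 3

    def test_biased_hd_captures_more(self, toy_std, toy_hd):
        cfg = SimulationConfig(insert_length=8, pool_size=128, depth=512,
                               beta3=3.0, beta5=3.0, tag_samples=8, seed=0)
        cmp = simulate_hd_vs_standard(cfg, toy_std, toy_hd)
        assert cmp.capture_hd > cmp.capture_standard


class TestDuplexSimulator:
    def test_zero_switch_fraction_gives_zero_switches(self):
        dups, truth, ta, tb = simulate_duplex_counts(60, 0.0, seed=1)
        assert truth == set()
        calls, _ = detect_arm_switch(dups, sorted(ta), sorted(tb), ta, tb, 10.0)
        assert sum(1 for c in calls if c.direction == -1) == 0

    def test_truth_labels_match_requested_fraction(self):
        dups, truth, *_ = simulate_duplex_counts(100, 0.12, seed=2)
        assert len(truth) == 12
        assert len(dups) == 100

    def test_all_counts_below_threshold_empty_analysis(self):
        dups, truth, ta, tb = simulate_duplex_counts(
            20, 0.5, mean_expression=0.05, seed=3
        )
        # inflate totals so every strand sits below the RPM floor
        ta = {k: 10_000_000 for k in ta}
        tb = {k: 10_000_000 for k in tb}
        calls, n = detect_arm_switch(dups, sorted(ta), sorted(tb), ta, tb, 10.0)
        assert n == 0
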