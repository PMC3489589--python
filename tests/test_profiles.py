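"""Construct building, pairing profiles, and structure/abundance statistics."""

import numpy as np
import pytest

from ligbias.profiles import (
    FoldingContext,
    PairingProfile,
    build_construct,
    combine_replicates,
    junction_pairing_fraction,
    mfe_abundance_correlation,
    pairing_profile,
    profile_similarity,
    top_abundant,
)
from ligbias.sequences import AdapterSet, ReadCountTable


class TestBuildConstruct:
    def test_insert_only(self, toy_adapters):
        seq, ctx = build_construct("AAA", toy_adapters, "insert_only")
        assert seq == "AAA"
        assert ctx.junction5 is None and ctx.junction3 is None

    def test_insert_plus_3_junction_index(self):
        ad = AdapterSet("CCCCCCCC", "GGGGGGGG", 0)
        seq, ctx = build_construct("AAA", ad, "insert_plus_3")
        assert seq == "AAA" + "GGGGGGGG"
        assert ctx.junction3 == 3

    def test_hd_full_construct_junctions(self):
        """Junctions sit at the first insert base and the first 3'-tag base;
        verified by segment-length arithmetic."""
        ad = AdapterSet("CC", "GG", 2)
        seq, ctx = build_construct("AAA", ad, "full_construct", tag5="AU", tag3="GC")
        assert seq == "CC" + "AU" + "AAA" + "GC" + "GG"
        assert ctx.junction5 == len("CC") + len("AU") == 4
        assert ctx.junction3 == 4 + len("AAA") == 7

    def test_tag_mode_mismatch(self, toy_adapters, toy_hd_adapters):
        with pytest.raises(ValueError):
            build_construct("AAA", toy_hd_adapters, "full_construct")  # tags missing
        with pytest.raises(ValueError):
            build_construct("AAA", toy_adapters, "full_construct", tag5="AU", tag3="GC")

    def test_context_invariants_enforced(self):
        with pytest.raises(ValueError):
            FoldingContext("full_construct", junction5=3)
        with pytest.raises(ValueError):
            FoldingContext("insert_only", junction3=2)


class TestPairingProfile:
    def test_unpairable_molecules_give_zero_profile(self, toy_adapters):
        mols = [build_construct("AAAAAAAA", AdapterSet("AAAA", "AAAA", 0), "insert_plus_3")
                for _ in range(3)]
        prof = pairing_profile(mols)
        assert np.all(prof.frequency == 0)

    def test_single_hairpin_profile_is_indicator(self):
        mols = [("GGGAAAACCC", FoldingContext("insert_only"))]
        prof = pairing_profile(mols)
        assert list(prof.frequency) == [1, 1, 1, 0, 0, 0, 0, 1, 1, 1]

    def test_mixed_lengths_rejected(self):
        ctx = FoldingContext("insert_only")
        with pytest.raises(ValueError, match="length"):
            pairing_profile([("AAAA", ctx), ("AAAAA", ctx)])

    def test_mixture_identity(self):
        """Profile of a union equals the molecule-weighted average of the
        two sub-profiles, exactly."""
        ctx = FoldingContext("insert_only")
        a = [("GGGAAAACCC", ctx), ("GCGCAAAACG", ctx)]
        b = [("AUAUAUAUAU", ctx), ("GGCCAAAAGG", ctx), ("ACGUACGUAC", ctx)]
        pa, pb, pu = (pairing_profile(m) for m in (a, b, a + b))
        mix = (2 * pa.frequency + 3 * pb.frequency) / 5
        assert np.allclose(pu.frequency, mix)

    def test_adding_one_molecule_moves_each_frequency_at_most_1_over_n(self):
        ctx = FoldingContext("insert_only")
        mols = [("GGGAAAACCC", ctx), ("ACGUACGUAC", ctx), ("GCGCAAAACG", ctx)]
        before = pairing_profile(mols).frequency
        after = pairing_profile(mols + [("GGCCAAAAGG", ctx)]).frequency
        assert np.max(np.abs(after - before)) <= 1 / 4 + 1e-12

    def test_replicate_bands(self):
        ctx = FoldingContext("insert_only")
        p1 = pairing_profile([("GGGAAAACCC", ctx)])
        p2 = pairing_profile([("ACGUACGUAC", ctx)])
        comb = combine_replicates([p1, p2])
        assert np.all(comb.min_rep <= comb.frequency)
        assert np.all(comb.frequency <= comb.max_rep)


class TestJunctionPairingFraction:
    def test_zero_profile(self):
        prof = PairingProfile(np.zeros(10), 5)
        assert junction_pairing_fraction(prof, 4, "upstream") == 0.0

    def test_accessor_reads_the_adjacent_base(self):
        freq = np.zeros(10)
        freq[4] = 0.53
        freq[3] = 0.25
        prof = PairingProfile(freq, 100)
        assert junction_pairing_fraction(prof, 4, "downstream") == pytest.approx(0.53)
        assert junction_pairing_fraction(prof, 4, "upstream") == pytest.approx(0.25)

    def test_edge_junction_rejected(self):
        prof = PairingProfile(np.zeros(5), 1)
        with pytest.raises(ValueError):
            junction_pairing_fraction(prof, 0, "upstream")
        with pytest.raises(ValueError):
            junction_pairing_fraction(prof, 5, "downstream")


class TestProfileSimilarity:
    def test_identical_profiles(self):
        p = PairingProfile(np.array([0.1, 0.5, 0.9]), 10)
        assert profile_similarity(p, p) == pytest.approx(1.0)

    def test_sign_invariance(self):
        a = PairingProfile(np.array([0.1, 0.5, 0.9, 0.3]), 10)
        b = PairingProfile(1 - a.frequency, 10)
        assert profile_similarity(a, b) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        a = PairingProfile(np.array([0.5, 0.5, 0.5]), 10)
        b = PairingProfile(np.array([0.1, 0.2, 0.3]), 10)
        with pytest.raises(ValueError):
            profile_similarity(a, b)

    def test_independent_random_profiles_have_small_r2(self):
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(200):
            a = PairingProfile(rng.uniform(size=21), 1)
            b = PairingProfile(rng.uniform(size=21), 1)
            vals.append(profile_similarity(a, b))
        assert np.mean(vals) < 0.15  # ~1/(len-1) order, well below real signal


class TestTopAbundant:
    def test_ranking_correctness(self):
        t = ReadCountTable({"AA": 9, "CC": 4, "GG": 4, "UU": 1})
        sub = top_abundant(t, 2)
        kept_min = min(sub.counts.values())
        dropped_max = max(c for s, c in t.counts.items() if s not in sub.counts)
        assert kept_min >= dropped_max


class TestMfeAbundanceCorrelation:
    def test_monotone_construction_gives_r2_near_one(self, toy_adapters):
        """Counts assigned as an exact monotone (exponential) function of the
        construct MFE give R^2 ~ 1 on the log scale."""
        from ligbias.folding import fold

        seqs = ["GGGAAAACCC", "GCGCAAAACG", "ACGUACGUAC", "GGCCAAAAGG",
                "AUAUAUAUAU", "GGGGAAACCC"]
        counts = {}
        for s in seqs:
            mfe = fold(s + toy_adapters.adapter3).mfe
            counts[s] = int(round(10 ** (-mfe))) - 1  # log10(count+1) = -mfe
        table = ReadCountTable(counts)
        assert mfe_abundance_correlation(table, toy_adapters) > 0.999

    def test_constant_counts_rejected(self, toy_adapters):
        table = ReadCountTable({"GGGAAAACCC": 5, "ACGUACGUAC": 5})
        with pytest.raises(ValueError):
            mfe_abundance_correlation(table, toy_adapters)

    def test_empty_table_rejected(self, toy_adapters):
        with pytest.raises(ValueError):
            mfe_abundance_correlation(ReadCountTable({}), toy_adapters)
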