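"""Masking, consensus ANI, colonist/carriage rules, population census."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainsites import (MaskedRegions, PileupMatrix, call_colonists, carriage,
                         consensus_ani, detection_threshold, mask_genome,
                         same_population, shared_populations)
from strainsites.simulate import simulate_colonization_tables


def uniform_pileup(length, depth, ref="A"):
    """Single-sample pileup where all reads agree with the reference."""
    counts = np.zeros((1, length, 4), dtype=np.int64)
    counts[0, :, "ACGT".index(ref)] = depth
    return PileupMatrix(counts, ref * length)


class TestMasking:
    def test_end_buffer_arithmetic(self):
        masked = mask_genome([1_000], end_buffer=100)
        assert masked.unmasked_length == 800
        assert masked.reasons_at(50) == {"scaffold_end"}
        assert masked.reasons_at(950) == {"scaffold_end"}
        assert masked.reasons_at(500) == set()

    def test_conserved_bed_interval_masked(self):
        bed = pd.DataFrame({"start": [400], "end": [450]})
        masked = mask_genome([1_000], conserved=bed, end_buffer=0)
        assert "conserved" in masked.reasons_at(425)
        assert masked.unmasked_length == 950

    def test_low_coverage_segment_masked(self):
        pm = uniform_pileup(1_000, 10)
        pm.counts[0, 300:350, :] = 0  # zero-depth hole
        masked = mask_genome([1_000], pileup=pm, end_buffer=0, min_depth=5)
        assert "low_coverage" in masked.reasons_at(320)
        assert masked.unmasked_length == 950

    def test_multi_scaffold_ends(self):
        masked = mask_genome([500, 500], end_buffer=50)
        # four scaffold-end buffers of 50 bp
        assert masked.unmasked_length == 1_000 - 4 * 50
        assert "scaffold_end" in masked.reasons_at(520)

    def test_negative_buffer_rejected(self):
        with pytest.raises(ValueError):
            mask_genome([100], end_buffer=-1)

    def test_out_of_bounds_conserved_rejected(self):
        with pytest.raises(ValueError):
            mask_genome([100], conserved=[(50, 200)])

    @given(st.lists(st.tuples(st.integers(0, 900), st.integers(0, 900)), max_size=5))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_masking_monotone(self, intervals):
        """Adding mask intervals never increases the unmasked length."""
        base = mask_genome([1_000], end_buffer=100)
        prev = base.unmasked_length
        for a, b in intervals:
            base.add(min(a, b), max(a, b), "conserved")
            cur = base.unmasked_length
            assert cur <= prev
            prev = cur


class TestConsensusANI:
    def test_exact_formula_with_planted_variants(self):
        pm = uniform_pileup(100_000, 20)
        for pos in range(0, 1_000, 100):  # 10 planted 100%-conflict sites
            pm.counts[0, pos] = [0, 20, 0, 0]
        masked = MaskedRegions(100_000)  # nothing masked
        res = consensus_ani(pm, masked)
        assert res.variant_position_count == 10
        assert res.unmasked_length == 100_000
        assert res.consensus_ani == 1 - 10 / 100_000
        assert res.consensus_ani == pytest.approx(0.9999)

    @pytest.mark.parametrize("conflict,counted", [(0.70, False), (0.80, True), (0.95, True)])
    def test_conflict_threshold_boundary(self, conflict, counted):
        pm = uniform_pileup(1_000, 100)
        k = int(conflict * 100)
        pm.counts[0, 500] = [100 - k, k, 0, 0]
        res = consensus_ani(pm, MaskedRegions(1_000))
        assert res.variant_position_count == (1 if counted else 0)

    def test_no_variants_gives_ani_one(self):
        res = consensus_ani(uniform_pileup(5_000, 10), MaskedRegions(5_000))
        assert res.consensus_ani == 1.0

    def test_masked_variant_not_counted(self):
        pm = uniform_pileup(1_000, 50)
        pm.counts[0, 500] = [0, 50, 0, 0]
        masked = MaskedRegions(1_000)
        masked.add(490, 510, "conserved")
        res = consensus_ani(pm, masked)
        assert res.variant_position_count == 0
        assert res.unmasked_length == 980

    def test_fully_masked_rejected(self):
        masked = MaskedRegions(100)
        masked.add(0, 100, "conserved")
        with pytest.raises(ValueError):
            consensus_ani(uniform_pileup(100, 10), masked)

    def test_matches_bruteforce_recount(self, rng):
        """Vectorised ANI equals a per-position pure-Python recount."""
        L = 2_000
        counts = rng.integers(0, 30, size=(1, L, 4))
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
        pm = PileupMatrix(counts, ref)
        masked = MaskedRegions(L)
        masked.add(100, 300, "conserved")
        res = consensus_ani(pm, masked, conflict_threshold=0.8)
        # oracle: explicit loop
        nvar = 0
        mask = masked.mask_array()
        for pos in range(L):
            if mask[pos]:
                continue
            d = counts[0, pos].sum()
            if d == 0:
                continue
            refc = counts[0, pos, "ACGT".index(ref[pos])]
            if (d - refc) / d >= 0.8:
                nvar += 1
        assert res.variant_position_count == nvar
        assert res.consensus_ani == 1 - nvar / masked.unmasked_length

    def test_sample_vs_own_consensus_is_identity(self, rng):
        """A pileup whose reference is its own consensus has ANI exactly 1."""
        L = 1_000
        counts = np.zeros((1, L, 4), dtype=np.int64)
        maj = rng.integers(0, 4, L)
        counts[0, np.arange(L), maj] = 30
        other = (maj + 1) % 4
        counts[0, np.arange(L), other] = 5   # 14% minor allele everywhere
        ref = "".join("ACGT"[i] for i in maj)
        res = consensus_ani(PileupMatrix(counts, ref), MaskedRegions(L))
        assert res.consensus_ani == 1.0


class TestIdentityRules:
    @pytest.mark.parametrize("ani,expected", [
        (0.99998, True),    # within-strain comparisons
        (0.999, False),     # strict inequality at the boundary
        (0.95, False),
    ])
    def test_same_population_threshold(self, ani, expected):
        assert same_population(ani) is expected

    @pytest.mark.parametrize("breadth,expected", [(0.995, True), (0.99, True), (0.98, False)])
    def test_carriage_threshold(self, breadth, expected):
        assert carriage(breadth) is expected

    def test_carriage_fully_covered_phage(self, rng):
        """A 20x-covered phage has essentially certain full breadth."""
        for seed in range(10):
            depths = np.random.default_rng(seed).poisson(20.0, 40_000)
            breadth = float((depths > 0).mean())
            assert carriage(breadth)


class TestColonists:
    def abundance(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "body_site", "genome_id",
                                           "percent_of_nonhuman_reads"])

    def test_single_site_colonist(self):
        t = self.abundance([("s1", "gut", "g1", 1.5), ("s2", "mouth", "g1", 0.4),
                            ("s3", "skin", "g1", 0.2)])
        flags = call_colonists(t)
        assert flags.loc[("g1", "gut"), "colonist"]
        assert not flags.loc[("g1", "mouth"), "colonist"]
        assert not flags.loc[("g1", "skin"), "colonist"]

    def test_below_threshold_everywhere(self):
        t = self.abundance([("s1", "gut", "g1", 0.9), ("s2", "skin", "g1", 0.9)])
        assert not call_colonists(t)["colonist"].any()

    def test_invariance_to_row_order(self):
        rows = [("s1", "gut", "g1", 2.0), ("s2", "gut", "g2", 0.5),
                ("s3", "mouth", "g1", 0.1)]
        f1 = call_colonists(self.abundance(rows))
        f2 = call_colonists(self.abundance(rows[::-1]))
        pd.testing.assert_frame_equal(f1.sort_index(), f2.sort_index())


class TestDetectionThreshold:
    def table(self):
        return pd.DataFrame({
            "sample_id": ["a", "b"],
            "percent_of_nonhuman_reads": [0.04, 0.01],
            "total_sample_reads": [10_000_000, 40_000_000],
            "read_length": [150, 150],
        })

    def test_cutoff_formula(self):
        cutoff, _ = detection_threshold(self.table(), genome_length=5_000_000)
        # 100 * (0.1 * 5e6 / 150) / 1e7
        assert cutoff == pytest.approx(0.0333333, rel=1e-4)

    def test_presence_boundary_inclusive(self):
        t = self.table()
        cutoff, calls = detection_threshold(t, 5_000_000)
        t2 = t.copy()
        t2.loc[0, "percent_of_nonhuman_reads"] = cutoff
        _, calls2 = detection_threshold(t2, 5_000_000)
        assert calls2.loc[0, "present"]

    def test_single_shared_cutoff(self):
        cutoff, calls = detection_threshold(self.table(), 5_000_000)
        # deeper sample uses the same percent cutoff as the shallowest
        assert calls.loc[0, "present"] == (0.04 >= cutoff)
        assert calls.loc[1, "present"] == (0.01 >= cutoff)

    def test_missing_read_counts_rejected(self):
        t = self.table()
        t.loc[0, "total_sample_reads"] = np.nan
        with pytest.raises(ValueError):
            detection_threshold(t, 1_000_000)


class TestSharedPopulations:
    def test_one_genome_three_sites(self):
        flags = pd.DataFrame(
            {"colonist": [True, True, True]},
            index=pd.MultiIndex.from_tuples(
                [("g1", "gut"), ("g1", "mouth"), ("g1", "skin")],
                names=["genome_id", "body_site"]))
        census = shared_populations(flags, [], {"g1": "infant1"})
        assert census.n_multi_site == 1
        assert census.n_cross_infant == 0

    def test_identical_but_single_site_each(self):
        """Two identical genomes, each colonising one site of different infants."""
        flags = pd.DataFrame(
            {"colonist": [True, True]},
            index=pd.MultiIndex.from_tuples(
                [("g1", "gut"), ("g2", "mouth")], names=["genome_id", "body_site"]))
        census = shared_populations(flags, [("g1", "g2")],
                                    {"g1": "infant1", "g2": "infant2"})
        assert census.n_multi_site == 0
        assert census.n_cross_infant == 1

    def test_synthetic_cohort_census(self):
        abundance, identical, infant_of = simulate_colonization_tables(seed=0)
        flags = call_colonists(abundance)
        census = shared_populations(flags, identical, infant_of)
        assert census.n_multi_site == 7
        assert census.n_cross_infant == 0
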