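"""CRISPR array comparison, protospacer search, variant ratios, SNV links."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from strainsites import (CrisprArray, VariantTrajectory, compare_arrays,
                         correlate_snvs, find_protospacers, unique_regions,
                         variant_array_ratio)
from strainsites.crispr import scan_mismatch
from strainsites.simulate import simulate_crispr_system


def array_from(seqs, array_id="a", repeat="G" * 14 + "C" * 14):
    return CrisprArray(array_id, repeat, [(f"{array_id}{i}", s) for i, s in enumerate(seqs)])


def random_seq(n, rng):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestCompareArrays:
    def test_shared_unique_arithmetic(self):
        a, b, _, _ = simulate_crispr_system(5, 8, 6, 4, seed=3)
        cmp = compare_arrays(a, b)
        assert cmp.n_shared == 5
        assert len(cmp.unique_a) == 8
        assert len(cmp.unique_b) == 6

    def test_self_comparison_identity_alignment(self):
        a, _, _, _ = simulate_crispr_system(3, 4, 2, 4, seed=4)
        cmp = compare_arrays(a, a)
        assert cmp.shared == [(i, i) for i in range(len(a))]
        assert cmp.unique_a == [] and cmp.unique_b == []

    def test_symmetric_shared_count(self):
        a, b, _, _ = simulate_crispr_system(4, 5, 3, 4, seed=5)
        assert compare_arrays(a, b).n_shared == compare_arrays(b, a).n_shared

    def test_strand_agnostic_matching(self):
        rng = np.random.default_rng(6)
        s = random_seq(32, rng)
        a = array_from([s, random_seq(32, rng)], "a")
        b = array_from([reverse_complement(s), random_seq(32, rng)], "b")
        assert compare_arrays(a, b).n_shared == 1

    def test_duplicate_spacer_reported_at_both_positions(self):
        """13 vs 11 spacers with one spacer duplicated in array B."""
        rng = np.random.default_rng(7)
        shared = [random_seq(32, rng) for _ in range(5)]
        ua = [random_seq(32, rng) for _ in range(8)]
        dup = shared[2]
        b_seqs = [random_seq(32, rng) for _ in range(5)] + shared + [dup]
        a = array_from(ua + shared, "a")      # 13 spacers
        b = array_from(b_seqs, "b")           # 11 distinct + 1 duplicate
        cmp = compare_arrays(a, b)
        assert len(a) == 13
        assert cmp.duplicates_b  # the duplicated spacer is tracked
        positions = next(iter(cmp.duplicates_b.values()))
        assert len(positions) == 2

    def test_empty_array_rejected(self):
        with pytest.raises(ValueError):
            CrisprArray("x", "G" * 28, [])


class TestProtospacerSearch:
    def test_planted_exact_and_one_mismatch_found(self):
        a, _, phages, truth = simulate_crispr_system(5, 8, 6, 6, seed=2)
        matches = find_protospacers(a.spacers, phages, [a.repeat], max_mismatch=1)
        found = {(m.spacer_id, m.target_id, m.mismatches) for m in matches}
        assert (truth.exact[0], truth.exact[1], 0) in found
        assert (truth.one_mismatch[0], truth.one_mismatch[1], 1) in found

    def test_two_mismatch_copy_not_found_at_max_one(self):
        a, _, phages, truth = simulate_crispr_system(5, 8, 6, 6, seed=2)
        matches = find_protospacers(a.spacers, phages, [a.repeat], max_mismatch=1)
        assert all(m.target_id != truth.two_mismatch[1] for m in matches)
        # but it is found when two mismatches are allowed
        m2 = find_protospacers(a.spacers, phages, [a.repeat], max_mismatch=2)
        assert any(m.target_id == truth.two_mismatch[1] and m.mismatches == 2
                   for m in m2)

    def test_hits_inside_planted_array_excluded(self):
        """Spacers match their own array in a target, but repeat filtering
        removes those hits."""
        a, _, phages, truth = simulate_crispr_system(5, 8, 6, 6, seed=2)
        assert truth.array_in_phage is not None
        with_filter = find_protospacers(a.spacers, phages, [a.repeat])
        assert all(m.target_id != truth.array_in_phage for m in with_filter)
        without_filter = find_protospacers(a.spacers, phages, repeats=())
        assert any(m.target_id == truth.array_in_phage for m in without_filter)

    def test_exclude_targets_wholesale(self):
        a, _, phages, truth = simulate_crispr_system(5, 8, 6, 6, seed=2)
        matches = find_protospacers(a.spacers, phages, [a.repeat],
                                    exclude_targets={truth.exact[1]})
        assert all(m.target_id != truth.exact[1] for m in matches)

    def test_minus_strand_hit_reported(self):
        rng = np.random.default_rng(8)
        spacer = random_seq(30, rng)
        target = random_seq(200, rng) + reverse_complement(spacer) + random_seq(200, rng)
        matches = find_protospacers([("s", spacer)], [("t", target)])
        assert any(m.strand == "-" and m.position == 200 for m in matches)

    def test_short_spacer_rejected(self):
        with pytest.raises(ValueError):
            find_protospacers([("s", "ACGTACGT")], [("t", "ACGT" * 100)])

    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    def test_scan_agrees_with_bruteforce_hamming(self, max_mm):
        """Seeded scan equals a sliding-window Hamming oracle."""
        rng = np.random.default_rng(max_mm)
        for _ in range(20):
            pattern = random_seq(24, rng)
            text = random_seq(3_000, rng)
            # plant some near-copies
            for nmm in (0, 1, 2, 3):
                pos = int(rng.integers(0, len(text) - 24))
                copy = list(pattern)
                for p in rng.choice(24, nmm, replace=False):
                    copy[p] = "ACGT"[(("ACGT".index(copy[p]) + 1) % 4)]
                text = text[:pos] + "".join(copy) + text[pos + 24:]
            got = set(scan_mismatch(pattern, text, max_mm))
            oracle = set()
            for i in range(len(text) - 24 + 1):
                d = sum(x != y for x, y in zip(pattern, text[i:i + 24]))
                if d <= max_mm:
                    oracle.add((i, d))
            assert got == oracle


class TestVariantRatios:
    def test_simple_ratio(self):
        freq = variant_array_ratio([60], [40])
        assert freq[0] == pytest.approx(0.6)

    def test_zero_reads_no_call(self):
        freq = variant_array_ratio([0, 60], [0, 40])
        assert np.isnan(freq[0])
        assert freq[1] == pytest.approx(0.6)

    def test_length_normalization(self):
        # same raw counts but A's unique region is twice as long
        raw = variant_array_ratio([60], [30], normalize=False)
        norm = variant_array_ratio([60], [30], length_a=200, length_b=100)
        assert raw[0] == pytest.approx(2 / 3)
        assert norm[0] == pytest.approx(0.5)

    def test_freq_sums_to_one(self):
        rng = np.random.default_rng(1)
        ra, rb = rng.integers(1, 100, 20), rng.integers(1, 100, 20)
        fa = variant_array_ratio(ra, rb, 120.0, 90.0)
        fb = variant_array_ratio(rb, ra, 90.0, 120.0)
        assert np.allclose(fa + fb, 1.0)

    def test_poisson_mixture_recovery(self):
        """A 30/70 variant mixture is recovered within +-0.05 over 20 seeds."""
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            reads_a = rng.poisson(0.3 * 500)
            reads_b = rng.poisson(0.7 * 500)
            errs.append(variant_array_ratio([reads_a], [reads_b])[0] - 0.3)
        assert np.all(np.abs(errs) < 0.05)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            variant_array_ratio([-1], [5])


class TestCorrelateSNVs:
    def make_traj(self, freqs, position=0):
        n = len(freqs)
        return VariantTrajectory(position, "A", "G", np.asarray(freqs, float),
                                 np.full(n, 100), [f"S{i}" for i in range(n)])

    def test_identical_series_linked(self):
        series = np.array([0.1, 0.3, 0.6, 0.8, 0.5, 0.2, 0.7, 0.9])
        links = correlate_snvs([self.make_traj(series)], {"variant_A": series})
        assert len(links) == 1
        pos, name, r, p = links[0]
        assert name == "variant_A" and r == pytest.approx(1.0)

    def test_two_tracking_snvs_exactly_linked(self):
        """One SNV tracks variant A, one tracks B; only those two link."""
        rng = np.random.default_rng(3)
        fa = np.clip(0.5 + 0.4 * np.sin(np.linspace(0, 6, 12)), 0, 1)
        fb = 1 - fa
        snv_a = self.make_traj(np.clip(fa + rng.normal(0, 0.01, 12), 0, 1), position=100)
        snv_b = self.make_traj(np.clip(fb + rng.normal(0, 0.01, 12), 0, 1), position=200)
        noise = [self.make_traj(rng.uniform(0, 1, 12), position=300 + i)
                 for i in range(20)]
        links = correlate_snvs([snv_a, snv_b] + noise, {"A": fa, "B": fb})
        linked_positions = {(pos, name) for pos, name, _, p in links}
        assert (100, "A") in linked_positions
        assert (200, "B") in linked_positions
        assert all(pos in (100, 200) for pos, _ in linked_positions)

    def test_null_series_produce_no_links(self):
        """Independent noise: Bonferroni keeps the family error below alpha."""
        total_links = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            snvs = [self.make_traj(rng.uniform(0, 1, 20), position=i)
                    for i in range(200)]
            series = {"A": rng.uniform(0, 1, 20)}
            total_links += len(correlate_snvs(snvs, series, alpha=0.01))
        assert total_links == 0

    def test_constant_series_no_call(self):
        traj = self.make_traj([0.5] * 8)
        links = correlate_snvs([traj], {"A": np.full(8, 0.3)})
        assert links == []

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            correlate_snvs([self.make_traj([0.1, 0.2, 0.3])], {"A": np.ones(5)})


class TestUniqueRegions:
    def test_disjoint_sequences_fully_unique(self):
        rng = np.random.default_rng(9)
        a, b = random_seq(200, rng), random_seq(200, rng)
        regions = unique_regions(a, b, min_length=30)
        assert regions == [(0, 200)]

    def test_identical_sequences_nothing_unique(self):
        rng = np.random.default_rng(10)
        a = random_seq(300, rng)
        assert unique_regions(a, a) == []

    def test_inserted_block_detected(self):
        rng = np.random.default_rng(11)
        core = random_seq(400, rng)
        insert = random_seq(60, rng)
        a = core[:200] + insert + core[200:]
        regions = unique_regions(a, core, min_length=30)
        assert len(regions) == 1
        s, e = regions[0]
        assert s > 150 and e < 300  # covers the inserted block neighbourhood
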