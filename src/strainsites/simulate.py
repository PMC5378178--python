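"""Synthetic communities with the statistical structure the pipeline assumes.

The generator emulates, without touching raw reads, the data a read mapper
would produce from a bacterial population undergoing bidirectional genome
replication:

* a circular genome whose G/C composition is biased per replichore, so GC skew
  is positive on one half and negative on the other (sign flips at ori/ter);
* a coverage track with an exponential origin-to-terminus gradient set by a
  true peak-to-trough ratio (PTR) — expected depth at circular ori-distance
  fraction ``d`` in [0, 0.5] is ``mean_coverage * true_ptr ** (1 - 2 d)``;
* multi-sample pileups obtained by mixing a small number of haplotypes at
  sample-specific frequencies, with per-base sequencing error elsewhere;
* fragmented / shuffled / reverse-complemented draft assemblies;
* paired CRISPR arrays and phage sequences carrying planted protospacers.

Every generator records its ground truth so downstream estimators can be
scored by recovery rather than by eye.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .containers import BASE_ORDER, CoverageTrack, PileupMatrix, base_indices

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_community",
    "simulate_skewed_genome",
    "expected_coverage",
    "simulate_coverage_track",
    "fragment_assembly",
    "simulate_trajectories",
    "simulate_crispr_system",
    "simulate_growth_table",
    "simulate_colonization_tables",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Parameters of one synthetic community.

    ``haplotypes`` is a list of ``{position: alt_base}`` mappings, one per
    mixture component; an empty mapping is the reference haplotype.
    ``haplotype_frequencies`` has shape ``(n_samples, n_haplotypes)`` and each
    row must sum to 1.  ``mean_coverage`` is the expected fold-coverage at the
    replication *terminus*; the origin is covered ``true_ptr`` times deeper.
    """

    genome_length: int = 100_000
    ori_position: int = 0
    ter_position: int | None = None
    skew_amplitude: float = 0.1
    gc_content: float = 0.5
    true_ptr: float = 1.5
    mean_coverage: float = 50.0
    read_length: int = 150
    error_rate: float = 0.0
    n_samples: int = 1
    haplotypes: Sequence[dict[int, str]] = field(default_factory=lambda: [{}])
    haplotype_frequencies: Sequence[Sequence[float]] | None = None
    noise: str = "poisson"  # or "none" for rounded expectations
    make_pileups: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ter_position is None:
            self.ter_position = (self.ori_position + self.genome_length // 2) % self.genome_length
        if self.ori_position == self.ter_position:
            raise ValueError("ori_position and ter_position must differ")
        for p in (self.ori_position, self.ter_position):
            if not 0 <= p < self.genome_length:
                raise ValueError("ori/ter positions must lie within the genome")
        if self.true_ptr < 1.0:
            raise ValueError("true_ptr must be >= 1 (peak over trough)")
        if not 0.0 < self.skew_amplitude <= 1.0:
            raise ValueError("skew_amplitude must be in (0, 1]")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")
        if self.haplotype_frequencies is None:
            # uniform mixture in every sample
            k = len(self.haplotypes)
            self.haplotype_frequencies = [[1.0 / k] * k for _ in range(self.n_samples)]
        freqs = np.asarray(self.haplotype_frequencies, dtype=float)
        if freqs.shape != (self.n_samples, len(self.haplotypes)):
            raise ValueError("haplotype_frequencies must be (n_samples, n_haplotypes)")
        if np.any(np.abs(freqs.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("haplotype frequencies per sample must sum to 1")
        for hap in self.haplotypes:
            for pos, alt in hap.items():
                if not 0 <= pos < self.genome_length:
                    raise ValueError(f"variant position {pos} outside genome")
                if alt not in BASE_ORDER:
                    raise ValueError(f"invalid alt base {alt!r}")

    @property
    def frequencies(self) -> np.ndarray:
        return np.asarray(self.haplotype_frequencies, dtype=float)


@dataclass
class SyntheticTruth:
    """A simulated community together with its ground truth."""

    config: SimulationConfig
    genome: str
    coverage: list[CoverageTrack]            # one per sample
    pileup: PileupMatrix | None              # all samples, or None
    variant_truth: dict[int, str]            # position -> planted alt base
    variant_mixture: np.ndarray              # (n_samples, n_variants) planted alt freq

    @property
    def variant_positions(self) -> np.ndarray:
        return np.array(sorted(self.variant_truth), dtype=np.int64)


# ---------------------------------------------------------------------------
# genome & coverage
# ---------------------------------------------------------------------------

def _replichore_mask(length: int, ori: int, ter: int) -> np.ndarray:
    """True for positions on the replichore running forward from ori to ter."""
    pos = np.arange(length)
    if ori < ter:
        return (pos >= ori) & (pos < ter)
    return (pos >= ori) | (pos < ter)


def simulate_skewed_genome(length: int, ori: int, ter: int, skew_amplitude: float,
                           gc_content: float, rng: np.random.Generator) -> str:
    """Random genome whose GC skew is ``+skew_amplitude`` on the ori->ter
    replichore and ``-skew_amplitude`` on the other, in expectation.

    The skew is imposed through base composition (G enriched over C on the
    leading strand), so downstream skew analysis is exercised on sequence
    rather than on labels.
    """
    at = (1.0 - gc_content) / 2.0
    g_lead = gc_content / 2.0 * (1.0 + skew_amplitude)
    c_lead = gc_content / 2.0 * (1.0 - skew_amplitude)
    lead = _replichore_mask(length, ori, ter)
    # draw per-position bases under the two compositions
    u = rng.random(length)
    probs_lead = np.cumsum([at, c_lead, g_lead, at])   # A, C, G, T
    probs_lag = np.cumsum([at, g_lead, c_lead, at])    # C/G swapped on the lagging replichore
    idx = np.empty(length, dtype=np.int64)
    idx[lead] = np.searchsorted(probs_lead, u[lead], side="right")
    idx[~lead] = np.searchsorted(probs_lag, u[~lead], side="right")
    idx = np.clip(idx, 0, 3)
    return "".join(BASE_ORDER[i] for i in idx) if length < 2_000 else (
        np.frombuffer(BASE_ORDER.encode(), dtype="S1")[idx].tobytes().decode()
    )


def expected_coverage(length: int, ori: int, true_ptr: float, mean_coverage: float) -> np.ndarray:
    """Expected depth per position under bidirectional replication.

    Depth decays exponentially with circular distance from the origin:
    ``mean_coverage * true_ptr ** (1 - 2 d)`` where ``d`` is the ori-distance
    as a fraction of genome length, in [0, 0.5].  The maximum (``mean_coverage
    * true_ptr``) sits at the origin, the minimum (``mean_coverage``) half a
    genome away.
    """
    pos = np.arange(length)
    forward = (pos - ori) % length
    d = np.minimum(forward, length - forward) / length
    return mean_coverage * true_ptr ** (1.0 - 2.0 * d)


def simulate_coverage_track(length: int, ori: int, true_ptr: float, mean_coverage: float,
                            rng: np.random.Generator | None = None,
                            noise: str = "poisson", genome_id: str = "genome") -> CoverageTrack:
    """Draw a realized coverage track around the expected replication gradient.

    ``noise='poisson'`` models independent shotgun sampling per position;
    ``noise='none'`` emits rounded expectations for analytic tests.
    """
    exp = expected_coverage(length, ori, true_ptr, mean_coverage)
    if noise == "none":
        depths = np.round(exp)
    else:
        if rng is None:
            rng = np.random.default_rng()
        depths = rng.poisson(exp).astype(float)
    return CoverageTrack(depths, genome_id=genome_id, circular=True)


def _split_errors(rng: np.random.Generator, errors: np.ndarray) -> np.ndarray:
    """Split per-position error counts uniformly over 3 non-reference bases."""
    n1 = rng.binomial(errors, 1.0 / 3.0)
    n2 = rng.binomial(errors - n1, 0.5)
    n3 = errors - n1 - n2
    return np.stack([n1, n2, n3], axis=-1)


def simulate_community(config: SimulationConfig) -> SyntheticTruth:
    """Generate a genome, per-sample coverage tracks and (optionally) pileups.

    Planted variant positions receive alternate-allele counts that are
    binomial in the sample's haplotype mixture frequency; all other positions
    receive uniform sequencing error at ``config.error_rate``.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    genome = simulate_skewed_genome(L, config.ori_position, config.ter_position,
                                    config.skew_amplitude, config.gc_content, rng)
    ref_idx = base_indices(genome)

    # planted variants: one alt base per position; mixture freq per sample
    variant_truth: dict[int, str] = {}
    for hap in config.haplotypes:
        for pos, alt in hap.items():
            if variant_truth.setdefault(pos, alt) != alt:
                raise ValueError(f"conflicting alt bases planted at position {pos}")
    vpos = np.array(sorted(variant_truth), dtype=np.int64)
    freqs = config.frequencies
    mixture = np.zeros((config.n_samples, len(vpos)))
    for h, hap in enumerate(config.haplotypes):
        for j, pos in enumerate(vpos):
            if int(pos) in hap:
                mixture[:, j] += freqs[:, h]
    # a planted variant must change the base
    for j, pos in enumerate(vpos):
        if ref_idx[pos] == BASE_ORDER.index(variant_truth[int(pos)]):
            # flip the reference base at the planted site so alt differs
            alt_i = (ref_idx[pos] + 1) % 4
            genome = genome[:pos] + BASE_ORDER[alt_i] + genome[pos + 1:]
            ref_idx[pos] = alt_i
            # keep planted alt as recorded

    tracks: list[CoverageTrack] = []
    pileup: PileupMatrix | None = None
    counts = None
    if config.make_pileups:
        counts = np.zeros((config.n_samples, L, 4), dtype=np.int64)

    for s in range(config.n_samples):
        track = simulate_coverage_track(L, config.ori_position, config.true_ptr,
                                        config.mean_coverage, rng, config.noise)
        tracks.append(track)
        if counts is None:
            continue
        depth = track.depths.astype(np.int64)
        c = counts[s]
        np.add.at(c, (np.arange(L), ref_idx), depth)
        if config.error_rate > 0:
            errors = rng.binomial(depth, config.error_rate)
            errors[vpos] = 0  # mixture handled below
            split = _split_errors(rng, errors)
            other = np.argsort(np.eye(4)[ref_idx], axis=1)[:, :3]  # 3 non-ref indices
            for k in range(3):
                np.add.at(c, (np.arange(L), other[:, k]), split[:, k])
            c[np.arange(L), ref_idx] -= errors
        if len(vpos):
            alt_counts = rng.binomial(depth[vpos], mixture[s])
            alt_idx = np.array([BASE_ORDER.index(variant_truth[int(p)]) for p in vpos])
            c[vpos, ref_idx[vpos]] -= alt_counts
            c[vpos, alt_idx] += alt_counts
    if counts is not None:
        pileup = PileupMatrix(counts, ref_idx, [f"S{i}" for i in range(config.n_samples)])

    return SyntheticTruth(config, genome, tracks, pileup, variant_truth, mixture)


# ---------------------------------------------------------------------------
# draft assemblies
# ---------------------------------------------------------------------------

@dataclass
class FragmentTruth:
    """Ground truth for a fragmented assembly.

    ``order`` lists contig ids in true circular order starting from the random
    rotation point; ``orientation`` maps contig id to '+'/'-'; ``rotation`` is
    the offset of the first fragment in the original genome.
    """

    order: list[str]
    orientation: dict[str, str]
    rotation: int


def fragment_assembly(genome: str, n_contigs: int, seed: int = 0,
                      min_length: int = 2_000,
                      cut_seed: int = 0) -> tuple[list[tuple[str, str]], FragmentTruth]:
    """Cut a circular genome into fragments, shuffle and strand-flip them.

    Fragments partition a random rotation of the genome (so one fragment wraps
    the origin of the original coordinate system).  ``cut_seed`` controls the
    rotation and cut points while ``seed`` controls shuffling and strand
    flips, so two draws with different ``seed`` values yield the same
    fragment multiset in different arrangements.  Returns the shuffled
    contigs as ``(contig_id, sequence)`` pairs plus the recorded truth.
    """
    L = len(genome)
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if n_contigs * min_length > L:
        raise ValueError(f"cannot cut {L} bp into {n_contigs} fragments of >= {min_length} bp")
    rng_cut = np.random.default_rng(cut_seed)
    rng = np.random.default_rng(seed)
    rotation = int(rng_cut.integers(L))
    rotated = genome[rotation:] + genome[:rotation]
    extra = rng_cut.multinomial(L - n_contigs * min_length, [1.0 / n_contigs] * n_contigs)
    lengths = extra + min_length
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    ids = [f"contig_{i:03d}" for i in range(n_contigs)]
    orientation = {cid: ("-" if rng.random() < 0.5 and n_contigs > 1 else "+") for cid in ids}
    frags = {}
    for cid, start, ln in zip(ids, starts, lengths):
        seq = rotated[start:start + ln]
        frags[cid] = reverse_complement(seq) if orientation[cid] == "-" else seq
    shuffled = list(ids)
    rng.shuffle(shuffled)
    contigs = [(cid, frags[cid]) for cid in shuffled]
    return contigs, FragmentTruth(order=ids, orientation=orientation, rotation=rotation)


# ---------------------------------------------------------------------------
# SNV frequency trajectories
# ---------------------------------------------------------------------------

def _latent_curves(n_curves: int, n_samples: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Smooth latent frequency curves with pairwise correlation exactly 0.

    Curves are distinct circular Fourier modes (cos/sin of integer frequency)
    on the sample grid, which are mutually orthogonal, so every pair of
    latent curves sits at correlation distance 1 — well clear of any
    clustering cutoff below 1.  Amplitudes are jittered and the mode
    assignment shuffled so curve shapes vary between seeds.
    """
    x = np.arange(n_samples) / n_samples
    modes = []
    for k in range(1, (n_samples - 1) // 2 + 1):
        modes.append(np.cos(2 * np.pi * k * x))
        modes.append(np.sin(2 * np.pi * k * x))
    if n_curves > len(modes):
        raise ValueError(f"at most {len(modes)} separable cohorts at {n_samples} samples; "
                         "increase n_samples")
    order = rng.permutation(len(modes))[:n_curves]
    curves = []
    for i in order:
        amp = rng.uniform(0.25, 0.42) * rng.choice([-1.0, 1.0])
        curves.append(np.clip(0.5 + amp * modes[i], 0.05, 0.95))
    return curves


def simulate_trajectories(n_cohorts: int, n_singletons: int, n_samples: int,
                          noise_sd: float, seed: int = 0,
                          members_per_cohort: int = 5,
                          depth: int = 100) -> tuple[list["VariantTrajectory"], np.ndarray]:
    """Planted-cohort variant trajectories for clustering benchmarks.

    Each cohort follows one smooth latent curve; members are the curve plus
    i.i.d. Gaussian noise truncated to [0, 1].  Singletons get their own
    curves.  Latent curves are mutually orthogonal (see
    :func:`_latent_curves`), which makes the planted partition identifiable.
    Returns the trajectories and integer labels (cohorts first, then
    singletons).
    """
    from .microdiversity import VariantTrajectory  # local import to avoid cycle

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_samples < 2:
        raise ValueError("trajectories need at least 2 samples")
    rng = np.random.default_rng(seed)
    n_curves = n_cohorts + n_singletons
    curves = _latent_curves(n_curves, n_samples, rng)
    sample_ids = [f"S{i}" for i in range(n_samples)]
    trajectories: list[VariantTrajectory] = []
    labels: list[int] = []
    pos = 0
    for ci, curve in enumerate(curves):
        n_members = members_per_cohort if ci < n_cohorts else 1
        for _ in range(n_members):
            f = np.clip(curve + rng.normal(0.0, noise_sd, n_samples), 0.0, 1.0)
            trajectories.append(VariantTrajectory(
                position=pos, ref_base="A", alt_base="G",
                freqs=f, depths=np.full(n_samples, depth, dtype=np.int64),
                sample_ids=list(sample_ids)))
            labels.append(ci)
            pos += 997  # spread positions out
    return trajectories, np.asarray(labels)


# ---------------------------------------------------------------------------
# CRISPR arrays and phage
# ---------------------------------------------------------------------------

def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(BASE_ORDER[i] for i in rng.integers(0, 4, length))


def _mutate(seq: str, n_mismatches: int, rng: np.random.Generator) -> str:
    out = list(seq)
    for p in rng.choice(len(seq), size=n_mismatches, replace=False):
        choices = [b for b in BASE_ORDER if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


@dataclass
class CrisprTruth:
    """Where protospacers were planted in the phage pool."""

    exact: tuple[str, str, int]        # (spacer_id, phage_id, position)
    one_mismatch: tuple[str, str, int]
    two_mismatch: tuple[str, str, int]
    array_in_phage: str | None         # phage carrying a full CRISPR locus


def simulate_crispr_system(n_shared_spacers: int, n_unique_a: int, n_unique_b: int,
                           phage_pool_size: int, seed: int = 0,
                           spacer_length: int = 32, repeat_length: int = 28,
                           phage_length: int = 3_000,
                           plant_array_in_phage: bool = True):
    """Two CRISPR arrays sharing a spacer block, plus a phage pool with
    planted protospacers at 0, 1 and 2 mismatches.

    Shared spacers sit at the (ancestral) trailer end of both arrays; unique
    spacers at the leader end, mimicking unidirectional spacer acquisition.
    Returns ``(array_a, array_b, phages, truth)`` where ``phages`` is a list
    of ``(phage_id, sequence)``.
    """
    from .crispr import CrisprArray  # local import to avoid cycle

    if spacer_length < 20 or repeat_length < 20:
        raise ValueError("spacer and repeat lengths must be >= 20 bp")
    needed = 3 + (1 if plant_array_in_phage else 0)
    if phage_pool_size < needed:
        raise ValueError(f"phage pool too small to hold planted targets (need >= {needed})")
    rng = np.random.default_rng(seed)
    repeat = _random_seq(repeat_length, rng)
    total = n_shared_spacers + n_unique_a + n_unique_b
    spacers = []
    seen = set()
    while len(spacers) < total:
        s = _random_seq(spacer_length, rng)
        if s not in seen and reverse_complement(s) not in seen:
            spacers.append(s)
            seen.add(s)
    shared = spacers[:n_shared_spacers]
    uniq_a = spacers[n_shared_spacers:n_shared_spacers + n_unique_a]
    uniq_b = spacers[n_shared_spacers + n_unique_a:]
    array_a = CrisprArray("array_A", repeat,
                          [(f"A{i}", s) for i, s in enumerate(uniq_a + shared)], "genome_A")
    array_b = CrisprArray("array_B", repeat,
                          [(f"B{i}", s) for i, s in enumerate(uniq_b + shared)], "genome_B")

    phages = [(f"phage_{i:02d}", _random_seq(phage_length, rng))
              for i in range(phage_pool_size)]

    def plant(phage_i: int, insert: str) -> int:
        pid, seq = phages[phage_i]
        pos = int(rng.integers(0, len(seq) - len(insert)))
        phages[phage_i] = (pid, seq[:pos] + insert + seq[pos + len(insert):])
        return pos

    sp = array_a.spacers
    exact_id, exact_seq = sp[0]
    mm1_id, mm1_seq = sp[1 % len(sp)]
    mm2_id, mm2_seq = sp[2 % len(sp)]
    p0 = plant(0, exact_seq)
    p1 = plant(1, _mutate(mm1_seq, 1, rng))
    p2 = plant(2, _mutate(mm2_seq, 2, rng))
    array_phage = None
    if plant_array_in_phage:
        locus = array_a.locus_sequence()
        pid, seq = phages[3]
        seq = seq + locus + _random_seq(200, rng)
        phages[3] = (pid, seq)
        array_phage = pid
    truth = CrisprTruth((exact_id, phages[0][0], p0),
                        (mm1_id, phages[1][0], p1),
                        (mm2_id, phages[2][0], p2),
                        array_phage)
    return array_a, array_b, phages, truth


# ---------------------------------------------------------------------------
# synthetic study tables (stand-ins for per-sample summaries)
# ---------------------------------------------------------------------------

def simulate_growth_table(seed: int = 0, n_gut: int = 135, n_mouth: int = 25,
                          n_skin: int = 25, gut_age_rho: float = 0.31) -> pd.DataFrame:
    """Synthetic PTR measurement table emulating a two-infant study design.

    Gut measurements dominate (longitudinal stool sampling, default n=135)
    and carry a planted positive rank correlation between PTR and day of
    life; mouth and skin carry fewer measurements with systematically higher
    replication rates, the study condition the body-site comparison is meant
    to detect.  PTR values are 1 + lognormal, so always >= 1.
    """
    rng = np.random.default_rng(seed)
    rows = []
    day = rng.integers(1, 31, size=n_gut)
    z_day = (day - day.mean()) / day.std()
    z = gut_age_rho * z_day + np.sqrt(1 - gut_age_rho ** 2) * rng.normal(size=n_gut)
    gut_ptr = 1.0 + np.exp(-1.0 + 0.5 * z)
    for i in range(n_gut):
        rows.append(("genome_%02d" % (i % 12), f"gut_{i:03d}", "gut", int(day[i]), float(gut_ptr[i])))
    for site, n in (("mouth", n_mouth), ("skin", n_skin)):
        d = rng.integers(1, 31, size=n)
        ptr = 1.0 + np.exp(-0.05 + 0.5 * rng.normal(size=n))
        for i in range(n):
            rows.append(("genome_%02d" % (i % 8), f"{site}_{i:03d}", site, int(d[i]), float(ptr[i])))
    return pd.DataFrame(rows, columns=["genome_id", "sample_id", "body_site", "day_of_life", "ptr"])


def simulate_colonization_tables(seed: int = 0) -> tuple[pd.DataFrame, list[tuple[str, str]], dict[str, str]]:
    """Synthetic abundance table and identity calls with 7 planted multi-site
    populations across two infants and none shared between infants.

    Infant 1 carries one population colonizing gut, mouth and skin; infant 2
    carries four three-site populations plus two two-site populations,
    mirroring a NICU cohort in which early colonists span body habitats.
    Genomes assembled independently from different body sites of the same
    infant are recorded as identical (>99.9% consensus ANI) pairs; no pair
    crosses infants.  Returns ``(abundance, identical_pairs, infant_of)``.
    """
    rng = np.random.default_rng(seed)
    plan = [
        # (infant, population, sites colonized)
        ("infant1", "koseri", ["gut", "mouth", "skin"]),
        ("infant1", "faecalis1", ["gut"]),            # single-site
        ("infant2", "ecoli", ["gut", "mouth", "skin"]),
        ("infant2", "aeruginosa", ["gut", "mouth", "skin"]),
        ("infant2", "pneumoniae", ["gut", "mouth", "skin"]),
        ("infant2", "marcescens", ["gut", "mouth", "skin"]),
        ("infant2", "faecalis2", ["mouth", "skin"]),
        ("infant2", "epidermidis", ["mouth", "gut"]),
        ("infant2", "agalactiae", ["gut"]),           # single-site
    ]
    rows = []
    identical: list[tuple[str, str]] = []
    infant_of: dict[str, str] = {}
    for infant, pop, sites in plan:
        genomes = []
        for site in ["gut", "mouth", "skin"]:
            gid = f"{infant}:{pop}:{site}"
            infant_of[gid] = infant
            genomes.append(gid)
            colonized = site in sites
            for t in range(3):
                pct = float(rng.uniform(2, 40)) if colonized else float(rng.uniform(0.01, 0.5))
                rows.append((f"{infant}_{site}_{t}", site, 3 + 7 * t, gid, pct,
                             10_000_000, 150))
        # genomes of one population are pairwise identical
        for i in range(len(genomes)):
            for j in range(i + 1, len(genomes)):
                identical.append((genomes[i], genomes[j]))
    abundance = pd.DataFrame(rows, columns=[
        "sample_id", "body_site", "day_of_life", "genome_id",
        "percent_of_nonhuman_reads", "total_sample_reads", "read_length"])
    return abundance, identical, infant_of
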